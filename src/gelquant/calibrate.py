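"""Ladder calibration: mapping migration distance (rows) to size (kb).

DNA fragment migration in gel electrophoresis is, to good approximation,
linear in the logarithm of fragment size.  The calibration therefore
interpolates ``log10(size_kb)`` piecewise-linearly between the ladder
knots, which tolerates the mild deviations from global log-linearity real
gels show at the size extremes.  A global least-squares line in the same
coordinates is fitted alongside purely as a QC diagnostic (``fit_r2``).

Ladder bands are paired with known sizes strictly by position: the i-th
band by increasing migration gets the i-th size by decreasing size.  A
count mismatch is surfaced to the caller (who can edit the ladder lane's
calls) rather than resolved by combinatorial guessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError
from .detect import PeakCall
from .gelio import Band

#: fraction of the knot span over which the terminal segments may be
#: extrapolated before size_at refuses.
DEFAULT_EXTRAPOLATION_FRAC = 0.10

#: global log-linear R^2 below which fit_ladder emits a QC warning.
R2_WARN_THRESHOLD = 0.98


@dataclass(frozen=True)
class LadderCalibration:
    """Fitted monotone map between migration rows and fragment size.

    ``knots`` are (position_row, size_kb) pairs with strictly increasing
    positions and strictly decreasing sizes.  ``fit_r2`` is the R^2 of a
    single global line through (position, log10 size) — a linearity
    diagnostic, not the interpolant itself.
    """

    knots: tuple[tuple[float, float], ...]
    model: str = "piecewise-linear-in-log10(size)"
    fit_r2: float = float("nan")
    extrapolation_limit_rows: float = 0.0

    def __post_init__(self) -> None:
        if len(self.knots) < 3:
            raise CalibrationError(
                f"calibration needs >= 3 knots, got {len(self.knots)}"
            )
        pos = np.array([k[0] for k in self.knots])
        size = np.array([k[1] for k in self.knots])
        if not np.all(np.diff(pos) > 0):
            raise CalibrationError("knot positions must strictly increase")
        if not np.all(np.diff(size) < 0):
            raise CalibrationError(
                "knot sizes must strictly decrease with migration — "
                "check the ladder band/size pairing"
            )
        if np.any(size <= 0):
            raise CalibrationError("knot sizes must be > 0")

    @property
    def positions(self) -> np.ndarray:
        return np.array([k[0] for k in self.knots])

    @property
    def sizes_kb(self) -> np.ndarray:
        return np.array([k[1] for k in self.knots])

    @property
    def domain(self) -> tuple[float, float]:
        pos = self.positions
        lim = self.extrapolation_limit_rows
        return float(pos[0] - lim), float(pos[-1] + lim)


def fit_ladder(ladder_bands: list[PeakCall] | list[Band],
               known_sizes_kb: list[float],
               extrapolation_frac: float = DEFAULT_EXTRAPOLATION_FRAC,
               ) -> LadderCalibration:
    """Pair ladder band calls with known sizes and fit the calibration.

    ``known_sizes_kb`` must be in descending order (largest fragment
    migrates least) and match the band count exactly.
    """
    positions = sorted(
        float(b.position if isinstance(b, PeakCall) else b.position_row)
        for b in ladder_bands
    )
    sizes = sorted((float(s) for s in known_sizes_kb), reverse=True)
    if len(positions) != len(sizes):
        raise CalibrationError(
            f"ladder band count mismatch: {len(positions)} bands called but "
            f"{len(sizes)} known sizes — edit the ladder lane's calls first"
        )
    if len(positions) < 3:
        raise CalibrationError("calibration needs >= 3 ladder bands")
    knots = tuple(zip(positions, sizes))

    pos = np.asarray(positions)
    logs = np.log10(np.asarray(sizes))
    slope, intercept = np.polyfit(pos, logs, 1)
    resid = logs - (slope * pos + intercept)
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    fit_r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    if fit_r2 < R2_WARN_THRESHOLD:
        warnings.warn(
            f"ladder global log-linear R^2 = {fit_r2:.4f} < "
            f"{R2_WARN_THRESHOLD}; check ladder calls",
            stacklevel=2,
        )
    span = positions[-1] - positions[0]
    cal = LadderCalibration(
        knots=knots,
        fit_r2=fit_r2,
        extrapolation_limit_rows=extrapolation_frac * span,
    )
    return cal


def size_at(cal: LadderCalibration, position_row: float) -> float:
    """Fragment size (kb) at a migration position.

    Interpolates log10(size) linearly between bracketing knots; beyond the
    terminal knots the terminal segment's slope is extended up to
    ``extrapolation_limit_rows``, after which the position is out of
    domain.
    """
    pos = cal.positions
    logs = np.log10(cal.sizes_kb)
    lo, hi = cal.domain
    p = float(position_row)
    if not (lo <= p <= hi):
        raise CalibrationError(
            f"position {p} outside calibration domain [{lo:.2f}, {hi:.2f}]"
        )
    if p <= pos[0]:
        slope = (logs[1] - logs[0]) / (pos[1] - pos[0])
        return float(10.0 ** (logs[0] + slope * (p - pos[0])))
    if p >= pos[-1]:
        slope = (logs[-1] - logs[-2]) / (pos[-1] - pos[-2])
        return float(10.0 ** (logs[-1] + slope * (p - pos[-1])))
    return float(10.0 ** np.interp(p, pos, logs))


def assign_sizes(bands: list[Band], cal: LadderCalibration
                 ) -> tuple[list[Band], list[Band]]:
    """Attach sizes to bands via the calibration.

    Out-of-domain bands are left unsized and returned separately as flags
    for the run report; nothing is dropped.  Ordering and all other
    fields are unchanged.

    Returns
    -------
    (sized, flagged)
        ``sized`` is the full band list (out-of-domain entries keep
        ``size_kb=None``); ``flagged`` lists those out-of-domain bands.
    """
    from dataclasses import replace

    lo, hi = cal.domain
    out, flagged = [], []
    for b in bands:
        if lo <= b.position_row <= hi:
            out.append(replace(b, size_kb=size_at(cal, b.position_row)))
        else:
            out.append(b)
            flagged.append(b)
    return out, flagged
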