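"""Synthetic Universal STELA gel images with exact ground truth.

Every upstream stage (preprocessing, lane/band detection, calibration,
quantification) is validated against gels rendered from a fully specified
generative model:

* migration is log-linear, ``log10(size_kb) = a + b * row`` with ``b < 0``
  — the classic electrophoresis approximation and intentionally the same
  family the calibrator fits, so calibration error is separable from
  detection error;
* each band is a separable 2-D Gaussian (spread ``band_sigma_rows`` along
  migration, ``lane_sigma_cols`` laterally) of a given amplitude;
* background is a smooth base level plus a linear row gradient;
* noise is additive Gaussian (scanned film/CCD gels at working
  intensities are well approximated, and it keeps signal-to-noise
  definitions simple), clipped at zero.

The spec plus its seed fully determine the image: same spec, same pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import SimulationError
from .gelio import Band, GelImage

#: ladder fragment sizes (kb) shared by all presets, largest first.
LADDER_SIZES_KB = (8.0, 6.0, 4.0, 3.0, 2.0, 1.5, 1.0, 0.5)

FIXTURE_KINDS = ("clean", "noisy", "crowded", "ladder-only")


@dataclass(frozen=True)
class LaneSpec:
    """One simulated lane: center column, role, band sizes and amplitudes."""

    center_col: float
    role: str  # "sample" | "ladder"
    band_sizes_kb: tuple[float, ...]
    band_amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.role not in ("sample", "ladder"):
            raise SimulationError(f"unknown lane role {self.role!r}")
        if len(self.band_sizes_kb) != len(self.band_amplitudes):
            raise SimulationError("one amplitude per band required")
        if any(s <= 0 for s in self.band_sizes_kb):
            raise SimulationError("band sizes must be > 0")
        if any(a <= 0 for a in self.band_amplitudes):
            raise SimulationError("band amplitudes must be > 0")


@dataclass(frozen=True)
class SyntheticGelSpec:
    """Complete generative description of one synthetic gel."""

    n_rows: int
    n_cols: int
    migration_model: tuple[float, float]  # (a, b): log10(kb) = a + b*row
    lanes: tuple[LaneSpec, ...]
    band_sigma_rows: float = 2.5
    lane_sigma_cols: float = 6.0
    background: tuple[float, float] = (20.0, 0.02)  # (base, per-row gradient)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.migration_model
        if b >= 0:
            raise SimulationError("migration slope b must be < 0")
        if self.band_sigma_rows <= 0 or self.lane_sigma_cols <= 0:
            raise SimulationError("band/lane sigmas must be > 0")
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be >= 0")
        for lane in self.lanes:
            if not (0 <= lane.center_col < self.n_cols):
                raise SimulationError(
                    f"lane center {lane.center_col} outside [0, {self.n_cols})"
                )
            for s in lane.band_sizes_kb:
                position_of(self, s)  # raises if out of bounds


def position_of(spec: SyntheticGelSpec, size_kb: float) -> float:
    """Row at which a fragment of ``size_kb`` sits: ``(log10(s) - a) / b``."""
    a, b = spec.migration_model
    row = (math.log10(size_kb) - a) / b
    if not (0 <= row < spec.n_rows):
        raise SimulationError(
            f"size {size_kb} kb maps to row {row:.1f}, outside "
            f"[0, {spec.n_rows})"
        )
    return row


def truth_table(spec: SyntheticGelSpec) -> pd.DataFrame:
    """Ground-truth band table: one row per simulated band."""
    rows = []
    for lane_id, lane in enumerate(spec.lanes):
        for size, amp in zip(lane.band_sizes_kb, lane.band_amplitudes):
            rows.append({
                "lane_id": lane_id,
                "true_size_kb": size,
                "true_position_row": position_of(spec, size),
                "true_amplitude": amp,
            })
    return pd.DataFrame(
        rows, columns=["lane_id", "true_size_kb", "true_position_row",
                       "true_amplitude"],
    )


def render_gel(spec: SyntheticGelSpec) -> tuple[GelImage, pd.DataFrame]:
    """Render the gel image and its truth table.

    image = background + sum of separable Gaussian bands + N(0, sigma),
    clipped at 0.  Deterministic under ``spec.seed``.
    """
    rows = np.arange(spec.n_rows, dtype=float)[:, None]
    cols = np.arange(spec.n_cols, dtype=float)[None, :]
    base, gradient = spec.background
    image = np.broadcast_to(base + gradient * rows,
                            (spec.n_rows, spec.n_cols)).copy()
    truth = truth_table(spec)
    for lane_id, lane in enumerate(spec.lanes):
        lateral = np.exp(-((cols - lane.center_col) ** 2)
                         / (2.0 * spec.lane_sigma_cols ** 2))
        axial = np.zeros((spec.n_rows, 1))
        for size, amp in zip(lane.band_sizes_kb, lane.band_amplitudes):
            pos = position_of(spec, size)
            axial += amp * np.exp(-((rows - pos) ** 2)
                                  / (2.0 * spec.band_sigma_rows ** 2))
        image += axial * lateral
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, None)
    gel = GelImage(pixels=image, bit_depth=16,
                   provenance=f"synthetic seed={spec.seed}")
    return gel, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _sample_sizes(rng: np.random.Generator, n: int, lo_kb: float,
                  hi_kb: float, min_log_gap: float) -> tuple[float, ...]:
    """Draw ``n`` sizes log-uniform in [lo, hi] kb with pairwise log10
    spacing >= ``min_log_gap``, via the stick-breaking construction
    (uniform draws on the shrunk interval plus deterministic offsets)."""
    lo, hi = math.log10(lo_kb), math.log10(hi_kb)
    span = hi - lo
    free = span - (n - 1) * min_log_gap
    if free <= 0:
        raise SimulationError(
            f"cannot place {n} bands with log-spacing {min_log_gap} in "
            f"[{lo_kb}, {hi_kb}] kb"
        )
    u = np.sort(rng.uniform(0.0, free, size=n))
    logs = lo + u + min_log_gap * np.arange(n)
    return tuple(float(10.0 ** x) for x in logs)


def default_fixture(kind: str, seed: int = 0) -> SyntheticGelSpec:
    """Documented simulation presets.

    * ``clean`` — 600x400 image, migration ``log10(kb) = 1.0 - 0.0025*row``,
      one ladder lane (8, 6, 4, 3, 2, 1.5, 1, 0.5 kb, amplitude 300) and 3
      sample lanes with 5–12 bands drawn log-uniform in [0.4, 8] kb with a
      minimum log10 spacing of 0.03 (~12 rows), amplitudes U(180, 280),
      noise sigma 11.5 (SNR ~ 20 by mean amplitude / noise).
    * ``noisy`` — clean with noise sigma 57.5 (SNR ~ 4).
    * ``crowded`` — clean with the minimum inter-band spacing halved.
    * ``ladder-only`` — the ladder lane alone, no noise.

    Same kind + seed always returns the identical spec.
    """
    if kind not in FIXTURE_KINDS:
        raise SimulationError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )
    n_rows, n_cols = 600, 400
    migration = (1.0, -0.0025)
    ladder = LaneSpec(
        center_col=50.0, role="ladder",
        band_sizes_kb=LADDER_SIZES_KB,
        band_amplitudes=(300.0,) * len(LADDER_SIZES_KB),
    )
    if kind == "ladder-only":
        return SyntheticGelSpec(
            n_rows=n_rows, n_cols=n_cols, migration_model=migration,
            lanes=(ladder,), noise_sigma=0.0, seed=seed,
        )
    noise_sigma = 57.5 if kind == "noisy" else 11.5
    min_log_gap = 0.015 if kind == "crowded" else 0.03
    rng = np.random.default_rng(seed)
    lanes = [ladder]
    for i in range(3):
        n_bands = int(rng.integers(5, 13))
        sizes = _sample_sizes(rng, n_bands, 0.4, 8.0, min_log_gap)
        amps = tuple(float(a) for a in rng.uniform(180.0, 280.0, n_bands))
        lanes.append(LaneSpec(
            center_col=150.0 + 100.0 * i, role="sample",
            band_sizes_kb=sizes, band_amplitudes=amps,
        ))
    return SyntheticGelSpec(
        n_rows=n_rows, n_cols=n_cols, migration_model=migration,
        lanes=tuple(lanes), noise_sigma=noise_sigma, seed=seed,
    )


# ---------------------------------------------------------------------------
# scoring detections against truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionScore:
    """Truth-vs-called matching summary for one or more lanes."""

    n_truth: int
    n_called: int
    n_matched: int
    size_errors_frac: tuple[float, ...]  # |est - true| / true per match

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else math.nan

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_called if self.n_called else math.nan


def score_detection(truth: pd.DataFrame, bands: list[Band],
                    tol_rows: float = 3.0) -> DetectionScore:
    """Match called bands to truth one-to-one within ``tol_rows`` per lane.

    Matching minimizes total |row error| via the assignment problem; pairs
    farther apart than ``tol_rows`` are never matched.
    """
    n_truth = len(truth)
    n_called = len(bands)
    n_matched = 0
    errors: list[float] = []
    big = 1e9
    for lane_id in sorted(set(truth["lane_id"]) | {b.lane_id for b in bands}):
        t = truth[truth["lane_id"] == lane_id]
        c = [b for b in bands if b.lane_id == lane_id]
        if len(t) == 0 or len(c) == 0:
            continue
        t_pos = t["true_position_row"].to_numpy()
        c_pos = np.array([b.position_row for b in c])
        cost = np.abs(t_pos[:, None] - c_pos[None, :])
        cost = np.where(cost <= tol_rows, cost, big)
        ti, ci = linear_sum_assignment(cost)
        for a, b_ in zip(ti, ci):
            if cost[a, b_] < big:
                n_matched += 1
                est = c[b_].size_kb
                if est is not None:
                    true_size = float(t["true_size_kb"].iloc[a])
                    errors.append(abs(est - true_size) / true_size)
    return DetectionScore(
        n_truth=n_truth, n_called=n_called, n_matched=n_matched,
        size_errors_frac=tuple(errors),
    )


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, index=False)


def spec_to_json_dict(spec: SyntheticGelSpec) -> dict:
    d = asdict(spec)
    d["lanes"] = [asdict(l) for l in spec.lanes]
    return d
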