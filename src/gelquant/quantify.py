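"""Per-lane telomere statistics and run reports.

Universal STELA produces discrete bands, each one amplified telomere
molecule, so per-lane summaries are computed over the called band set:

* ``mean_size_kb`` — unweighted mean of band sizes (every molecule counts
  once);
* ``intensity_weighted_mean_kb`` — area-weighted mean, closer to what a
  densitometric readout would give;
* ``short_ratio`` — fraction of bands strictly below the short-telomere
  threshold (default 1.6 kb, the cut-off used to flag critically short
  Uni-STELA products);
* ``short_intensity_ratio`` — the same fraction measured in integrated
  band intensity.

Both count- and intensity-based short ratios are reported because
discrete STELA bands argue for counts while densitometry traditions argue
for intensity; the count-based ratio is primary.

``smear_mean_length`` implements the standard TRF (terminal restriction
fragment) smear estimator ``sum(OD_i) / sum(OD_i / L_i)`` as an optional
add-on for continuous-smear lanes; it is not part of the STELA band
statistics.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .calibrate import LadderCalibration, size_at
from .detect import IntensityProfile
from .errors import QuantError
from .gelio import Band, Lane

DEFAULT_SHORT_THRESHOLD_KB = 1.6


@dataclass(frozen=True)
class LaneStats:
    """Summary statistics for one lane's sized bands.

    With zero bands the means and ratios are NaN (undefined), never zero.
    """

    lane_id: int
    n_bands: int
    mean_size_kb: float
    intensity_weighted_mean_kb: float
    short_threshold_kb: float
    short_count: int
    short_ratio: float
    short_intensity_ratio: float


def lane_stats(bands: list[Band],
               short_threshold_kb: float = DEFAULT_SHORT_THRESHOLD_KB,
               lane_id: int | None = None) -> LaneStats:
    """Compute per-lane statistics from sized bands of a single lane.

    A band exactly at the threshold counts as NOT short (strict ``<``).
    ``lane_id`` is only needed for an empty lane, where it cannot be
    inferred from the bands.
    """
    if not bands:
        return LaneStats(
            lane_id=-1 if lane_id is None else lane_id, n_bands=0,
            mean_size_kb=math.nan, intensity_weighted_mean_kb=math.nan,
            short_threshold_kb=short_threshold_kb,
            short_count=0, short_ratio=math.nan,
            short_intensity_ratio=math.nan,
        )
    lane_ids = {b.lane_id for b in bands}
    if len(lane_ids) > 1:
        raise QuantError(f"bands from multiple lanes: {sorted(lane_ids)}")
    unsized = [b for b in bands if b.size_kb is None]
    if unsized:
        raise QuantError(
            f"{len(unsized)} unsized band(s) in lane {bands[0].lane_id}; "
            "run calibration first or remove flagged bands"
        )
    sizes = np.array([b.size_kb for b in bands])
    areas = np.array([b.area for b in bands])
    short = sizes < short_threshold_kb
    total_area = float(areas.sum())
    return LaneStats(
        lane_id=bands[0].lane_id,
        n_bands=len(bands),
        mean_size_kb=float(sizes.mean()),
        intensity_weighted_mean_kb=(
            float((areas * sizes).sum() / total_area) if total_area > 0
            else math.nan
        ),
        short_threshold_kb=short_threshold_kb,
        short_count=int(short.sum()),
        short_ratio=float(short.sum() / len(bands)),
        short_intensity_ratio=(
            float(areas[short].sum() / total_area) if total_area > 0
            else math.nan
        ),
    )


def smear_mean_length(profile: IntensityProfile, cal: LadderCalibration,
                      row_range: tuple[int, int]) -> float:
    """TRF-style intensity-weighted mean length over a smear region.

    ``sum_i OD_i / sum_i (OD_i / L_i)`` for rows i in the half-open
    ``row_range``, with OD the (background-subtracted) profile value and
    L the calibrated size at that row.  The calibration must cover the
    whole range.
    """
    start, stop = int(row_range[0]), int(row_range[1])
    if not (0 <= start < stop <= len(profile)):
        raise QuantError(f"invalid row_range {row_range}")
    rows = np.arange(start, stop)
    od = profile.values[start:stop]
    total = float(od.sum())
    if total <= 0:
        raise QuantError("zero total intensity in smear region")
    sizes = np.array([size_at(cal, float(r)) for r in rows])
    return float(total / float((od / sizes).sum()))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _stats_frame(stats: list[LaneStats]) -> pd.DataFrame:
    cols = ["lane_id", "n_bands", "mean_size_kb",
            "intensity_weighted_mean_kb", "short_threshold_kb",
            "short_count", "short_ratio", "short_intensity_ratio"]
    return pd.DataFrame([asdict(s) for s in stats], columns=cols)


def gel_report(lanes: list[Lane], stats: list[LaneStats],
               cal: LadderCalibration | None,
               config: dict | None = None,
               warnings_list: list[str] | None = None) -> dict:
    """Assemble the deterministic JSON run report.

    Field order is fixed; no timestamps, so identical inputs give
    byte-identical serializations.
    """
    from . import __version__

    warnings_list = list(warnings_list or [])
    sample_lanes = [l for l in lanes if l.role == "sample"]
    if len(stats) != len(sample_lanes):
        raise QuantError(
            f"{len(stats)} stats entries for {len(sample_lanes)} sample lanes"
        )
    if not sample_lanes:
        warnings_list.append("no sample lanes detected")
    report = {
        "tool": "gelquant",
        "version": __version__,
        "config": dict(sorted((config or {}).items())),
        "lanes": [
            {"lane_id": l.lane_id, "center_col": l.center_col,
             "half_width": l.half_width, "role": l.role}
            for l in lanes
        ],
        "calibration": None if cal is None else {
            "model": cal.model,
            "knots": [[p, s] for p, s in cal.knots],
            "fit_r2": cal.fit_r2,
            "extrapolation_limit_rows": cal.extrapolation_limit_rows,
        },
        "lane_stats": _stats_frame(stats).to_dict(orient="records"),
        "warnings": warnings_list,
    }
    return report


def write_report(report: dict, stats: list[LaneStats], bands: list[Band],
                 out_dir: str) -> dict[str, str]:
    """Write lane_stats.csv, bands.csv and report.json into ``out_dir``."""
    from .gelio import write_band_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "lane_stats": os.path.join(out_dir, "lane_stats.csv"),
        "bands": os.path.join(out_dir, "bands.csv"),
        "report": os.path.join(out_dir, "report.json"),
    }
    _stats_frame(stats).to_csv(paths["lane_stats"], index=False)
    write_band_table(bands, paths["bands"])
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return paths
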