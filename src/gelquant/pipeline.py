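"""End-to-end quantification: image in, per-lane telomere statistics out.

``quantify_gel`` runs the full chain — preprocess, lane detection, per-
lane band calling, ladder calibration, size assignment, lane statistics —
and returns everything a report needs.  The CLI and the examples are thin
wrappers over this function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .calibrate import LadderCalibration, assign_sizes, fit_ladder
from .config import RunConfig, config_to_dict
from .detect import (
    IntensityProfile,
    apply_edits,
    bands_from_peaks,
    detect_bands,
    detect_lanes,
    lane_profile,
    lateral_profile,
    smooth_profile,
)
from .errors import EditError
from .gelio import Band, EditSet, GelImage, Lane
from .preprocess import preprocess
from .quantify import LaneStats, gel_report, lane_stats


@dataclass
class QuantifyResult:
    """Everything one quantification run produced."""

    image: GelImage  # preprocessed image
    lanes: list[Lane]
    profiles: dict[int, IntensityProfile]  # smoothed lane profiles
    bands: list[Band]  # all lanes, sized where in calibration domain
    calibration: LadderCalibration
    stats: list[LaneStats]
    warnings: list[str]
    report: dict


def quantify_gel(image: GelImage, ladder_sizes_kb: list[float],
                 ladder_lane: int = 0,
                 config: RunConfig | None = None,
                 expected_n_lanes: int | None = None,
                 edits: EditSet | None = None) -> QuantifyResult:
    """Quantify one Universal STELA gel image.

    Parameters
    ----------
    image
        Polarity-normalized gel image (wells at top).
    ladder_sizes_kb
        Known ladder fragment sizes; descending order is enforced.
    ladder_lane
        Index (left to right, 0-based) of the ladder lane.
    config
        Pipeline parameters; defaults used when omitted.
    expected_n_lanes
        Optional lane-count hint passed to lane detection.
    edits
        Manual band add/remove adjustments, applied per lane after
        automatic calling and before calibration.
    """
    cfg = config or RunConfig()
    warnings_list: list[str] = []

    pre = preprocess(
        image,
        sharpen_sigma=cfg.sharpen_sigma,
        sharpen_amount=cfg.sharpen_amount,
        background_radius_rows=cfg.background_radius_rows,
        sharpen_enabled=cfg.sharpen_enabled,
        background_enabled=cfg.background_enabled,
    )

    lat = lateral_profile(pre)
    lanes = detect_lanes(
        lat,
        expected_n=expected_n_lanes,
        min_separation_cols=cfg.lane_min_separation_cols,
        prominence_frac=cfg.lane_prominence_frac,
    )
    if not (0 <= ladder_lane < len(lanes)):
        raise EditError(
            f"ladder lane index {ladder_lane} out of range for "
            f"{len(lanes)} detected lanes"
        )
    lanes = [
        replace(l, role="ladder" if i == ladder_lane else "sample")
        for i, l in enumerate(lanes)
    ]
    if edits is not None:
        known = {l.lane_id for l in lanes}
        bad = edits.lane_ids - known
        if bad:
            raise EditError(f"edits reference unknown lanes {sorted(bad)}")

    profiles: dict[int, IntensityProfile] = {}
    per_lane_bands: dict[int, list[Band]] = {}
    for lane in lanes:
        prof = smooth_profile(lane_profile(pre, lane), window=cfg.smooth_window)
        profiles[lane.lane_id] = prof
        peaks = detect_bands(
            prof,
            min_prominence=cfg.band_threshold,
            min_distance_rows=cfg.band_min_distance_rows,
        )
        lane_bands = bands_from_peaks(
            peaks, lane.lane_id, prof,
            area_half_window_rows=cfg.band_min_distance_rows,
        )
        if edits is not None:
            lane_edits = EditSet(edits=tuple(edits.for_lane(lane.lane_id)))
            if lane_edits.edits:
                lane_bands = apply_edits(
                    lane_bands, lane_edits, prof,
                    min_distance_rows=cfg.band_min_distance_rows,
                    area_half_window_rows=cfg.band_min_distance_rows,
                )
        per_lane_bands[lane.lane_id] = lane_bands

    ladder_bands = per_lane_bands[lanes[ladder_lane].lane_id]
    cal = fit_ladder(ladder_bands, ladder_sizes_kb,
                     extrapolation_frac=cfg.extrapolation_frac)

    all_bands: list[Band] = []
    stats: list[LaneStats] = []
    for lane in lanes:
        sized, flagged = assign_sizes(per_lane_bands[lane.lane_id], cal)
        all_bands.extend(sized)
        if flagged:
            warnings_list.append(
                f"lane {lane.lane_id}: {len(flagged)} band(s) outside "
                "calibration domain left unsized"
            )
        if lane.role == "sample":
            usable = [b for b in sized if b.size_kb is not None]
            stats.append(lane_stats(
                usable, short_threshold_kb=cfg.short_threshold_kb,
                lane_id=lane.lane_id,
            ))

    report = gel_report(lanes, stats, cal, config=config_to_dict(cfg),
                        warnings_list=warnings_list)
    return QuantifyResult(
        image=pre, lanes=lanes, profiles=profiles, bands=all_bands,
        calibration=cal, stats=stats, warnings=warnings_list, report=report,
    )
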