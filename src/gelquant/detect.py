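"""Lane and band detection from intensity profiles.

The detection strategy mirrors classic gel densitometry: project the image
onto one axis and call peaks in the resulting 1-D profile.

* Lanes: sum the (preprocessed) image over rows to get the *lateral*
  profile; each lane is a peak in that profile.
* Bands: sum each lane's window over columns to get the *migration*
  profile; each band is a peak in that profile.

Peaks are selected on **prominence** — the height of a peak above the
higher of the two minima separating it from any higher peak — rather than
raw height, so bands riding on residual smear survive while smear
shoulders do not.  All tie-breaks are deterministic: among equal peaks the
smaller index wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .errors import DetectionError, EditError, ProfileError
from .gelio import Band, EditSet, GelImage, Lane

#: scale factor turning a median absolute deviation into a Gaussian-sigma
#: equivalent: 1 / Phi^-1(3/4).
MAD_TO_SIGMA = 1.4826

#: default multiplier for the adaptive band threshold (~5 sigma under
#: Gaussian noise).
DEFAULT_THRESHOLD_K = 5.0


@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D projection of the gel image.

    ``axis`` records which projection this is ("lateral" = column sums
    used for lane finding, "migration" = row sums within a lane used for
    band calling); ``origin`` describes the summed region.
    """

    values: np.ndarray
    axis: str  # "lateral" | "migration"
    origin: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ProfileError(f"profile must be 1-D with >= 2 samples, got {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ProfileError("profile values must be finite and >= 0")
        if self.axis not in ("lateral", "migration"):
            raise ProfileError(f"unknown profile axis {self.axis!r}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PeakCall:
    """One called peak: sub-pixel position, height, prominence."""

    position: float
    height: float
    prominence: float

    def __post_init__(self) -> None:
        if self.prominence > self.height + 1e-9:
            raise DetectionError("prominence cannot exceed height")


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, GelImage) else np.asarray(image, float)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def lateral_profile(image, row_range: tuple[int, int] | None = None
                    ) -> IntensityProfile:
    """Column sums over ``row_range`` (default: all rows).

    ``row_range`` is half-open ``[start, stop)`` in rows.
    """
    px = _as_pixels(image)
    n_rows = px.shape[0]
    if row_range is None:
        row_range = (0, n_rows)
    start, stop = int(row_range[0]), int(row_range[1])
    if not (0 <= start < stop <= n_rows):
        raise ProfileError(f"empty or out-of-bounds row_range {row_range}")
    values = px[start:stop, :].sum(axis=0)
    return IntensityProfile(values=values, axis="lateral",
                            origin=f"rows [{start}, {stop})")


def lane_profile(image, lane: Lane) -> IntensityProfile:
    """Row sums over the lane window ``[center - hw, center + hw)``.

    The window is intersected with the image; a window entirely outside
    the image is an error.
    """
    px = _as_pixels(image)
    n_rows, n_cols = px.shape
    lo = int(math.ceil(lane.center_col - lane.half_width))
    hi = int(math.ceil(lane.center_col + lane.half_width))
    lo, hi = max(lo, 0), min(hi, n_cols)
    if lo >= hi:
        raise ProfileError(
            f"lane {lane.lane_id} window [{lo}, {hi}) lies outside the image"
        )
    values = px[:, lo:hi].sum(axis=1)
    return IntensityProfile(values=values, axis="migration",
                            origin=f"lane {lane.lane_id} cols [{lo}, {hi})")


def smooth_profile(profile: IntensityProfile, window: int = 5
                   ) -> IntensityProfile:
    """Centered moving average; edges use the truncated window.

    ``window`` must be odd; ``window = 1`` is the identity.
    """
    if window % 2 == 0:
        raise ProfileError(f"smoothing window must be odd, got {window}")
    if window < 1 or window > len(profile):
        raise ProfileError(
            f"smoothing window {window} outside [1, {len(profile)}]"
        )
    if window == 1:
        return profile
    v = profile.values
    half = window // 2
    # truncated-window mean via cumulative sums
    csum = np.concatenate(([0.0], np.cumsum(v)))
    n = v.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return IntensityProfile(values=out, axis=profile.axis,
                            origin=profile.origin + f" | smoothed w={window}")


# ---------------------------------------------------------------------------
# peak machinery
# ---------------------------------------------------------------------------

def refine_subpixel(profile: IntensityProfile | np.ndarray,
                    peak_index: int) -> float:
    """Sub-pixel peak position by parabolic interpolation through the
    peak sample and its two neighbors.

    The vertex offset ``(y- − y+) / (2 (y- − 2 y0 + y+))`` is clamped to
    [-0.5, +0.5]; symmetric neighbors give offset 0.  Boundary indices are
    returned unchanged.
    """
    v = profile.values if isinstance(profile, IntensityProfile) else np.asarray(profile, float)
    i = int(peak_index)
    if i <= 0 or i >= v.size - 1:
        return float(i)
    ym, y0, yp = v[i - 1], v[i], v[i + 1]
    denom = 2.0 * (ym - 2.0 * y0 + yp)
    if denom == 0:
        return float(i)
    offset = (ym - yp) / denom
    return float(i + np.clip(offset, -0.5, 0.5))


def _thin_by_distance(indices: np.ndarray, heights: np.ndarray,
                      min_distance: float) -> np.ndarray:
    """Greedy peak thinning: repeatedly keep the highest remaining peak
    (ties -> smallest index) and drop peaks closer than ``min_distance``.

    Returns a boolean keep-mask aligned with ``indices`` (assumed sorted).
    """
    order = np.lexsort((indices, -heights))  # height desc, then index asc
    keep = np.ones(indices.size, dtype=bool)
    alive = np.ones(indices.size, dtype=bool)
    for k in order:
        if not alive[k]:
            continue
        close = np.abs(indices - indices[k]) < min_distance
        close[k] = False
        keep[close & alive] = False
        alive[close] = False
    return keep


def _find_candidates(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All local maxima with their heights and textbook prominences."""
    idx, _ = find_peaks(values)
    if idx.size == 0:
        return idx, np.array([]), np.array([])
    prom = peak_prominences(values, idx)[0]
    return idx, values[idx], prom


def detect_bands(profile: IntensityProfile,
                 min_prominence: float | str = "auto",
                 min_distance_rows: int = 4,
                 threshold_k: float = DEFAULT_THRESHOLD_K) -> list[PeakCall]:
    """Call bands as prominent local maxima of a migration profile.

    ``min_prominence`` is either an absolute value (a.u.) or ``"auto"``,
    which uses the adaptive rule ``k * MAD(profile) * 1.4826`` (~k-sigma
    under Gaussian noise, robust to the bands themselves).  Surviving
    peaks are thinned to ``min_distance_rows`` (higher peak wins; equal
    heights -> smaller row) and refined to sub-pixel positions.

    A flat or empty profile yields an empty list, not an error.
    """
    if min_distance_rows < 1:
        raise DetectionError(f"min_distance_rows must be >= 1, got {min_distance_rows}")
    v = profile.values
    idx, heights, prom = _find_candidates(v)
    if idx.size == 0:
        return []
    if min_prominence == "auto":
        mad = float(np.median(np.abs(v - np.median(v))))
        threshold = threshold_k * mad * MAD_TO_SIGMA
    else:
        threshold = float(min_prominence)
    sel = prom >= threshold
    idx, heights, prom = idx[sel], heights[sel], prom[sel]
    if idx.size == 0:
        return []
    keep = _thin_by_distance(idx, heights, float(min_distance_rows))
    calls = [
        PeakCall(position=refine_subpixel(v, i), height=float(h),
                 prominence=float(p))
        for i, h, p in zip(idx[keep], heights[keep], prom[keep])
    ]
    calls.sort(key=lambda c: c.position)
    return calls


def detect_lanes(profile: IntensityProfile,
                 expected_n: int | None = None,
                 min_separation_cols: int = 20,
                 prominence_frac: float = 0.2) -> list[Lane]:
    """Find lane centers as prominent peaks of the lateral profile.

    Peaks with prominence >= ``prominence_frac * max(profile)`` are kept,
    thinned so adjacent centers are >= ``min_separation_cols`` apart
    (higher peak wins; equal -> leftmost).  If ``expected_n`` is given and
    more peaks survive, the ``expected_n`` most prominent are kept.
    ``half_width`` is half the median inter-center gap, capped at half the
    minimum gap so lane windows never overlap; a single lane gets
    ``min_separation_cols``.
    """
    if profile.axis != "lateral":
        raise ProfileError("detect_lanes expects a lateral profile")
    if min_separation_cols < 2:
        raise DetectionError("min_separation_cols must be >= 2")
    v = profile.values
    idx, heights, prom = _find_candidates(v)
    threshold = prominence_frac * float(v.max())
    sel = prom >= threshold
    idx, heights, prom = idx[sel], heights[sel], prom[sel]
    if idx.size == 0:
        raise DetectionError("no lanes found in lateral profile")
    keep = _thin_by_distance(idx, heights, float(min_separation_cols))
    idx, heights, prom = idx[keep], heights[keep], prom[keep]
    if expected_n is not None:
        if idx.size < expected_n:
            raise DetectionError(
                f"found {idx.size} lanes, expected {expected_n}"
            )
        if idx.size > expected_n:
            order = np.lexsort((idx, -prom))[:expected_n]
            sel = np.zeros(idx.size, dtype=bool)
            sel[order] = True
            idx, heights, prom = idx[sel], heights[sel], prom[sel]
    centers = np.array([refine_subpixel(v, i) for i in idx])
    order = np.argsort(centers)
    centers = centers[order]
    if centers.size == 1:
        half_width = float(min_separation_cols)
    else:
        gaps = np.diff(centers)
        half_width = float(min(np.median(gaps), gaps.min()) / 2.0)
    return [
        Lane(lane_id=i, center_col=float(c), half_width=half_width)
        for i, c in enumerate(centers)
    ]


# ---------------------------------------------------------------------------
# bands from peaks, manual edits
# ---------------------------------------------------------------------------

def measure_band_area(profile: IntensityProfile, position_row: float,
                      half_window_rows: int = 4) -> float:
    """Integrated profile intensity in a fixed window around a band.

    A fixed +/- window (default the band minimum-spacing radius) keeps
    area measurements comparable across bands; on a background-subtracted
    profile the window sum approximates the band's integrated signal.
    """
    v = profile.values
    c = int(round(position_row))
    lo = max(c - half_window_rows, 0)
    hi = min(c + half_window_rows + 1, v.size)
    return float(v[lo:hi].sum())


def bands_from_peaks(peaks: list[PeakCall], lane_id: int,
                     profile: IntensityProfile,
                     area_half_window_rows: int = 4) -> list[Band]:
    """Convert peak calls in a lane profile into Band records."""
    return [
        Band(lane_id=lane_id, position_row=p.position,
             peak_intensity=p.height, prominence=p.prominence,
             area=measure_band_area(profile, p.position, area_half_window_rows),
             origin="auto")
        for p in peaks
    ]


def apply_edits(bands: list[Band], edits: EditSet,
                profile: IntensityProfile,
                min_distance_rows: int = 4,
                area_half_window_rows: int = 4) -> list[Band]:
    """Apply manual add/remove edits to one lane's band list.

    ``remove`` deletes every band within ``tolerance_rows`` of the stated
    row (an edit matching nothing is an error — re-applying a successful
    removal therefore errors, which makes silent double-application
    impossible).  ``add`` inserts a band at the stated row with
    ``origin="manual"`` and height/area measured from the profile; adding
    within ``min_distance_rows`` of an existing band is a collision error.
    The result is re-sorted by position.
    """
    if not edits.edits:
        return list(bands)
    lane_ids = {b.lane_id for b in bands}
    out = list(bands)
    for edit in edits.edits:
        if lane_ids and edit.lane_id not in lane_ids and edit.action == "remove":
            raise EditError(
                f"edit references lane {edit.lane_id}, not present in band set"
            )
        if edit.action == "remove":
            survivors = [
                b for b in out
                if not (b.lane_id == edit.lane_id
                        and abs(b.position_row - edit.position_row)
                        <= edit.tolerance_rows)
            ]
            if len(survivors) == len(out):
                raise EditError(
                    f"remove at row {edit.position_row} +/- "
                    f"{edit.tolerance_rows} (lane {edit.lane_id}) matches no band"
                )
            out = survivors
        else:  # add
            v = profile.values
            if not (0 <= edit.position_row < v.size):
                raise EditError(
                    f"add at row {edit.position_row} outside profile "
                    f"[0, {v.size})"
                )
            for b in out:
                if (b.lane_id == edit.lane_id
                        and abs(b.position_row - edit.position_row)
                        < min_distance_rows):
                    raise EditError(
                        f"add at row {edit.position_row} collides with "
                        f"existing band at {b.position_row}"
                    )
            height = float(v[int(round(edit.position_row))])
            out.append(Band(
                lane_id=edit.lane_id, position_row=float(edit.position_row),
                peak_intensity=height, prominence=height,
                area=measure_band_area(profile, edit.position_row,
                                       area_half_window_rows),
                origin="manual",
            ))
            lane_ids.add(edit.lane_id)
    out.sort(key=lambda b: (b.lane_id, b.position_row))
    return out
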