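"""Domain types and file I/O for gel quantification.

This module owns every external artifact the tool touches — gel scans
(TIFF/PNG), ladder specification tables, band tables, manual-edit scripts
and pedigree tables — and the shared dataclasses the rest of the package
operates on.

Conventions
-----------
* Images follow a fixed orientation: row 0 is the well edge (top) and the
  row index increases with migration distance; columns run left to right.
  Orientation is a documented input contract, not auto-detected.
* Polarity is normalized on load so that higher pixel value = more band
  signal (bands bright on dark background).
* All coordinates are 0-based; positions are sub-pixel floats; intervals
  are half-open ``[start, end)``.
* CSV is the canonical tabular dialect: comma separator, ``.`` decimal,
  UTF-8, header row required.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BandTableError,
    DegenerateImageError,
    EditError,
    LadderSpecError,
    PedigreeError,
    UnsupportedImageError,
)

MIN_IMAGE_DIM = 16

GENOTYPES = ("wild-type", "carrier", "affected", "unknown")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GelImage:
    """A gel scan as a non-negative float intensity matrix.

    Parameters
    ----------
    pixels
        2-D float array, higher value = more band signal.
    bit_depth
        Bit depth of the source file (8 or 16); retained so images can be
        written back on the same scale.
    provenance
        Free-text note on where the image came from (file path, simulator
        preset, processing step).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DegenerateImageError(
                f"gel image must be 2-D, got shape {px.shape}"
            )
        if px.shape[0] < MIN_IMAGE_DIM or px.shape[1] < MIN_IMAGE_DIM:
            raise DegenerateImageError(
                f"gel image {px.shape[0]}x{px.shape[1]} is smaller than the "
                f"{MIN_IMAGE_DIM}x{MIN_IMAGE_DIM} minimum"
            )
        if not np.all(np.isfinite(px)):
            raise DegenerateImageError("gel image contains non-finite pixels")
        if np.any(px < 0):
            raise DegenerateImageError("gel image contains negative pixels")
        if self.bit_depth not in (8, 16):
            raise UnsupportedImageError(
                f"bit depth {self.bit_depth} not supported (8 or 16)"
            )
        self.pixels = px

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray, note: str = "") -> "GelImage":
        prov = self.provenance + (f" | {note}" if note else "")
        return GelImage(pixels=pixels, bit_depth=self.bit_depth, provenance=prov)


@dataclass(frozen=True)
class Lane:
    """A detected lane: sub-pixel center column and half-width window."""

    lane_id: int
    center_col: float
    half_width: float
    role: str = "sample"  # "sample" | "ladder"

    def __post_init__(self) -> None:
        if self.lane_id < 0:
            raise ValueError("lane_id must be >= 0")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.role not in ("sample", "ladder"):
            raise ValueError(f"unknown lane role {self.role!r}")


@dataclass(frozen=True)
class Band:
    """A called band in one lane.

    ``position_row`` is the sub-pixel migration distance in rows;
    ``size_kb`` stays ``None`` until ladder calibration assigns it.
    """

    lane_id: int
    position_row: float
    peak_intensity: float
    prominence: float
    area: float
    size_kb: float | None = None
    origin: str = "auto"  # "auto" | "manual"

    def __post_init__(self) -> None:
        if self.position_row < 0:
            raise ValueError("position_row must be >= 0")
        if self.peak_intensity < 0 or self.prominence < 0 or self.area < 0:
            raise ValueError("band intensities must be >= 0")
        if self.size_kb is not None:
            if not math.isfinite(self.size_kb) or self.size_kb <= 0:
                raise ValueError("size_kb must be finite and > 0 when set")
        if self.origin not in ("auto", "manual"):
            raise ValueError(f"unknown band origin {self.origin!r}")


@dataclass(frozen=True)
class Edit:
    """One manual adjustment: add a band at a row, or remove bands near one."""

    action: str  # "add" | "remove"
    lane_id: int
    position_row: float
    tolerance_rows: float = 0.0

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise EditError(f"unknown edit action {self.action!r}")
        if self.action == "remove" and self.tolerance_rows <= 0:
            raise EditError("remove edits need tolerance_rows > 0")


@dataclass(frozen=True)
class EditSet:
    edits: tuple[Edit, ...] = ()

    def for_lane(self, lane_id: int) -> list[Edit]:
        return [e for e in self.edits if e.lane_id == lane_id]

    @property
    def lane_ids(self) -> set[int]:
        return {e.lane_id for e in self.edits}


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: generation, age, measured telomere length (kb)."""

    individual_id: str
    generation: int
    age_years: float
    measured_tl_kb: float
    genotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.generation < 1:
            raise PedigreeError(
                f"{self.individual_id}: generation must be >= 1"
            )
        if not (0 <= self.age_years <= 130):
            raise PedigreeError(
                f"{self.individual_id}: age {self.age_years} outside [0, 130]"
            )
        if not (0.5 < self.measured_tl_kb < 25):
            raise PedigreeError(
                f"{self.individual_id}: telomere length {self.measured_tl_kb} "
                "outside (0.5, 25) kb — check units (kb expected, not bp)"
            )
        if self.genotype not in GENOTYPES:
            raise PedigreeError(
                f"{self.individual_id}: unknown genotype {self.genotype!r}"
            )


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _load_raw(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    if ext == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    raise UnsupportedImageError(f"unsupported image format {ext!r} (TIFF or PNG)")


def read_gel_image(path: str, invert: bool | str = "auto",
                   rotate: int = 0) -> GelImage:
    """Load a gel scan and normalize its polarity.

    Parameters
    ----------
    path
        An existing 8- or 16-bit single-channel TIFF or PNG.  RGB inputs
        are collapsed to grayscale by the unweighted channel mean (gel
        scanners emit near-gray RGB; any weighting would be arbitrary).
    invert
        ``"auto"`` flips dark-bands-on-light scans (detected when the
        image median sits above the midrange of the pixel values);
        ``True``/``False`` force the choice.
    rotate
        Number of clockwise 90-degree turns to apply first, for scans not
        stored wells-at-top.

    Returns
    -------
    GelImage
        Bright-bands-on-dark float image obeying all invariants.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"gel image not found: {path}")
    raw = _load_raw(path)
    if raw.ndim == 3:
        if raw.shape[2] in (3, 4):
            raw = raw[:, :, :3].mean(axis=2)
        else:
            raise UnsupportedImageError(
                f"cannot interpret image with shape {raw.shape}"
            )
    if raw.ndim != 2:
        raise UnsupportedImageError(f"expected 2-D image, got shape {raw.shape}")

    kind = np.asarray(raw).dtype
    if kind == np.uint8:
        bit_depth, full_scale = 8, 255.0
    elif kind == np.uint16:
        bit_depth, full_scale = 16, 65535.0
    elif np.issubdtype(kind, np.floating):
        # RGB mean of 8/16-bit channels comes back float; infer the scale.
        full_scale = 255.0 if np.nanmax(raw) <= 255.0 else 65535.0
        bit_depth = 8 if full_scale == 255.0 else 16
    else:
        raise UnsupportedImageError(f"unsupported pixel dtype {kind}")

    px = raw.astype(float)
    if px.shape[0] < MIN_IMAGE_DIM or px.shape[1] < MIN_IMAGE_DIM:
        raise DegenerateImageError(
            f"image {px.shape[0]}x{px.shape[1]} smaller than "
            f"{MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}"
        )
    if rotate % 4:
        px = np.rot90(px, k=-(rotate % 4))

    if invert == "auto":
        # Bands occupy a small pixel fraction, so the median tracks the
        # background: a median above the midrange means a light background
        # with dark bands, i.e. the scan needs inverting.
        do_invert = bool(np.median(px) > (px.min() + px.max()) / 2.0)
    else:
        do_invert = bool(invert)
    if do_invert:
        px = full_scale - px
    px = np.clip(px, 0.0, None)
    return GelImage(pixels=px, bit_depth=bit_depth, provenance=str(path))


def write_gel_image(image: GelImage, path: str) -> None:
    """Write a GelImage to TIFF or PNG at its recorded bit depth."""
    full = 255 if image.bit_depth == 8 else 65535
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    px = np.clip(np.rint(image.pixels), 0, full).astype(dtype)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, px)
    elif ext == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, px)
    else:
        raise UnsupportedImageError(f"unsupported output format {ext!r}")


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_ladder_spec(path: str) -> list[float]:
    """Read a ladder CSV (one ``size_kb`` column) and return sizes in
    descending order — the largest fragment migrates least.

    At least 3 distinct positive sizes are required; with fewer, a
    piecewise calibration cannot be anchored.
    """
    df = pd.read_csv(path)
    if "size_kb" not in df.columns:
        raise LadderSpecError("ladder CSV must have a 'size_kb' column")
    sizes = df["size_kb"].astype(float).tolist()
    if any(not math.isfinite(s) or s <= 0 for s in sizes):
        raise LadderSpecError("ladder sizes must all be finite and > 0")
    if len(set(sizes)) != len(sizes):
        raise LadderSpecError("ladder sizes must be distinct")
    if len(sizes) < 3:
        raise LadderSpecError(
            f"need >= 3 ladder sizes for calibration, got {len(sizes)}"
        )
    return sorted(sizes, reverse=True)


_BAND_COLUMNS = ["lane_id", "position_row", "peak_intensity", "prominence",
                 "area", "size_kb", "origin"]


def write_band_table(bands: Sequence[Band], path: str) -> None:
    """Write bands to CSV; round-trips losslessly (full float precision).

    Unset ``size_kb`` is written as an empty cell.
    """
    rows = [
        {
            "lane_id": b.lane_id,
            "position_row": b.position_row,
            "peak_intensity": b.peak_intensity,
            "prominence": b.prominence,
            "area": b.area,
            "size_kb": np.nan if b.size_kb is None else b.size_kb,
            "origin": b.origin,
        }
        for b in bands
    ]
    df = pd.DataFrame(rows, columns=_BAND_COLUMNS)
    df.to_csv(path, index=False)


def read_band_table(path: str) -> list[Band]:
    df = pd.read_csv(path)
    missing = [c for c in _BAND_COLUMNS if c not in df.columns]
    if missing:
        raise BandTableError(f"band CSV missing columns: {missing}")
    bands = []
    for i, row in df.iterrows():
        size = row["size_kb"]
        try:
            bands.append(Band(
                lane_id=int(row["lane_id"]),
                position_row=float(row["position_row"]),
                peak_intensity=float(row["peak_intensity"]),
                prominence=float(row["prominence"]),
                area=float(row["area"]),
                size_kb=None if pd.isna(size) else float(size),
                origin=str(row["origin"]),
            ))
        except ValueError as exc:
            raise BandTableError(f"band CSV row {i + 2}: {exc}") from exc
    return bands


def read_edits(path: str) -> EditSet:
    """Read a manual-edit CSV: columns action, lane_id, position_row,
    tolerance_rows (tolerance may be blank for adds)."""
    df = pd.read_csv(path)
    needed = ["action", "lane_id", "position_row"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise EditError(f"edits CSV missing columns: {missing}")
    edits = []
    for i, row in df.iterrows():
        tol = row.get("tolerance_rows", 0.0)
        edits.append(Edit(
            action=str(row["action"]).strip().lower(),
            lane_id=int(row["lane_id"]),
            position_row=float(row["position_row"]),
            tolerance_rows=0.0 if pd.isna(tol) else float(tol),
        ))
    return EditSet(edits=tuple(edits))


_ROMAN = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100}


def parse_generation(value) -> int:
    """Parse a generation given as an integer or a Roman numeral (I–C)."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, float) and float(value).is_integer():
        return int(value)
    text = str(value).strip().upper()
    if text.isdigit():
        return int(text)
    if text and all(ch in _ROMAN for ch in text):
        total, prev = 0, 0
        for ch in reversed(text):
            v = _ROMAN[ch]
            total += v if v >= prev else -v
            prev = max(prev, v)
        if total >= 1:
            return total
    raise PedigreeError(f"cannot parse generation {value!r}")


def read_pedigree(path: str) -> list[PedigreeRecord]:
    """Read a pedigree CSV into records; generation accepts Roman numerals.

    Invariant violations (age > 130, TL outside (0.5, 25) kb — almost
    always a bp-vs-kb unit slip) are reported with their CSV row number.
    """
    df = pd.read_csv(path)
    needed = ["individual_id", "generation", "age_years", "measured_tl_kb"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        genotype = row.get("genotype", "unknown")
        if pd.isna(genotype):
            genotype = "unknown"
        try:
            records.append(PedigreeRecord(
                individual_id=str(row["individual_id"]),
                generation=parse_generation(row["generation"]),
                age_years=float(row["age_years"]),
                measured_tl_kb=float(row["measured_tl_kb"]),
                genotype=str(genotype).strip().lower(),
            ))
        except PedigreeError as exc:
            raise PedigreeError(f"pedigree CSV row {i + 2}: {exc}") from exc
    return records


def read_links(path: str) -> list[tuple[str, str]]:
    """Read a parent-child link CSV (columns parent_id, child_id)."""
    df = pd.read_csv(path)
    for c in ("parent_id", "child_id"):
        if c not in df.columns:
            raise PedigreeError(f"links CSV missing column {c!r}")
    return [(str(p), str(c)) for p, c in zip(df["parent_id"], df["child_id"])]
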