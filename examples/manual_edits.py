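"""Correct automatic band calls with a declarative edit script.

Automatic calling can produce false positives/negatives; edits are
add/remove instructions that are re-applied deterministically on every
run instead of mutating state interactively.
"""

import numpy as np

from gelquant import Edit, EditSet, apply_edits, detect_bands
from gelquant.detect import IntensityProfile, bands_from_peaks

rows = np.arange(300, dtype=float)
profile = IntensityProfile(
    values=(120 * np.exp(-((rows - 60) ** 2) / 8)
            + 18 * np.exp(-((rows - 140) ** 2) / 8)   # faint true band
            + 90 * np.exp(-((rows - 220) ** 2) / 8)),
    axis="migration",
)

peaks = detect_bands(profile, min_prominence=30.0)
bands = bands_from_peaks(peaks, lane_id=1, profile=profile)
print("auto calls:", [round(b.position_row, 1) for b in bands])

edits = EditSet(edits=(
    Edit("add", lane_id=1, position_row=140.0),          # rescue the faint band
    Edit("remove", lane_id=1, position_row=220.0, tolerance_rows=3.0),
))
edited = apply_edits(bands, edits, profile)
print("after edits:", [(round(b.position_row, 1), b.origin) for b in edited])
# manual additions keep origin="manual" so reports show which calls a
# human vouched for.
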