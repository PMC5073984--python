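"""TRF-style smear mean length from a continuous lane profile.

Terminal restriction fragment (TRF) blots give a smear rather than
discrete bands; the standard densitometric estimator is
sum(OD_i) / sum(OD_i / L_i) over the smear rows.
"""

import numpy as np

from gelquant import fit_ladder, smear_mean_length
from gelquant.detect import IntensityProfile, PeakCall

cal = fit_ladder(
    [PeakCall(position=p, height=1.0, prominence=1.0)
     for p in (0.0, 120.0, 240.0, 360.0)],
    [10.0, 5.0, 2.5, 1.25],  # log-linear: halves every 120 rows
)

rows = np.arange(400, dtype=float)
smear = np.exp(-((rows - 150.0) ** 2) / (2 * 40.0**2))  # broad smear
profile = IntensityProfile(values=1000.0 * smear, axis="migration")

mean_kb = smear_mean_length(profile, cal, row_range=(20, 380))
print(f"smear mean length: {mean_kb:.3f} kb")
# the OD-weighted harmonic-style mean is the bulk telomere length a TRF
# densitometry readout reports; short fragments pull it down strongly.
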