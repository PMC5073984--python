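"""Fit a ladder calibration and convert migration distances to sizes.

DNA migrates log-linearly in fragment size, so the calibration
interpolates log10(kb) between the ladder knots.
"""

from gelquant import fit_ladder, size_at
from gelquant.detect import PeakCall

# ladder band positions (rows) called from the ladder lane, and the
# known fragment sizes loaded in that lane (kb, largest migrates least)
positions = [38.6, 88.6, 159.1, 209.1, 279.6, 329.6, 400.0, 520.4]
sizes_kb = [8.0, 6.0, 4.0, 3.0, 2.0, 1.5, 1.0, 0.5]

cal = fit_ladder([PeakCall(position=p, height=1.0, prominence=1.0)
                  for p in positions], sizes_kb)
print(f"global log-linear R^2 = {cal.fit_r2:.5f} (QC: ~1 means the gel "
      "ran log-linearly)")

for row in (38.6, 100.0, 250.0, 450.0):
    print(f"row {row:6.1f} -> {size_at(cal, row):6.3f} kb")
# a band's migration row maps through the calibration to its length;
# a 1.6 kb threshold row can be found the same way for short-telomere calls.
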