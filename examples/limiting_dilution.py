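"""Estimate a repopulating-cell frequency from a limiting-dilution assay.

Transplants at graded cell doses either produce an outgrowth or not; under
the single-hit model each transplant succeeds iff it received at least one
active cell, so Pr(outgrowth | dose d) = 1 - exp(-f d).  The maximum-
likelihood f is reported in the conventional "1 cell in N" form with a
95% likelihood-ratio confidence interval.
"""

import pandas as pd

import hairpinscreen as hs

assay = pd.DataFrame({
    "dose":     [10, 50, 250],   # cells per transplant
    "n":        [10, 10, 10],    # transplants performed
    "positive": [1, 4, 9],       # outgrowths observed
})

fit = hs.limiting_dilution_frequency(assay)
print(assay.to_string(index=False))
print(f"\nactive-cell frequency: 1 in {fit.frequency:.0f}")
print(f"95% CI               : 1 in {fit.frequency_lower:.0f} "
      f"to 1 in {fit.frequency_upper:.0f}")
# Around 1 in 100 transplanted cells can regenerate an outgrowth; the CI
# spans the frequencies whose likelihood is within the chi-square cutoff
# of the maximum.
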