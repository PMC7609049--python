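"""Subpopulation-specific toxicity: dopaminergic neurons vs all neurons.

A dose series (0-500 µM) is generated in which the toxin ablates only
TH+ cells (EC50 100 µM planted); both TH and Map2 readouts are
area-normalized, normalized to vehicle control, and fitted with a
four-parameter logistic.
"""

import numpy as np

from orgscreen.dose_response import specificity_profile
from orgscreen.pipeline import run_toxicity_assay

assay = run_toxicity_assay(seed=17, replicates=3)
series = assay["series"]

print("dose (µM)   TH survival   Map2 survival")
for dose, th, map2 in zip(series.doses, series.means("TH"), series.means("Map2")):
    print(f"{dose:9.0f}   {th:11.3f}   {map2:13.3f}")

fit = assay["fits"]["TH"]
print(f"\n4PL fit (TH): top={fit['top']:.2f} bottom={fit['bottom']:.2f} "
      f"EC50={fit['ec50']:.0f} µM hill={fit['hill_slope']:.2f} "
      f"R²={fit['r_squared']:.3f}")

profile = specificity_profile(series, "TH", "Map2")
print("TH/Map2 specificity ratio by dose:",
      np.round(profile["ratio"].to_numpy(), 2))

print("""
TH survival falls with dose while Map2 stays near 1: the toxin is
specific for the dopaminergic subpopulation.  The recovered EC50 close
to the planted 100 µM shows the imaging pipeline preserves the
dose-response shape, and the falling TH/Map2 ratio is the
subpopulation-specificity signature.""")
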