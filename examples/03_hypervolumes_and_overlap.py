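"""Fit per-period niche hypervolumes and measure their pairwise overlap.

Each cumulative period's records are transformed into PC space and enclosed
by a one-class SVM (RBF kernel, gamma = 0.5, nu = 0.01); volume, centroid
and per-axis extent come from Monte-Carlo integration.  Jaccard and Sorensen
similarities between periods are estimated from one shared uniform sample,
so S = 2J/(1+J) holds exactly.
"""

import numpy as np

from hyperniche import cumulative_subsets, extract_values, fit_hypervolume, transform
from hyperniche.overlap import matrix_to_frame, overlap_matrix
from hyperniche.pipeline import analyze
from hyperniche.synthetic import SyntheticScenario, generate_climate, sample_occurrences

scn = SyntheticScenario(seed=1)
stack = generate_climate(scn)
occ = sample_occurrences(scn)
res = analyze(occ, stack, scn.slicing, mc_draws=20_000, overlap_draws=50_000,
              seed=1, with_tss=False)

print("per-period hypervolumes (PC-space volume, centroid of the MC inlier cloud):")
for hv in res["hypervolumes"]:
    c = ", ".join(f"{x:+.2f}" for x in hv.centroid)
    print(f"  {hv.label:>9}: volume {hv.volume:8.2f} ± {hv.volume_se:.2f}  centroid ({c})")

frame = matrix_to_frame(res["jaccard"], res["sorensen"], res["labels"])
print("\noverlap matrix (Jaccard above the diagonal, Sorensen below):")
print(frame.round(3).to_string())

print("\nOverlap decays as the compared periods grow farther apart in time —")
print("later hypervolumes cover PC-space that early ones never reached,")
print("which is the signature of a realized-niche expansion.")
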