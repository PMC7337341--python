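"""Mask the climate stack with the occurrence envelope and fit the PC space.

The envelope (an axis-aligned min-max box over all 19 variables, trained on
the full record set) removes cells whose climate the species has never been
seen in, shrinking the projection space.  A correlation-matrix PCA of the
surviving cells then gives the orthogonal predictor space in which the
niche hypervolumes are delineated; components with eigenvalue > 1 are kept.
"""

from hyperniche import apply_envelope_mask, extract_values, fit_envelope, fit_pca
from hyperniche.synthetic import SyntheticScenario, generate_climate, sample_occurrences

scn = SyntheticScenario(seed=1)
stack = generate_climate(scn)
occ = sample_occurrences(scn)

values, kept, dropped = extract_values(occ, stack)
box = fit_envelope(values, stack.names)
masked = apply_envelope_mask(stack, box)
print(f"envelope mask: {stack.n_valid} land cells -> {masked.n_valid} inside the box")

space = fit_pca(masked.values_table()[0], tuple(stack.names))
print(f"correlation PCA: eigenvalue sum = {space.eigenvalues.sum():.6f} (= K = {space.k})")
print(f"retained components (eigenvalue > 1): m = {space.m}\n")
print(space.summary().round(3).to_string())
print("\nLoadings are Pearson correlations between each variable and each")
print("retained component; explained variance is eigenvalue / K.")
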