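"""Selection gradients, constraint angles and residue rankings.

Simulates landmark-shaped data (30 residues = 90 traits), decomposes the
covariance, takes the most distant pair of homolog mean shapes as the
selection target and source, and runs the breeder's-equation machinery:
realized response, long-term gradient on the genetic proxy G and on the
dynamic matrix M, constraint angles, and the per-residue ranking tables.
"""

import numpy as np

from protqg import analyze_selection, decompose, realized_response, simulate_dataset

data = simulate_dataset(n_traits=90, n_taxa=25, n_replicates=40, seed=11)
dec = decompose(data.phenotypes)

labels, means = data.phenotypes.group_means()
dists = np.linalg.norm(means[:, None] - means[None], axis=-1)
i, j = np.unravel_index(np.argmax(dists), dists.shape)
print(f"target homolog: {labels[i]}   source homolog: {labels[j]}")

delta_z = realized_response(means[i], means[j])
genetic = analyze_selection(dec.between, delta_z, "G", top=3)
dynamic = analyze_selection(dec.within, delta_z, "M", top=3)

print(f"\n|delta_z| = {np.linalg.norm(delta_z):.3f} (realized response, target - source)")
for a in (genetic, dynamic):
    print(
        f"{a.matrix_used}: theta(dz, beta) = {a.theta_dz_beta:6.2f} deg, "
        f"theta(dz, 99% subspace) = {a.theta_dz_subspace:6.2f} deg"
    )

print("\ntop residues under directional selection (on G):")
print(genetic.directional.to_string(index=False, float_format="%.3f"))
print("\ntop residues under purifying selection (on G):")
print(genetic.purifying.to_string(index=False, float_format="%.3f"))

print(
    "\nA small theta(dz, beta) means the realized response is nearly"
    "\nparallel to the gradient: selection toward the target is barely"
    "\nconstrained by trait covariation.  The tables rank residues by the"
    "\nsummed gradient components, the coarse map used to nominate"
    "\nengineering candidates."
)
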