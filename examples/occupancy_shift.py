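"""Occupancy modelling: detect a dorsoventral shift between two groups.

Generates two synthetic cell populations whose true occupancy grids are
offset by exactly one DV bin, bins the coordinates onto the 15 x 4 grid,
samples the Dirichlet posterior for each group, and summarises the
difference by KL divergence, axis shifts, and the multivariate KS test.
"""

import numpy as np

from neurotopo import occupancy as occ
from neurotopo import synthetic
from neurotopo.pipeline import _base_grid

base = _base_grid(15, 4)
shifted = synthetic.shift_grid(base, dz=-1)  # perturbed group sits 1 bin ventral

grids = {}
binned = {}
for name, probs, n_larvae, seed in (("wildtype", base, 19, 1),
                                    ("perturbed", shifted, 22, 2)):
    truth = synthetic.SyntheticTruth(probs, n_larvae=n_larvae,
                                     cells_per_larva=(20, 60), seed=seed)
    cells = synthetic.gen_occupancy_dataset(truth, genotype=name)
    b = occ.assign_bins(cells, z_extent=synthetic.DV_EXTENT_UM,
                        x_extent=synthetic.ML_EXTENT_UM)
    binned[name] = b
    grids[name] = occ.pool_counts(b)
    print(f"{name}: {grids[name].n_cells} cells, {n_larvae} larvae")

post = {name: occ.posterior_sample(g, n_samples=20_000, seed=i)
        for i, (name, g) in enumerate(grids.items())}

kl = occ.kl_posterior(post["wildtype"], post["perturbed"])
z = occ.axis_shift(post["wildtype"], post["perturbed"], "DV")
x = occ.axis_shift(post["wildtype"], post["perturbed"], "ML")
print(f"KL_mean = {kl.kl_mean:.4f}, 95% CI [{kl.kl_ci_low:.4f}, {kl.kl_ci_high:.4f}]")
print(f"z-shift = {z.shift_mean:.4f}, 95% CI [{z.ci_low:.4f}, {z.ci_high:.4f}]")
print(f"x-shift = {x.shift_mean:.4f}, 95% CI [{x.ci_low:.4f}, {x.ci_high:.4f}]")
# z-shift ~ +1: the wildtype-like group sits one DV bin dorsal of the
# perturbed group, recovering the shift built into the generator; the
# x-shift CI straddles 0 because no ML shift was simulated.

pts = {k: v[["z_bin", "x_bin"]].to_numpy(float) for k, v in binned.items()}
ks = occ.mks_test(pts["wildtype"], pts["perturbed"], n_perm=999, seed=0)
print(f"multivariate KS: k = {ks['k']:.4f}, p = {ks['p']:.4f}")

report = occ.convergence_check(grids["wildtype"], grids["perturbed"], seed=0)
print("KL stability over sample sizes:",
      np.round(report["kl_means"], 4), "converged at", report["converged_at"])
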