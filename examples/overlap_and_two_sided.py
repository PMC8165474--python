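"""Panel-overlap and add/remove variants of the exact attack.

First: two studies that share only 150 of their 200 SNPs — restricting the
normal-equation products to the shared rows recovers the added individual's
shared-SNP genotype exactly.  Second: each study contains one individual the
other lacks — the difference reduces to a two-individual problem whose
constants carry opposite-signed residuals.
"""

import numpy as np

from grsleak import (
    GenotypeMatrix, PhenotypeVector, SimConfig, accuracy, assign_genotypes,
    build_K, fit_grs, identify_Cm_simple, make_split, reconstruct_single,
    restrict_to_overlap, symmetric_difference_d,
)

# --- overlapping SNP panels ------------------------------------------------
cfg = SimConfig(seed=6000, n_added=0, n_private=800, n_snps=250, n_public=10, n_test=5)
split = make_split(cfg)
panel1 = split.private_base.snp_ids[:200]        # first study's SNPs
panel2 = split.private_base.snp_ids[50:250]      # second study's SNPs (150 shared)
G1 = split.private_base.select_snps(panel1)
old = fit_grs(G1, split.private_phenotypes)
G_add = split.test_pool.take([0])
joint = GenotypeMatrix(
    np.vstack([split.private_base.select_snps(panel2).values,
               G_add.select_snps(panel2).values]),
    panel2, split.private_base.individual_ids + G_add.individual_ids, "binary")
y2 = PhenotypeVector(
    np.concatenate([split.private_phenotypes.values,
                    split.test_phenotypes.take([0]).values]),
    "trait", joint.individual_ids)
new = fit_grs(joint, y2)

d = restrict_to_overlap(old, new, build_K(G1),
                        build_K(split.private_base.select_snps(panel2)))
result = reconstruct_single(d)
acc = accuracy(result.genotypes, G_add.select_snps(d.snp_ids))
print(f"overlap attack: {len(d.snp_ids)} shared SNPs recovered at {acc:.1%}")

# --- one added, one removed ------------------------------------------------
def with_extra(split, row):
    G_x = split.test_pool.take([row])
    joint = GenotypeMatrix(
        np.vstack([split.private_base.values, G_x.values]),
        list(split.private_base.snp_ids),
        split.private_base.individual_ids + G_x.individual_ids, "binary")
    y = PhenotypeVector(
        np.concatenate([split.private_phenotypes.values,
                        split.test_phenotypes.take([row]).values]),
        "trait", joint.individual_ids)
    return fit_grs(joint, y), G_x

cfg2 = SimConfig(seed=6100, n_added=0, n_private=600, n_snps=100, n_public=10, n_test=5)
sp = make_split(cfg2)
rel_A, G_a = with_extra(sp, 0)   # study A: core + individual a
rel_B, G_b = with_extra(sp, 1)   # study B: core + individual b
d2 = symmetric_difference_d(build_K(sp.private_base), rel_A, rel_B, a=1, b=1)
sol = identify_Cm_simple(d2, 2)
res = assign_genotypes(d2, sol)
acc2 = accuracy(res.genotypes.values, np.vstack([G_a.values, G_b.values]))
print(f"two-sided attack: both genotypes recovered at {acc2:.1%}, "
      f"C = {np.round(sol.C_values, 6)}")
# One constant is the +residual of study A's extra individual, the other the
# negated residual of study B's; the attack treats them as one m=2 problem.
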