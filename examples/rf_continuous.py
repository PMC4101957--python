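"""Random-forest gene set test for a continuous phenotype, with importance.

A quantitative outcome driven by three genes of one set; the RF regression
test scores each set by its out-of-bag mean squared error and permutes the
phenotype for significance.  Importance tables rank the genes inside the
significant set.
"""

import numpy as np

import permgsa as pg

rng = np.random.default_rng(11)
n_samples = 40
y = rng.normal(size=n_samples)
values = rng.normal(size=(15, n_samples))
values[0] = y + rng.normal(0, 0.3, n_samples)
values[1] = -y + rng.normal(0, 0.5, n_samples)
values[2] = y + rng.normal(0, 0.8, n_samples)

data = pg.ExpressionDataset(
    values,
    gene_ids=[f"g{i}" for i in range(15)],
    sample_ids=[f"s{i}" for i in range(n_samples)],
    phenotype=pg.Phenotype("continuous", y),
)
membership = np.zeros((15, 2), dtype=int)
membership[:5, 0] = 1   # contains the three associated genes
membership[5:15, 1] = 1
sets = pg.GeneSetCollection(["associated", "noise"], membership)

config = pg.RFConfig(n_trees=500, nb_perm=500, importance=True, seed=9)
result = pg.run_rf_gsa(data, sets, config)
print(result.table.round(4).to_string(index=False))
for name, table in result.importance.items():
    print(f"\nimportance for significant set {name!r} (mean increase in OOB MSE):")
    print(table.round(4).to_string(index=False))

# oob_score is the out-of-bag MSE of a forest predicting y from the set's
# genes; pvalue = fraction of phenotype permutations whose score is at most
# the observed one.  The 'associated' set should be significant with g0-g2
# leading its importance ranking; the 'noise' set should not.
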