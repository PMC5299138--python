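"""Gene-level targeting-shift statistic with a permutation null.

Builds a small gene x family incidence table, declares observed up- and
down-regulated family sets, and compares each gene's targeting change
delta = (#up families hitting it) - (#down families hitting it) against
random re-labellings of the family universe.  On this small universe the
exact enumeration oracle is feasible and shown next to the Monte-Carlo
estimate.
"""

from mirshift.io_formats import TargetIncidenceTable
from mirshift.targeting import (
    ShiftConfig,
    exact_pvalues_small,
    permutation_pvalues,
    rank_genes,
    TargetingShiftResult,
)

families = [f"fam{j}" for j in range(8)]
up = {"fam0", "fam1", "fam2"}
down = {"fam7"}
table = TargetIncidenceTable(
    {
        "stacked": {"fam0": 1, "fam1": 2, "fam2": 1},  # hit by every up family
        "mixed": {"fam0": 1, "fam7": 3},               # one up, one down
        "untouched": {"fam5": 1},                      # neither stratum
    }
)

config = ShiftConfig(n_up=3, n_down=1, iterations=100_000, rng_seed=1)
perm = permutation_pvalues(table, families, up, down, config)
exact = exact_pvalues_small(table, families, up, down, config)

print("gene       delta   p(permutation)   p(exact enumeration)")
for gene, (delta, p) in perm.items():
    print(f"{gene:<10} {delta:>4}   {p:>12.5f}   {exact[gene]:>12.5f}")

results = rank_genes(
    TargetingShiftResult(g, d, p, config.iterations)
    for g, (d, p) in perm.items()
)
print("\nranking (ascending p, ties by descending delta):")
for r in results:
    print(f"  rank {r.rank}: {r.gene_id} (delta {r.delta}, p {r.p_value:.4f})")
print(
    "\nA small p marks a gene whose 3'UTR is hit by more upregulated "
    "families than random family sets of the same sizes would achieve."
)
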