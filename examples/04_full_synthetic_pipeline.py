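"""Full pipeline on a synthetic study with known ground truth.

Simulates a two-timepoint small-RNA study (expression profile, family
map, target incidence with planted enriched genes, FPKMs), runs the
differential gates, derives the up/down family strata and scores every
gene with the permutation test — then checks what the pipeline
recovered against the planted truth.
"""

import numpy as np

from mirshift.diffexp import (
    DiffExpConfig,
    classify_differential,
    restrict_to_conserved,
    unique_family_sets,
)
from mirshift.synthetic_data import SyntheticConfig, simulate_study
from mirshift.targeting import ShiftConfig, run_targeting_shift

config = SyntheticConfig(seed=1)
dataset = simulate_study(config, with_reads=False)

records = restrict_to_conserved(
    classify_differential(dataset.profile, DiffExpConfig()), dataset.annotation
)
called_up = {r.mirna_id for r in records if r.direction == "up"}
called_down = {r.mirna_id for r in records if r.direction == "down"}
truth_up, truth_down = set(dataset.truth.spiked_up), set(dataset.truth.spiked_down)
print(
    f"spiked miRNAs recovered: {len(called_up & truth_up)}/{len(truth_up)} up, "
    f"{len(called_down & truth_down)}/{len(truth_down)} down "
    f"({len((called_up | called_down) - truth_up - truth_down)} extra calls from "
    "RPM-renormalization compression of the background)"
)

up_families, down_families = unique_family_sets(records)
results = run_targeting_shift(
    dataset.targets,
    dataset.annotation.universe,
    up_families,
    down_families,
    ShiftConfig(
        n_up=len(up_families), n_down=len(down_families),
        iterations=10_000, rng_seed=1, p_estimator="add_one",
    ),
    dataset.fpkm,
)
ranks = {r.gene_id: r.rank for r in results}
planted = sorted(ranks[g] for g in dataset.truth.enriched_genes if g in ranks)
background = [r.rank for r in results if r.gene_id not in dataset.truth.enriched_genes]
print(f"genes scored after the 1-FPKM gate: {len(results)}")
print(f"planted enriched gene ranks: {planted}")
print(
    f"median rank: planted {np.median(planted):.0f} vs background "
    f"{np.median(background):.0f} — the genes whose 3'UTRs were stacked "
    "with up-family sites surface at the top of the list."
)
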