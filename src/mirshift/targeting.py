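"""Gene-level miRNA targeting-shift statistic and its permutation null.

For each gene, the targeting change between two conditions is

    delta = |F_gene ∩ U| − |F_gene ∩ D|

where F_gene is the set of conserved miRNA families with at least one
predicted conserved site in the gene's 3'UTR, and U / D are the sets of
up- and down-regulated families.  Site multiplicity is ignored: a family
contributes at most +1 or −1.

Significance comes from a label-permutation null: U and D are replaced
by uniform random draws of the same sizes from the conserved-family
universe (each drawn without replacement; by default the two draws are
independent, so they may overlap — the observed strata can themselves
share a family).  The empirical p-value is the fraction of draws whose
delta is **equal or greater** than the observed one.  ``paper_literal``
divides by the iteration count (and can return 0); ``add_one`` uses the
(count+1)/(iterations+1) estimator, which is never 0 and is the proper
choice when p-values are consumed downstream.

A brute-force enumeration over all (U, D) label assignments is provided
as an exact oracle for small universes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, EnumerationBoundError
from .io_formats import GeneExpressionTable, TargetIncidenceTable

_SAMPLING_MODES = ("independent_overlap_allowed", "disjoint")
_P_ESTIMATORS = ("paper_literal", "add_one")


@dataclass(frozen=True)
class ShiftConfig:
    n_up: int
    n_down: int
    iterations: int = 100_000
    min_fpkm: float = 1.0
    rng_seed: int = 0
    sampling: str = "independent_overlap_allowed"
    p_estimator: str = "paper_literal"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down < 1:
            raise ConfigError("need n_up + n_down >= 1 with both non-negative")
        if self.sampling not in _SAMPLING_MODES:
            raise ConfigError(f"unknown sampling mode {self.sampling!r}")
        if self.p_estimator not in _P_ESTIMATORS:
            raise ConfigError(f"unknown p_estimator {self.p_estimator!r}")


@dataclass(frozen=True)
class TargetingShiftResult:
    gene_id: str
    delta: int
    p_value: float
    iterations_used: int
    rank: int | None = None
    p_adjusted: float | None = None


def targeting_delta(
    gene_families: Iterable[str],
    up_families: Iterable[str],
    down_families: Iterable[str],
) -> int:
    """Up-family hits minus down-family hits for one gene (presence only)."""
    fams = set(gene_families)
    return len(fams & set(up_families)) - len(fams & set(down_families))


def observed_deltas(
    targets: TargetIncidenceTable,
    up_families: Iterable[str],
    down_families: Iterable[str],
    genes: Sequence[str] | None = None,
) -> dict[str, int]:
    """Observed delta per gene (all table genes unless ``genes`` given)."""
    up, down = set(up_families), set(down_families)
    gene_ids = list(targets.sites) if genes is None else list(genes)
    return {
        g: targeting_delta(targets.families_of(g), up, down) for g in gene_ids
    }


def _incidence_matrix(
    targets: TargetIncidenceTable, universe: Sequence[str], genes: Sequence[str]
) -> np.ndarray:
    """Boolean genes x families matrix over the (ordered) universe."""
    index = {fam: j for j, fam in enumerate(universe)}
    matrix = np.zeros((len(genes), len(universe)), dtype=np.float32)
    for i, gene in enumerate(genes):
        for fam in targets.families_of(gene):
            j = index.get(fam)
            if j is not None:
                matrix[i, j] = 1.0
    return matrix


def _check_strata(universe_size: int, config: ShiftConfig) -> None:
    if config.n_up > universe_size or config.n_down > universe_size:
        raise ConfigError(
            f"stratum size exceeds family universe ({universe_size})"
        )
    if (
        config.sampling == "disjoint"
        and config.n_up + config.n_down > universe_size
    ):
        raise ConfigError("disjoint sampling needs n_up + n_down <= universe")


def permutation_pvalues(
    targets: TargetIncidenceTable,
    family_universe: Iterable[str],
    observed_up: Iterable[str],
    observed_down: Iterable[str],
    config: ShiftConfig,
    genes: Sequence[str] | None = None,
) -> dict[str, tuple[int, float]]:
    """Monte-Carlo p-values for every gene's observed targeting delta.

    Per iteration a size-``n_up`` and a size-``n_down`` family set are
    drawn from the universe and each gene's permuted delta is compared
    (inclusively, >=) with its observed delta.  Identical ``rng_seed``
    reproduces the p-values bit-exactly.  Sampling is vectorized in
    blocks: uniform sort keys are drawn per iteration (up keys first,
    then down keys within a block) and the smallest ``n`` keys select
    the set, which is a uniform draw without replacement.
    """
    universe = sorted(set(family_universe))
    up = set(observed_up)
    down = set(observed_down)
    if not up <= set(universe) or not down <= set(universe):
        raise ConfigError("observed families must lie inside the universe")
    if len(up) != config.n_up or len(down) != config.n_down:
        raise ConfigError(
            f"observed strata sizes ({len(up)}, {len(down)}) do not match "
            f"config ({config.n_up}, {config.n_down})"
        )
    _check_strata(len(universe), config)

    gene_ids = list(targets.sites) if genes is None else list(genes)
    matrix = _incidence_matrix(targets, universe, gene_ids)  # G x F
    delta_obs = np.array(
        [
            targeting_delta(targets.families_of(g), up, down)
            for g in gene_ids
        ],
        dtype=np.float32,
    )

    n_families = len(universe)
    rng = np.random.default_rng(config.rng_seed)
    exceed = np.zeros(len(gene_ids), dtype=np.int64)
    block = 4096
    done = 0
    while done < config.iterations:
        b = min(block, config.iterations - done)
        if config.sampling == "independent_overlap_allowed":
            up_sel = _select_smallest(rng.random((b, n_families)), config.n_up)
            down_sel = _select_smallest(rng.random((b, n_families)), config.n_down)
        else:  # disjoint: one key vector, first n_up then next n_down ranks
            order = np.argsort(rng.random((b, n_families)), axis=1)
            up_sel = _indicator(order[:, : config.n_up], n_families)
            down_sel = _indicator(
                order[:, config.n_up : config.n_up + config.n_down], n_families
            )
        perm_delta = (up_sel - down_sel) @ matrix.T  # b x G, exact small ints
        exceed += (perm_delta >= delta_obs[None, :]).sum(axis=0)
        done += b

    if config.p_estimator == "paper_literal":
        pvals = exceed / config.iterations
    else:
        pvals = (exceed + 1) / (config.iterations + 1)
    return {
        g: (int(delta_obs[i]), float(pvals[i])) for i, g in enumerate(gene_ids)
    }


def _select_smallest(keys: np.ndarray, n: int) -> np.ndarray:
    """Indicator matrix of the n smallest keys per row (uniform subset)."""
    b, f = keys.shape
    out = np.zeros((b, f), dtype=np.float32)
    if n == 0:
        return out
    idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
    np.put_along_axis(out, idx, 1.0, axis=1)
    return out


def _indicator(idx: np.ndarray, n_families: int) -> np.ndarray:
    out = np.zeros((idx.shape[0], n_families), dtype=np.float32)
    np.put_along_axis(out, idx, 1.0, axis=1)
    return out


def exact_pvalues_small(
    targets: TargetIncidenceTable,
    family_universe: Iterable[str],
    observed_up: Iterable[str],
    observed_down: Iterable[str],
    config: ShiftConfig,
    genes: Sequence[str] | None = None,
    max_combinations: int = 1_000_000,
) -> dict[str, float]:
    """Exact p-values by full enumeration of all (up-set, down-set) pairs.

    Serves as the independent oracle for :func:`permutation_pvalues` on
    small universes; refuses when the number of unordered set pairs
    exceeds ``max_combinations``.
    """
    universe = sorted(set(family_universe))
    up = set(observed_up)
    down = set(observed_down)
    _check_strata(len(universe), config)

    n_pairs = math.comb(len(universe), config.n_up) * math.comb(
        len(universe), config.n_down
    )
    if n_pairs > max_combinations:
        raise EnumerationBoundError(
            f"{n_pairs} label combinations exceed the bound {max_combinations}"
        )

    gene_ids = list(targets.sites) if genes is None else list(genes)
    gene_fams = [targets.families_of(g) & set(universe) for g in gene_ids]
    delta_obs = [
        targeting_delta(fams, up, down) for fams in gene_fams
    ]

    exceed = [0] * len(gene_ids)
    total = 0
    for up_set in itertools.combinations(universe, config.n_up):
        up_s = set(up_set)
        for down_set in itertools.combinations(universe, config.n_down):
            down_s = set(down_set)
            if config.sampling == "disjoint" and up_s & down_s:
                continue
            total += 1
            for i, fams in enumerate(gene_fams):
                d = len(fams & up_s) - len(fams & down_s)
                if d >= delta_obs[i]:
                    exceed[i] += 1
    return {g: exceed[i] / total for i, g in enumerate(gene_ids)}


def apply_expression_gate(
    results: Iterable[TargetingShiftResult],
    expression: GeneExpressionTable,
    min_fpkm: float = 1.0,
) -> list[TargetingShiftResult]:
    """Keep genes expressed at >= ``min_fpkm`` (closed bound); absent genes drop."""
    return [
        r
        for r in results
        if r.gene_id in expression and expression.get(r.gene_id) >= min_fpkm
    ]


def rank_genes(
    results: Iterable[TargetingShiftResult],
) -> list[TargetingShiftResult]:
    """Order by ascending p, ties by descending delta then gene id; rank 1..n."""
    ordered = sorted(
        results, key=lambda r: (r.p_value, -r.delta, r.gene_id)
    )
    return [replace(r, rank=i) for i, r in enumerate(ordered, start=1)]


def bh_adjust(results: Sequence[TargetingShiftResult]) -> list[TargetingShiftResult]:
    """Attach Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    from statsmodels.stats.multitest import multipletests

    if not results:
        return []
    _, adjusted, _, _ = multipletests(
        [r.p_value for r in results], method="fdr_bh"
    )
    return [replace(r, p_adjusted=float(q)) for r, q in zip(results, adjusted)]


def run_targeting_shift(
    targets: TargetIncidenceTable,
    family_universe: Iterable[str],
    observed_up: Iterable[str],
    observed_down: Iterable[str],
    config: ShiftConfig,
    expression: GeneExpressionTable | None = None,
) -> list[TargetingShiftResult]:
    """Full pipeline: permutation p-values, expression gate, ranking."""
    pvals = permutation_pvalues(
        targets, family_universe, observed_up, observed_down, config
    )
    results = [
        TargetingShiftResult(
            gene_id=g, delta=d, p_value=p, iterations_used=config.iterations
        )
        for g, (d, p) in pvals.items()
    ]
    if expression is not None:
        results = apply_expression_gate(results, expression, config.min_fpkm)
    return rank_genes(results)
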