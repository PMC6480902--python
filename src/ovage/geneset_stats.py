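"""Set-level aging statistics: the expression-matched permutation test,
directional counts and sign tests, and top-decile significance enrichment.

The permutation test asks whether a focal gene set (e.g. the piRNA
machinery) shows a coordinated old/young expression shift larger than
expected for genes of comparable expression level.  Each focal gene is
matched to its nearest expression-ranked neighbours (default the 10 above
and 10 below); null replicates re-draw one match per focal gene and the
p-value is the proportion of replicates whose mean log2 ratio meets or
exceeds the observed mean.

Two exceedance rules are provided.  The default compares the cross-strain
average of the per-strain set means — a scalar statistic whose permutation
p-value is uniform under the null.  The stricter rule
(``combine="all_strains"``) requires the null mean to meet the observed
mean in every strain simultaneously; that quadrant probability is
deliberately conservative for discordant shifts but is *not* uniformly
distributed under the null (for two independent strains it behaves like the
product of two uniforms), so it is reported as a companion statistic rather
than used as the primary calibrated p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .expression_metrics import ExpressionSummary, FLAT_EPS
from .io_formats import GeneSet, ValidationError
from .positional_enrichment import ContingencyTable2x2, yates_chi2

logger = logging.getLogger("ovage")


@dataclass
class MatchTable:
    """Per-focal-gene list of expression-matched non-focal genes."""

    matches: dict[str, tuple[str, ...]]
    k_up: int
    k_down: int

    def __post_init__(self) -> None:
        k = self.k_up + self.k_down
        for gene, m in self.matches.items():
            if len(m) != k:
                raise ValidationError(f"focal gene {gene!r} has {len(m)} matches, expected {k}")


def build_match_table(
    summary: ExpressionSummary,
    focal: GeneSet,
    k_up: int = 10,
    k_down: int = 10,
) -> MatchTable:
    """Match every focal gene to its nearest expression-ranked neighbours.

    Features are ranked by mean RPKM over all samples (both strains, both
    ages) so the age contrast never leaks into the null.  Focal-set members
    are excluded as candidates.  At rank extremes the deficit on one side is
    filled from the other, so every focal gene gets k_up + k_down matches.
    """
    focal_members = [g for g in focal.members if g in summary.features]
    if len(focal_members) < len(focal.members):
        logger.warning(
            "focal set %r: %d members not in expression data, dropped",
            focal.name, len(focal.members) - len(focal_members),
        )
    if not focal_members:
        raise ValidationError("focal set empty after matching to expression data")
    expr = summary.overall_mean
    focal_set = set(focal_members)
    # deterministic order: expression descending, feature id as tiebreak
    order = expr.loc[expr.index.sort_values()].sort_values(ascending=False, kind="mergesort")
    ranked = order.index.to_numpy()
    non_focal_mask = np.array([g not in focal_set for g in ranked])
    non_focal = ranked[non_focal_mask]
    k = k_up + k_down
    if len(non_focal) < k:
        raise ValidationError(f"only {len(non_focal)} non-focal genes; need >= {k}")
    # position of each focal gene within the non-focal ordering
    positions = {g: i for i, g in enumerate(ranked)}
    cum_non_focal = np.cumsum(non_focal_mask)  # non-focal genes at or above each rank
    matches: dict[str, tuple[str, ...]] = {}
    for gene in focal_members:
        pos = positions[gene]
        above = int(cum_non_focal[pos])  # non-focal ranked above (higher expression)
        lo = max(0, above - k_up)
        hi = min(len(non_focal), lo + k)
        lo = max(0, hi - k)  # backfill from above when short below
        matches[gene] = tuple(non_focal[lo:hi])
    return MatchTable(matches, k_up, k_down)


@dataclass
class SetTestResult:
    """Outcome of the matched permutation test."""

    observed: dict[str, float]  # per-strain mean log2 (or linear) fold
    n_perm: int
    exceedances: int
    p: float  # add-one estimator (s + 1) / (n + 1)
    p_raw: float  # plain proportion s / n
    seed: int
    combine: str = "mean"
    null_quantiles: dict[str, dict[float, float]] = field(default_factory=dict)


def _set_statistic(summary: ExpressionSummary, genes, strain: str, scale: str) -> float:
    ratios = summary.ratios(strain).loc[list(genes)]
    if scale == "log":
        return float(ratios.mean())
    t = summary.table
    sub = t[(t["strain"] == strain) & (t["feature"].isin(set(genes)))]
    return float(sub["fold"].mean())


def matched_permutation_test(
    summary: ExpressionSummary,
    matches: MatchTable,
    focal: GeneSet,
    n_perm: int = 10_000,
    seed: int | None = None,
    scale: str = "log",
    combine: str = "mean",
    unique_within_replicate: bool = False,
) -> SetTestResult:
    """Expression-matched permutation test for a coordinated set-level shift.

    Observed statistic: per-strain mean over focal genes of the log2
    old/young ratio (``scale="linear"`` uses the pseudocounted linear fold).
    Each null replicate draws, independently per focal gene, one uniform
    match; by default a matched gene may serve several focal genes within a
    replicate (set ``unique_within_replicate`` to forbid that).

    ``combine="mean"`` (default): a replicate counts as an exceedance when
    its cross-strain average set mean meets or exceeds the observed average
    — the calibrated rule.  ``combine="all_strains"``: the replicate must
    meet the observed mean in every strain simultaneously (conservative
    joint rule; see the module docstring).  p = (exceedances + 1) /
    (n_perm + 1).
    """
    if seed is None:
        raise ValidationError("a seed is required for the permutation test")
    if n_perm < 100:
        logger.warning("n_perm = %d is very small; p-value resolution is coarse", n_perm)
    focal_genes = [g for g in focal.members if g in matches.matches]
    if not focal_genes:
        raise ValidationError("no focal genes with matches")
    strains = summary.strains
    if scale not in ("log", "linear"):
        raise ValidationError(f"unknown scale {scale!r}")
    if combine not in ("mean", "all_strains"):
        raise ValidationError(f"unknown combine rule {combine!r}")

    observed = {s: _set_statistic(summary, focal_genes, s, scale) for s in strains}

    k = matches.k_up + matches.k_down
    match_matrix = np.array([matches.matches[g] for g in focal_genes], dtype=object)
    # per-strain ratio (or fold) lookup for all candidate genes
    value_arrays = []
    for s in strains:
        if scale == "log":
            lut = summary.ratios(s)
        else:
            t = summary.table
            sub = t[t["strain"] == s]
            lut = pd.Series(sub["fold"].to_numpy(), index=sub["feature"].to_numpy())
        value_arrays.append(
            np.array([[lut.loc[g] for g in row] for row in match_matrix], dtype=float)
        )

    rng = np.random.default_rng(seed)
    n_focal = len(focal_genes)
    obs_vec = np.array([observed[s] for s in strains])
    exceed = 0
    chunk = max(1, min(n_perm, 200_000 // max(n_focal, 1)))
    null_means_all = []
    done = 0
    row_idx = np.arange(n_focal)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if unique_within_replicate:
            draws = np.empty((m, n_focal), dtype=np.int64)
            for r in range(m):
                draws[r] = _draw_unique(rng, match_matrix, k)
        else:
            draws = rng.integers(0, k, size=(m, n_focal))
        means = np.empty((m, len(strains)))
        for j, vals in enumerate(value_arrays):
            means[:, j] = vals[row_idx[None, :], draws].mean(axis=1)
        if combine == "mean":
            exceed += int((means.mean(axis=1) >= obs_vec.mean() - 1e-12).sum())
        else:
            exceed += int(np.all(means >= obs_vec[None, :] - 1e-12, axis=1).sum())
        null_means_all.append(means)
        done += m
    null_means = np.vstack(null_means_all)
    quantiles = {
        s: {q: float(np.quantile(null_means[:, j], q)) for q in (0.05, 0.5, 0.95)}
        for j, s in enumerate(strains)
    }
    return SetTestResult(
        observed=observed,
        n_perm=n_perm,
        exceedances=exceed,
        p=(exceed + 1) / (n_perm + 1),
        p_raw=exceed / n_perm,
        seed=seed,
        combine=combine,
        null_quantiles=quantiles,
    )


def _draw_unique(rng, match_matrix, k) -> np.ndarray:
    """One replicate with no matched gene reused across focal genes (greedy)."""
    n_focal = match_matrix.shape[0]
    taken: set[str] = set()
    out = np.empty(n_focal, dtype=np.int64)
    for i in rng.permutation(n_focal):
        options = [j for j in range(k) if match_matrix[i, j] not in taken]
        j = int(rng.choice(options)) if options else int(rng.integers(0, k))
        out[i] = j
        taken.add(match_matrix[i, j])
    return out


def direction_count(summary: ExpressionSummary, gene_set: GeneSet) -> pd.DataFrame:
    """Counts of up / down / flat set members, per strain and pooled.

    Pooled direction is the sign of the mean over strains of the per-strain
    log2 ratios.
    """
    members = [g for g in gene_set.members if g in summary.features]
    if not members:
        raise ValidationError(f"gene set {gene_set.name!r} has no members in the data")
    rows = {}
    for strain in summary.strains:
        r = summary.ratios(strain).loc[members].to_numpy()
        rows[strain] = _count_signs(r)
    pooled = summary.pooled_ratios().loc[members].to_numpy()
    rows["pooled"] = _count_signs(pooled)
    return pd.DataFrame(rows, index=["n_up", "n_down", "n_flat"]).T


def _count_signs(r: np.ndarray) -> list[int]:
    up = int((r > FLAT_EPS).sum())
    down = int((r < -FLAT_EPS).sum())
    return [up, down, len(r) - up - down]


def sign_test(n_down: int, n_total: int) -> float:
    """Exact two-sided binomial sign test at p0 = 0.5.

    Doubles the smaller tail and caps at 1.  Flat (tied) observations are
    excluded by the caller before counting.
    """
    if n_total < 1:
        raise ValidationError("sign test needs n_total >= 1")
    if not 0 <= n_down <= n_total:
        raise ValidationError("n_down must be between 0 and n_total")
    k = min(n_down, n_total - n_down)
    p = 2.0 * scipy.stats.binom.cdf(k, n_total, 0.5)
    # with even n_total and a central k both tails share the middle term
    return float(min(p, 1.0))


def topk_enrichment(
    de,
    gene_set: GeneSet,
    top_fraction: float = 0.10,
) -> tuple[ContingencyTable2x2, float, float]:
    """Is the set over-represented in the top fraction of features ranked by
    differential-expression significance?

    Features are ranked by FDR-adjusted age p-value (ties broken by raw p,
    then by stable feature order); the top ceil(fraction * n) are crossed
    with set membership and tested with a Yates-corrected chi-squared.
    Returns (table, chi2, p).
    """
    table = de.table
    tested = table[table["p_age"].notna()]
    if len(tested) < 10:
        raise ValidationError("need >=10 tested features")
    if not 0 < top_fraction < 1:
        raise ValidationError("top_fraction must be in (0, 1)")
    members = set(gene_set.members) & set(tested.index)
    if not members:
        raise ValidationError(f"gene set {gene_set.name!r} disjoint from tested features")
    order = tested.assign(_pos=np.arange(len(tested))).sort_values(
        ["padj_age", "p_age", "_pos"], kind="mergesort"
    )
    n_top = int(np.ceil(top_fraction * len(order)))
    top_ids = set(order.index[:n_top])
    in_set = tested.index.isin(members)
    in_top = tested.index.isin(top_ids)
    a = int((in_top & in_set).sum())
    b = int((in_top & ~in_set).sum())
    c = int((~in_top & in_set).sum())
    d = int((~in_top & ~in_set).sum())
    ct = ContingencyTable2x2(a, b, c, d)
    chi2, _, p = yates_chi2(ct)
    return ct, chi2, p
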