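"""Transposable-element family aging statistics.

TE expression is quantified per family (aggregate counts over all insertions
of a family), and the statistics are exactly the gene machinery applied to
the family-level matrix: a paired t-test for global derepression within each
strain, NB differential expression with a strain-by-age interaction per
family, and the cross-strain correlation of old/young ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from . import differential, expression_metrics
from .io_formats import CountMatrix, SampleDesign, ValidationError

logger = logging.getLogger("ovage")


def te_global_test(
    summary: expression_metrics.ExpressionSummary,
    strain: str,
    scale: str = "log",
) -> tuple[float, float]:
    """Paired t-test of per-family mean expression, young vs old, one strain.

    Families are the pairs; by default the comparison is on
    log2(mean RPKM + offset), which stabilises the heavy-tailed family
    expression distribution (``scale="linear"`` uses raw mean RPKM).  A
    degenerate all-ties input returns (0.0, 1.0).
    """
    t = summary.table
    sub = t[t["strain"] == strain]
    if len(sub) < 3:
        raise ValidationError("need >=3 TE families for the paired test")
    young = sub["mean_rpkm_young"].to_numpy(dtype=float)
    old = sub["mean_rpkm_old"].to_numpy(dtype=float)
    if scale == "log":
        young = np.log2(young + summary.offset)
        old = np.log2(old + summary.offset)
    elif scale != "linear":
        raise ValidationError(f"unknown scale {scale!r}")
    if np.allclose(old, young):
        return 0.0, 1.0
    stat, p = scipy.stats.ttest_rel(young, old)
    return float(stat), float(p)


def te_family_tests(
    counts: CountMatrix,
    design: SampleDesign,
    annotation: pd.DataFrame,
    fdr: float = 0.05,
    offset: float = 0.5,
) -> pd.DataFrame:
    """Family-level differential expression with age and strain-by-age terms.

    Restricts the matrix to features flagged ``te_family``, delegates the
    statistics to :mod:`ovage.differential` (no TE-specific code path), and
    attaches per-strain fold differences and directions on the RPKM scale.
    Folds are reported as magnitudes (larger mean over smaller) with the
    direction column carrying the sign, one entry per strain when the
    strains disagree.
    """
    te = counts.subset_kind("te_family")
    if te.counts.shape[0] == 0:
        raise ValidationError("no te_family features in the count matrix")
    de = differential.test_age(te, design, fdr=fdr)
    rpkm_matrix = expression_metrics.rpkm(counts, annotation).loc[te.features]
    summary = expression_metrics.summarize_expression(rpkm_matrix, design, offset=offset)

    strains = de.strains
    out = de.table.copy()
    directions = {}
    for strain in strains:
        sub = summary.table[summary.table["strain"] == strain].set_index("feature")
        sub = sub.reindex(out.index)
        young = sub["mean_rpkm_young"].to_numpy() + offset
        old = sub["mean_rpkm_old"].to_numpy() + offset
        fold = np.where(old >= young, old / young, young / old)
        out[f"fold_{strain}"] = fold
        directions[strain] = sub["direction"].to_numpy()
    agree = directions[strains[0]] == directions[strains[1]]
    out["direction"] = np.where(
        agree,
        directions[strains[0]],
        [f"{a}, {b}" for a, b in zip(directions[strains[0]], directions[strains[1]])],
    )
    cols = (
        ["base_mean"]
        + [f"fold_{s}" for s in strains]
        + ["direction", "log2_age_effect", "p_age", "padj_age", "p_interaction",
           "padj_interaction", "significant"]
    )
    return out[cols]


def te_cross_strain_correlation(
    summary: expression_metrics.ExpressionSummary,
) -> tuple[float, float]:
    """Pearson correlation of TE-family old/young log2 ratios across strains."""
    return expression_metrics.cross_strain_correlation(summary)
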