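"""Chromatin-domain positional enrichment of differentially expressed genes.

Genes are intersected with repressive-chromatin domains (H3K9me2/me3-style
heterochromatin blocks supplied as BED intervals), cross-classified against
differential-expression significance in a 2x2 table, and tested with a
Yates-continuity-corrected chi-squared.  The same machinery drives the
dot-chromosome (4th chromosome) analysis with flags = (chromosome == dot
label).  A Welch t-test compares old/young expression ratios of
heterochromatic versus other genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree

from .io_formats import ValidationError, validate_annotation

logger = logging.getLogger("ovage")


@dataclass
class ContingencyTable2x2:
    """2x2 counts: rows = DE significant / not, columns = in-compartment / not."""

    a: int  # significant, in compartment
    b: int  # significant, outside
    c: int  # not significant, in compartment
    d: int  # not significant, outside

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def flag_compartment(
    annotation: pd.DataFrame,
    domains: pd.DataFrame,
    upstream: int = 0,
) -> pd.Series:
    """Flag genes overlapping any domain interval by >= 1 bp.

    Both sides use 0-based half-open arithmetic, so a gene [100, 200) does
    not overlap a domain [200, 300).  ``upstream`` widens each gene by that
    many bases on its upstream side (strand-aware) for promoter-window
    analyses; the default considers the gene body only.  Chromosomes named
    in the annotation but absent from the domain file are warned about.
    """
    validate_annotation(annotation)
    trees: dict[str, IntervalTree] = {}
    for chrom, block in domains.groupby("chromosome"):
        tree = IntervalTree()
        for start, end in zip(block["start"], block["end"]):
            if end > start:
                tree.addi(int(start), int(end))
        trees[str(chrom)] = tree
    missing = set(annotation["chromosome"].astype(str)) - set(trees)
    if missing:
        n = int(annotation["chromosome"].astype(str).isin(missing).sum())
        logger.warning(
            "%d genes on %d chromosome(s) absent from the domain file: %s",
            n, len(missing), sorted(missing),
        )
    starts = annotation["start"].to_numpy(dtype=np.int64)
    ends = annotation["end"].to_numpy(dtype=np.int64)
    if upstream:
        strands = annotation.get("strand", pd.Series(".", index=annotation.index)).to_numpy()
        starts = np.where(strands == "-", starts, np.maximum(starts - upstream, 0))
        ends = np.where(strands == "-", ends + upstream, ends)
    chroms = annotation["chromosome"].astype(str).to_numpy()
    flags = np.zeros(len(annotation), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(chroms, starts, ends)):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(int(s), int(e)):
            flags[i] = True
    return pd.Series(flags, index=annotation.index)


def yates_chi2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Yates-corrected chi-squared on a 2x2 table.

    chi2 = sum max(|O - E| - 0.5, 0)^2 / E with expectations from the
    margins; the correction is truncated at zero so perfectly proportional
    tables give chi2 = 0.  Returns (chi2, df=1, two-tailed p).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("2x2 table has a zero margin; test refused")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=True)
    return float(chi2), int(dof), float(p)


def build_de_compartment_table(de, flags: pd.Series) -> ContingencyTable2x2:
    """Cross-classify FDR significance against a compartment flag.

    ``flags`` must cover every tested gene.  The table is returned even when
    a margin is empty; :func:`yates_chi2` refuses such tables.
    """
    tested = de.table[de.table["p_age"].notna()]
    missing = tested.index.difference(flags.index)
    if len(missing):
        raise ValidationError(f"{len(missing)} tested genes lack a compartment flag")
    f = flags.loc[tested.index].astype(bool).to_numpy()
    sig = tested["significant"].astype(bool).to_numpy()
    return ContingencyTable2x2(
        a=int((sig & f).sum()),
        b=int((sig & ~f).sum()),
        c=int((~sig & f).sum()),
        d=int((~sig & ~f).sum()),
    )


def compartment_shift_test(
    summary, flags: pd.Series, strain: str
) -> tuple[float, float, float]:
    """Welch two-sample t-test of log2 old/young ratios, in-compartment
    versus outside, within one strain.

    Returns (t, p, mean difference in - out).  A subtle global derepression
    of heterochromatic genes would appear as a positive mean difference.
    """
    ratios = summary.ratios(strain)
    flags = flags.reindex(ratios.index)
    if flags.isna().any():
        raise ValidationError("compartment flags missing for some summarized genes")
    inside = ratios[flags.astype(bool)].to_numpy()
    outside = ratios[~flags.astype(bool)].to_numpy()
    if len(inside) < 2 or len(outside) < 2:
        raise ValidationError("need >=2 genes per group for the t-test")
    if (len(inside) <= 2 and np.var(inside) == 0) or (len(outside) <= 2 and np.var(outside) == 0):
        raise ValidationError("zero-variance group with n <= 2")
    t, p = scipy.stats.ttest_ind(inside, outside, equal_var=False)
    return float(t), float(p), float(inside.mean() - outside.mean())
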