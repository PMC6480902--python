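"""RPKM, replicate aggregation, log2 old/young ratios, cross-strain
correlation, and oogenic-stage verification.

The expression unit throughout is RPKM (reads per kilobase of transcript per
million mapped reads); ratios are formed on strain-level replicate means with
a +0.5 pseudocount, i.e. log2((mean_old + 0.5) / (mean_young + 0.5)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import CountMatrix, SampleDesign, ValidationError, validate_annotation

logger = logging.getLogger("ovage")

#: |log2 ratio| below this is called "flat" (exact-tie guard).
FLAT_EPS = 1e-9

#: stage assignments with max |r| below this are flagged low-confidence.
LOW_CONFIDENCE_R = 0.3


def rpkm(counts: CountMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RPKM: count / (length_kb * total_sample_counts / 1e6).

    The per-million total is the column sum over *all* features in the
    matrix.  Raises if a feature has no annotated length or a sample has
    zero total counts.
    """
    validate_annotation(annotation)
    missing = counts.features.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"{len(missing)} features lack annotation (e.g. {list(missing[:3])})")
    lengths_kb = annotation.loc[counts.features, "length"].to_numpy(dtype=float) / 1000.0
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        dead = counts.samples[totals == 0].tolist()
        raise ValidationError(f"samples with zero total counts: {dead}")
    values = counts.counts.to_numpy(dtype=float) / lengths_kb[:, None] / (totals[None, :] / 1e6)
    return pd.DataFrame(values, index=counts.features, columns=counts.samples)


@dataclass
class ExpressionSummary:
    """Per-feature, per-strain expression summary on the RPKM scale.

    ``table`` is long-format with one row per feature x strain:
    mean_rpkm_young, mean_rpkm_old, log2_ratio (with pseudocount), fold
    (pseudocounted linear ratio), fold_offset_free (plain mean_old /
    mean_young, NaN when the young mean is zero), direction.
    ``overall_mean`` is the mean RPKM of each feature across all samples of
    both strains — the matching axis for the permutation test.
    """

    table: pd.DataFrame
    overall_mean: pd.Series
    offset: float

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())

    @property
    def features(self) -> pd.Index:
        return self.overall_mean.index

    def ratios(self, strain: str) -> pd.Series:
        t = self.table[self.table["strain"] == strain]
        return pd.Series(t["log2_ratio"].to_numpy(), index=t["feature"].to_numpy())

    def pooled_ratios(self) -> pd.Series:
        """Mean over strains of the per-strain log2 ratios."""
        return self.table.groupby("feature", sort=False)["log2_ratio"].mean().reindex(self.features)

    def subset(self, features) -> "ExpressionSummary":
        keep = self.table["feature"].isin(set(features))
        return ExpressionSummary(
            self.table[keep].reset_index(drop=True),
            self.overall_mean.loc[self.overall_mean.index.isin(set(features))],
            self.offset,
        )


def _direction(log2_ratio: np.ndarray) -> np.ndarray:
    out = np.where(log2_ratio > FLAT_EPS, "up", np.where(log2_ratio < -FLAT_EPS, "down", "flat"))
    return out.astype(object)


def summarize_expression(
    rpkm_matrix: pd.DataFrame, design: SampleDesign, offset: float = 0.5
) -> ExpressionSummary:
    """Aggregate replicates to strain-level means per age and form ratios.

    Replicates are averaged on the RPKM scale before the ratio, so unbalanced
    replicate counts (4 vs 3) are handled naturally.  ``offset`` must be
    positive whenever a zero mean occurs.
    """
    design_samples = design.table["sample"]
    missing = set(design_samples) - set(rpkm_matrix.columns)
    if missing:
        raise ValidationError(f"design samples absent from RPKM matrix: {sorted(missing)}")
    rows = []
    for strain in design.strains:
        means = {}
        for age in ("young", "old"):
            samples = design.samples_for(strain, age)
            if not samples:
                raise ValidationError(f"missing strain x age cell: {strain} / {age}")
            means[age] = rpkm_matrix[samples].mean(axis=1)
        if offset <= 0 and ((means["young"] == 0) | (means["old"] == 0)).any():
            raise ValidationError("offset must be > 0 when zero means are present")
        log2_ratio = np.log2((means["old"] + offset) / (means["young"] + offset))
        with np.errstate(divide="ignore", invalid="ignore"):
            offset_free = np.where(
                means["young"].to_numpy() > 0,
                means["old"].to_numpy() / means["young"].to_numpy(),
                np.nan,
            )
        rows.append(
            pd.DataFrame(
                {
                    "feature": rpkm_matrix.index,
                    "strain": strain,
                    "mean_rpkm_young": means["young"].to_numpy(),
                    "mean_rpkm_old": means["old"].to_numpy(),
                    "log2_ratio": log2_ratio.to_numpy(),
                    "fold": ((means["old"] + offset) / (means["young"] + offset)).to_numpy(),
                    "fold_offset_free": offset_free,
                    "direction": _direction(log2_ratio.to_numpy()),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    overall = rpkm_matrix[design_samples].mean(axis=1)
    return ExpressionSummary(table, overall, offset)


def cross_strain_correlation(
    summary: ExpressionSummary, features=None
) -> tuple[float, float]:
    """Pearson correlation of per-strain log2 old/young ratios.

    Requires exactly two strains; the p-value is two-sided from the t
    distribution with n-2 degrees of freedom.
    """
    strains = summary.strains
    if len(strains) != 2:
        raise ValidationError(f"need exactly 2 strains, got {strains}")
    a = summary.ratios(strains[0])
    b = summary.ratios(strains[1])
    if features is not None:
        features = [f for f in features if f in a.index]
        a, b = a.loc[features], b.loc[features]
    else:
        b = b.reindex(a.index)
    if len(a) < 3:
        raise ValidationError("need >=3 features for a correlation")
    if np.std(a.to_numpy()) == 0 or np.std(b.to_numpy()) == 0:
        raise ValidationError("zero variance in a ratio vector")
    r, p = scipy.stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), float(p)


@dataclass
class StageAssignment:
    stage: str
    correlations: dict[str, float]
    low_confidence: bool


def verify_stage(
    sample_log_expression: pd.Series, profiles: pd.DataFrame
) -> StageAssignment:
    """Correlate a sample against per-stage reference profiles.

    ``sample_log_expression`` is log2(RPKM + offset) over a marker panel;
    ``profiles`` has panel genes as rows and stage labels as columns, on the
    same log scale.  The assigned stage maximises Pearson r over shared
    genes; ties break by column order with a warning; assignments with
    max |r| < 0.3 are flagged low-confidence.
    """
    shared = profiles.index.intersection(sample_log_expression.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared panel genes (<3)")
    sample = sample_log_expression.loc[shared].to_numpy(dtype=float)
    corr: dict[str, float] = {}
    for stage in profiles.columns:
        ref = profiles.loc[shared, stage].to_numpy(dtype=float)
        if np.std(ref) == 0 or np.std(sample) == 0:
            corr[stage] = float("nan")
            continue
        corr[stage] = float(scipy.stats.pearsonr(sample, ref)[0])
    finite = {s: r for s, r in corr.items() if np.isfinite(r)}
    if not finite:
        raise ValidationError("no stage profile with finite correlation")
    best = max(finite.values())
    winners = [s for s in profiles.columns if finite.get(s) == best]
    if len(winners) > 1:
        logger.warning("stage assignment tie between %s; keeping %s", winners, winners[0])
    low = abs(best) < LOW_CONFIDENCE_R
    return StageAssignment(winners[0], corr, low)
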