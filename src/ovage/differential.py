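"""Negative-binomial differential expression for a strain x age design.

Per feature, a log-linear NB model

    log mu = log(size factor) + b0 + b_strain + b_age (+ b_strain:age)

is fit by IRLS with a fixed per-feature dispersion (Var = mu + alpha mu^2).
The age effect "controlling for strain" is the Wald test on ``b_age`` in the
reduced (no-interaction) model; the strain-by-age effect is the Wald test on
the interaction coefficient in the full model.  Multiple testing is handled
with Benjamini-Hochberg.  This is a transparent NB-GLM pipeline, not an
emulation of any particular tool's shrinkage and outlier heuristics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_formats import CountMatrix, SampleDesign, ValidationError

logger = logging.getLogger("ovage")

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features with all-positive counts."""
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.sum() < 1:
        raise ValidationError("no feature has positive counts in every sample")
    ref = values[positive]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    sf = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return pd.Series(sf, index=counts.columns)


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    design: SampleDesign,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-feature NB dispersion by method of moments, shrunk toward a
    mean-dispersion trend.

    Within each strain x age cell the replicate variance of size-factor
    normalised counts is pooled; the raw moment estimate is
    (pooled var - mean) / mean^2.  A parametric trend
    ``alpha(mu) = a0 + a1 / mu`` is fit across features and each raw
    estimate is pulled toward the trend by a weighted midpoint
    (``shrink_weight`` on the trend).  Estimates are floored at 1e-8;
    degenerate features (constant counts) get the floor.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValidationError("shrink_weight must be in [0, 1]")
    sf = size_factors(table)
    norm = table.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cells = [
        design.samples_for(strain, age)
        for strain in design.strains
        for age in ("young", "old")
    ]
    col_index = {s: i for i, s in enumerate(table.columns)}
    ss = np.zeros(table.shape[0])
    df = 0
    cell_means = []
    for samples in cells:
        if len(samples) < 2:
            raise ValidationError("dispersion estimation needs >=2 replicates per cell")
        idx = [col_index[s] for s in samples]
        block = norm[:, idx]
        m = block.mean(axis=1)
        ss += block.var(axis=1, ddof=1) * (len(samples) - 1)
        df += len(samples) - 1
        cell_means.append(m)
    pooled_var = ss / df
    mean_level = np.mean(cell_means, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - mean_level) / mean_level**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, DISPERSION_FLOOR)

    # parametric trend alpha(mu) = a0 + a1/mu on informative features
    ok = mean_level > 1.0
    trend = np.full_like(raw, np.median(raw[ok]) if ok.any() else DISPERSION_FLOOR)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_level[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a0 > 0 or a1 > 0:
            with np.errstate(divide="ignore"):
                trend = a0 + a1 / np.maximum(mean_level, 1e-12)
    shrunk = shrink_weight * trend + (1.0 - shrink_weight) * raw
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=table.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up with NA passthrough.

    NAs are excluded from the number of tests m and returned as NA.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class DEResult:
    """Per-feature differential-expression results.

    ``table`` columns: base_mean, log2_age_effect (pooled, controlling for
    strain), se, per-strain effects ``log2_age_effect_<strain>``, p_age,
    p_interaction, padj_age, padj_interaction, significant (padj_age < fdr).
    """

    table: pd.DataFrame
    fdr: float
    strains: list[str]

    @property
    def significant_features(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False).astype(bool)]


def _fit_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    model = sm.GLM(y, X, family=fam, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def test_age(
    counts: CountMatrix | pd.DataFrame,
    design: SampleDesign,
    dispersions: pd.Series | None = None,
    fdr: float = 0.05,
) -> DEResult:
    """Wald tests for age (controlling for strain) and strain-by-age
    interaction, per feature.

    Features with zero counts in every sample are dropped before testing.
    Non-converged fits are flagged with NA p-values and excluded from the
    FDR denominator.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    design.validate_against(
        counts if isinstance(counts, CountMatrix)
        else CountMatrix(table, pd.Series("gene", index=table.index))
    )
    strains = design.strains
    if len(strains) != 2:
        raise ValidationError(f"design must have exactly 2 strains, got {strains}")

    # align columns to design order
    samples = design.table["sample"].tolist()
    table = table[samples]
    nonzero = table.sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("dropping %d features with zero counts everywhere", dropped)
    table = table.loc[nonzero]

    if dispersions is None:
        dispersions = estimate_dispersion(table, design)
    dispersions = dispersions.reindex(table.index)
    if dispersions.isna().any():
        raise ValidationError("dispersions missing for some tested features")

    sf = size_factors(table)
    offset = np.log(sf.to_numpy())
    strain_ind = (design.table["strain"] == strains[1]).to_numpy(dtype=float)
    age_ind = (design.table["age"] == "old").to_numpy(dtype=float)
    X_reduced = np.column_stack([np.ones(len(samples)), strain_ind, age_ind])
    X_full = np.column_stack([X_reduced, strain_ind * age_ind])

    values = table.to_numpy(dtype=float)
    alphas = dispersions.to_numpy()
    n = values.shape[0]
    beta_age = np.full(n, np.nan)
    se_age = np.full(n, np.nan)
    p_age = np.full(n, np.nan)
    beta_age_s0 = np.full(n, np.nan)
    beta_age_s1 = np.full(n, np.nan)
    p_inter = np.full(n, np.nan)
    base_mean = (values / sf.to_numpy()[None, :]).mean(axis=1)

    for i in range(n):
        y = values[i]
        try:
            red = _fit_nb(y, X_reduced, offset, alphas[i])
            if not np.all(np.isfinite(red.bse)):
                raise ValueError("non-finite SE")
            beta_age[i] = red.params[2]
            se_age[i] = red.bse[2]
            z = red.params[2] / red.bse[2]
            p_age[i] = 2.0 * scipy.stats.norm.sf(abs(z))
        except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
            pass
        try:
            full = _fit_nb(y, X_full, offset, alphas[i])
            if not np.all(np.isfinite(full.bse)):
                raise ValueError("non-finite SE")
            beta_age_s0[i] = full.params[2]
            beta_age_s1[i] = full.params[2] + full.params[3]
            z = full.params[3] / full.bse[3]
            p_inter[i] = 2.0 * scipy.stats.norm.sf(abs(z))
        except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
            pass

    padj_age = bh_adjust(p_age)
    padj_inter = bh_adjust(p_inter)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_age_effect": beta_age / LN2,
            "se": se_age / LN2,
            f"log2_age_effect_{strains[0]}": beta_age_s0 / LN2,
            f"log2_age_effect_{strains[1]}": beta_age_s1 / LN2,
            "p_age": p_age,
            "p_interaction": p_inter,
            "padj_age": padj_age,
            "padj_interaction": padj_inter,
        },
        index=table.index,
    )
    out["significant"] = out["padj_age"] < fdr
    out.loc[out["padj_age"].isna(), "significant"] = False
    n_failed = int(np.isnan(p_age).sum())
    if n_failed:
        logger.warning("%d features failed to converge (p = NA)", n_failed)
    return DEResult(out, fdr, strains)
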