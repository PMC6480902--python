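import numpy as np
import pandas as pd
import pytest

from ovage import expression_metrics as em
from ovage import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """One small dataset with the default (study-condition) effects."""
    cfg = sd.SimulationConfig(n_genes=800, n_te_families=25, seed=42)
    return sd.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_summary(small_sim):
    rpkm = em.rpkm(small_sim.counts, small_sim.annotation)
    genic = small_sim.counts.feature_kind[
        small_sim.counts.feature_kind.isin(["gene", "mito"])
    ].index
    return em.summarize_expression(rpkm.loc[genic], small_sim.design)


@pytest.fixture(scope="session")
def small_de(small_sim):
    from ovage import differential

    return differential.test_age(small_sim.counts.subset_kind("gene"), small_sim.design)


def make_summary_from_ratios(ratios: dict[str, pd.Series], overall: pd.Series,
                             offset: float = 0.5) -> em.ExpressionSummary:
    """Build an ExpressionSummary directly from per-strain log2 ratios.

    Mean RPKMs are back-filled to be consistent with the ratios
    (young mean fixed at 1), so both the log and linear statistics work.
    """
    rows = []
    for strain, r in ratios.items():
        young = np.ones(len(r))
        old = (young + offset) * np.power(2.0, r.to_numpy()) - offset
        rows.append(pd.DataFrame({
            "feature": r.index,
            "strain": strain,
            "mean_rpkm_young": young,
            "mean_rpkm_old": old,
            "log2_ratio": r.to_numpy(),
            "fold": (old + offset) / (young + offset),
            "fold_offset_free": old / young,
            "direction": np.where(r.to_numpy() > em.FLAT_EPS, "up",
                                  np.where(r.to_numpy() < -em.FLAT_EPS, "down", "flat")),
        }))
    return em.ExpressionSummary(pd.concat(rows, ignore_index=True), overall, offset)
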