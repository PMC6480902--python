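"""RPKM arithmetic, ratio summaries, correlations, stage verification."""

import numpy as np
import pandas as pd
import pytest

from ovage import expression_metrics as em
from ovage.io_formats import CountMatrix, SampleDesign, ValidationError


def _annotation(lengths_bp: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": "2L",
            "start": 0,
            "end": list(lengths_bp.values()),
            "strand": "+",
            "length": list(lengths_bp.values()),
        },
        index=pd.Index(lengths_bp.keys(), name="feature"),
    )


def _matrix(data: dict, samples) -> CountMatrix:
    df = pd.DataFrame(data, index=samples).T.astype(np.int64)
    df.columns = samples
    return CountMatrix(df, pd.Series("gene", index=df.index))


class TestRpkm:
    def test_hand_arithmetic(self):
        # 1,000 reads on a 2 kb feature in a 10,000,000-read sample -> 50.0
        counts = pd.DataFrame(
            {"s1": [1_000, 9_999_000]},
            index=pd.Index(["target", "rest"], name="feature"),
        )
        cm = CountMatrix(counts, pd.Series("gene", index=counts.index))
        ann = _annotation({"target": 2_000, "rest": 1_000})
        out = em.rpkm(cm, ann)
        assert out.loc["target", "s1"] == pytest.approx(50.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=pd.Index(["a", "b"], name="feature"))
        cm = CountMatrix(counts, pd.Series("gene", index=counts.index))
        out = em.rpkm(cm, _annotation({"a": 500, "b": 500}))
        assert out.loc["a", "s1"] == 0.0

    def test_scale_invariance_of_library_depth(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(20, 3)),
            index=pd.Index([f"g{i}" for i in range(20)], name="feature"),
            columns=["s1", "s2", "s3"],
        )
        ann = _annotation({f"g{i}": int(l) for i, l in enumerate(rng.integers(300, 5000, 20))})
        cm1 = CountMatrix(counts, pd.Series("gene", index=counts.index))
        cm2 = CountMatrix(counts * 2, pd.Series("gene", index=counts.index))
        pd.testing.assert_frame_equal(em.rpkm(cm1, ann), em.rpkm(cm2, ann))

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=pd.Index(["a", "b"], name="feature"))
        cm = CountMatrix(counts, pd.Series("gene", index=counts.index))
        with pytest.raises(ValidationError, match="zero total"):
            em.rpkm(cm, _annotation({"a": 500, "b": 500}))

    def test_column_sum_identity_on_random_matrices(self):
        # sum_i RPKM_ij == 1e9 * sum_i(count_ij / length_i) / total_j
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(5, 40))
            counts = pd.DataFrame(
                rng.integers(0, 1000, size=(n, 2)) + 1,
                index=pd.Index([f"g{i}" for i in range(n)], name="feature"),
                columns=["s1", "s2"],
            )
            lengths = rng.integers(200, 8000, n)
            ann = _annotation({f"g{i}": int(l) for i, l in enumerate(lengths)})
            cm = CountMatrix(counts, pd.Series("gene", index=counts.index))
            out = em.rpkm(cm, ann)
            totals = counts.sum(axis=0).to_numpy(dtype=float)
            expected = 1e9 * (counts.to_numpy() / lengths[:, None]).sum(axis=0) / totals
            np.testing.assert_allclose(out.sum(axis=0).to_numpy(), expected, rtol=1e-12)


def _two_strain_design():
    rows = []
    for strain in ("A", "B"):
        for age in ("young", "old"):
            for rep in (1, 2):
                rows.append((f"{strain}_{age}_{rep}", strain, age, rep))
    return SampleDesign(pd.DataFrame(rows, columns=["sample", "strain", "age", "replicate"]))


class TestSummarize:
    def _rpkm(self, young_val, old_val):
        design = _two_strain_design()
        data = {}
        for s in design.table["sample"]:
            data[s] = [old_val if "_old_" in s else young_val]
        return pd.DataFrame(data, index=pd.Index(["g1"], name="feature")), design

    def test_hand_ratio(self):
        # mean_old 3.5, mean_young 1.5, offset 0.5 -> log2(4/2) = 1
        rpkm, design = self._rpkm(1.5, 3.5)
        out = em.summarize_expression(rpkm, design, offset=0.5)
        assert out.table["log2_ratio"].to_numpy() == pytest.approx([1.0, 1.0])
        assert set(out.table["direction"]) == {"up"}

    def test_equal_means_flat(self):
        rpkm, design = self._rpkm(2.0, 2.0)
        out = em.summarize_expression(rpkm, design)
        assert (out.table["log2_ratio"] == 0).all()
        assert set(out.table["direction"]) == {"flat"}

    def test_zero_offset_with_zero_mean_rejected(self):
        rpkm, design = self._rpkm(0.0, 3.0)
        with pytest.raises(ValidationError, match="offset"):
            em.summarize_expression(rpkm, design, offset=0.0)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        design = _two_strain_design()
        rpkm = pd.DataFrame(
            rng.gamma(2, 10, size=(30, 8)),
            index=pd.Index([f"g{i}" for i in range(30)], name="feature"),
            columns=design.table["sample"],
        )
        shuffled = rpkm[rng.permutation(rpkm.columns)]
        a = em.summarize_expression(rpkm, design).table
        b = em.summarize_expression(shuffled, design).table
        pd.testing.assert_frame_equal(a, b)

    def test_missing_cell_rejected(self):
        design = _two_strain_design()
        trimmed = SampleDesign(design.table[design.table["sample"] != "A_old_1"])
        trimmed = SampleDesign(trimmed.table[trimmed.table["sample"] != "A_old_2"])
        rpkm = pd.DataFrame(
            np.ones((3, 6)),
            index=pd.Index(["g1", "g2", "g3"], name="feature"),
            columns=trimmed.table["sample"],
        )
        with pytest.raises(ValidationError, match="missing strain x age cell"):
            em.summarize_expression(rpkm, trimmed)


class TestCrossStrainCorrelation:
    def _summary(self, ra, rb):
        from conftest import make_summary_from_ratios

        idx = pd.Index([f"g{i}" for i in range(len(ra))])
        return make_summary_from_ratios(
            {"A": pd.Series(ra, index=idx), "B": pd.Series(rb, index=idx)},
            pd.Series(np.ones(len(ra)), index=idx),
        )

    def test_identical_vectors_r_one(self):
        r, _ = em.cross_strain_correlation(self._summary([1, 2, 3, 4], [1, 2, 3, 4]))
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        r, _ = em.cross_strain_correlation(self._summary([1, 2, 3], [2, 4, 6]))
        assert r == pytest.approx(1.0)

    def test_against_brute_force_covariance_formula(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=25)
        b = 0.4 * a + rng.normal(size=25)
        r, p = em.cross_strain_correlation(self._summary(a, b))
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        r_brute = cov / (a.std() * b.std())
        assert r == pytest.approx(r_brute, abs=1e-12)
        # p from the t distribution with n - 2 df
        import scipy.stats

        t = r_brute * np.sqrt(23 / (1 - r_brute**2))
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t), 23), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            em.cross_strain_correlation(self._summary([1, 1, 1], [1, 2, 3]))


class TestStageVerification:
    def _profiles(self, rng, n=30):
        idx = pd.Index([f"p{i}" for i in range(n)], name="feature")
        return pd.DataFrame(
            {s: rng.normal(2, 1.5, n) for s in ("9-10a", "10b", "12", "14")}, index=idx
        )

    def test_exact_profile_assigned_with_r_one(self):
        profiles = self._profiles(np.random.default_rng(4))
        out = em.verify_stage(profiles["14"], profiles)
        assert out.stage == "14"
        assert out.correlations["14"] == pytest.approx(1.0)
        assert not out.low_confidence

    def test_orthogonal_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(5)
        profiles = self._profiles(rng, n=60)
        noise = pd.Series(rng.normal(size=60), index=profiles.index)
        out = em.verify_stage(noise, profiles)
        assert out.low_confidence
        assert max(abs(r) for r in out.correlations.values()) < em.LOW_CONFIDENCE_R

    def test_noisy_mixture_still_assigned(self):
        rng = np.random.default_rng(6)
        profiles = self._profiles(rng, n=60)
        sample = 0.9 * profiles["14"] + 0.1 * pd.Series(
            rng.normal(2, 1.5, 60), index=profiles.index
        )
        out = em.verify_stage(sample, profiles)
        assert out.stage == "14"

    def test_too_few_shared_genes_rejected(self):
        profiles = self._profiles(np.random.default_rng(7))
        sample = pd.Series([1.0, 2.0], index=["p0", "p1"])
        with pytest.raises(ValidationError, match="shared"):
            em.verify_stage(sample, profiles)
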