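"""Synthetic cohort generator: shapes, distributional limits, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omicspanel.simulate import (
    CohortDesign,
    DesignError,
    LatentFactorSpec,
    LayerSpec,
    PlantedSignal,
    default_design,
    design_from_dict,
    generate_cohort,
    inject_latent_factors,
    loading_for_target_r,
    sample_amino_acid_layer,
    sample_microbiome_layer,
    sample_proteome_layer,
)
from omicspanel.tables import CohortMetadata, FeatureTable


def _meta(groups: dict) -> CohortMetadata:
    rows = []
    i = 0
    for g, n in groups.items():
        for _ in range(n):
            i += 1
            rows.append({"sample_id": f"S{i:03d}", "group": g, "age": 65.0,
                         "sex": "male", "bmi": 25.0, "smoking": "never"})
    return CohortMetadata(pd.DataFrame(rows).set_index("sample_id"))


class TestDesignValidation:
    def test_unknown_layer_in_planted(self):
        d = default_design(0)
        with pytest.raises(DesignError, match="metabolome"):
            CohortDesign(
                group_sizes=d.group_sizes,
                layers=d.layers,
                planted=[PlantedSignal("metabolome", 0, ("CRC", "control"), 1.0)],
            )

    def test_out_of_range_latent_loading(self):
        d = default_design(0)
        with pytest.raises(DesignError, match="out of range"):
            CohortDesign(
                group_sizes=d.group_sizes,
                layers=d.layers,
                latent_factors=[LatentFactorSpec([("amino_acid", 999, 1.0)])],
            )

    def test_tiny_group_rejected(self):
        d = default_design(0)
        with pytest.raises(DesignError, match=">= 2"):
            CohortDesign(group_sizes={"CRC": 1, "control": 5}, layers=d.layers)

    def test_baseline_length_mismatch(self):
        with pytest.raises(DesignError, match="baseline_profile"):
            LayerSpec("microbiota", 5, np.ones(4), depth_location=5.0)

    def test_design_from_dict_round(self):
        raw = {
            "seed": 3,
            "group_sizes": {"CRC": 5, "control": 6},
            "planted": [
                {"layer": "proteome", "feature_index": 2,
                 "contrast": ["CRC", "control"], "effect_size": 1.0}
            ],
        }
        d = design_from_dict(raw)
        assert d.group_sizes == {"CRC": 5, "control": 6}
        assert d.planted[0].contrast == ("CRC", "control")
        with pytest.raises(DesignError, match="unknown design key"):
            design_from_dict({"seeed": 1})


class TestGenerateCohort:
    def test_default_shapes(self):
        tables, meta, truth = generate_cohort(default_design(1))
        shapes = {t.layer_name: t.values.shape for t in tables}
        assert shapes == {
            "microbiota": (53, 225),
            "proteome": (53, 521),
            "amino_acid": (53, 44),
        }
        assert len(meta.sample_ids) == 53
        for t in tables:
            assert t.sample_ids == meta.sample_ids

    def test_bit_reproducibility(self):
        d = default_design(11)
        t1, m1, _ = generate_cohort(d)
        t2, m2, _ = generate_cohort(default_design(11))
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_value_kinds(self):
        tables, _, _ = generate_cohort(default_design(2))
        by = {t.layer_name: t for t in tables}
        for layer in ("microbiota", "proteome"):
            m = by[layer].matrix
            assert np.all(m >= 0) and np.all(m == np.round(m))
        assert np.all(by["amino_acid"].matrix >= 0)
        # quantified concentrations strictly positive
        aa = by["amino_acid"].matrix
        assert np.all(aa[aa != 0] > 0)

    def test_null_design_welch_calibration(self):
        # no planted effects, no factors: per-feature Welch tests reject ~5%
        d = default_design(5)
        pvals = []
        for seed in range(4):
            tables, meta, _ = generate_cohort(default_design(50 + seed))
            aa = [t for t in tables if t.layer_name == "amino_acid"][0]
            y = (meta.groups == "CRC").to_numpy()
            logs = np.log(np.where(aa.matrix > 0, aa.matrix, np.nan))
            for j in range(aa.n_features):
                col = aa.matrix[:, j]
                a, b = col[y], col[~y]
                if len(a) > 1 and len(b) > 1 and (a.var() + b.var()) > 0:
                    pvals.append(sps.ttest_ind(a, b, equal_var=False).pvalue)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_planted_proteome_power(self):
        # planting a shift of 2 SD at n=100/group is detected essentially always
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            d = design_from_dict(
                {
                    "seed": 200 + seed,
                    "group_sizes": {"CRC": 100, "control": 100},
                    "planted": [
                        {"layer": "amino_acid", "feature_index": 3,
                         "contrast": ["CRC", "control"], "effect_size": 2.0}
                    ],
                }
            )
            tables, meta, _ = generate_cohort(d)
            aa = [t for t in tables if t.layer_name == "amino_acid"][0]
            y = (meta.groups == "CRC").to_numpy()
            col = aa.matrix[:, 3]
            p = sps.ttest_ind(col[y], col[~y], equal_var=False).pvalue
            if p < 0.01:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestMicrobiomeLayer:
    def test_binomial_limit_two_equal_taxa(self):
        # overdispersion 0, fixed depth, 2 equal taxa -> Binomial(N, 0.5)
        N = 400
        spec = LayerSpec("microbiota", 2, np.array([1.0, 1.0]),
                         depth_location=np.log(N), depth_sigma=0.0,
                         overdispersion=0.0)
        meta = _meta({"CRC": 500, "control": 500})
        t = sample_microbiome_layer(spec, meta, [], np.random.default_rng(0))
        counts = t.matrix[:, 0]
        se = np.sqrt(N * 0.25 / len(counts))
        assert abs(counts.mean() - N * 0.5) < 3 * se
        # totals exactly N at depth_sigma 0
        assert np.all(t.matrix.sum(1) == N)

    def test_zero_effect_groups_equal(self):
        spec = LayerSpec("microbiota", 10, np.ones(10),
                         depth_location=np.log(2000), depth_sigma=0.1,
                         overdispersion=0.0)
        meta = _meta({"CRC": 150, "control": 150})
        planted = [PlantedSignal("microbiota", 0, ("CRC", "control"), 0.0)]
        t = sample_microbiome_layer(spec, meta, planted, np.random.default_rng(1))
        props = t.matrix / t.matrix.sum(1, keepdims=True)
        y = (meta.groups == "CRC").to_numpy()
        a, b = props[y, 0], props[~y, 0]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_depth_median_near_default(self):
        d = default_design(21)
        spec = d.layers[0]
        meta = _meta({"CRC": 250, "control": 250})
        t = sample_microbiome_layer(spec, meta, [], np.random.default_rng(2))
        med = np.median(t.matrix.sum(1))
        assert abs(med - 23041) / 23041 < 0.10

    def test_planted_log_fold_effect_shifts_composition(self):
        spec = LayerSpec("microbiota", 4, np.ones(4),
                         depth_location=np.log(5000), depth_sigma=0.0,
                         overdispersion=0.0)
        meta = _meta({"CRC": 200, "control": 200})
        planted = [PlantedSignal("microbiota", 0, ("CRC", "control"), np.log(2.0))]
        t = sample_microbiome_layer(spec, meta, planted, np.random.default_rng(3))
        props = t.matrix / t.matrix.sum(1, keepdims=True)
        y = (meta.groups == "CRC").to_numpy()
        # baseline 1/4 -> with doubling before renormalization: 2/5
        assert props[y, 0].mean() == pytest.approx(0.4, abs=0.01)
        assert props[~y, 0].mean() == pytest.approx(0.25, abs=0.01)


class TestProteomeLayer:
    def test_binomial_mean(self):
        p = 0.03
        base = np.full(4, p)
        spec = LayerSpec("proteome", 4, base, depth_location=np.log(1000),
                         depth_sigma=0.0, overdispersion=0.0)
        meta = _meta({"CRC": 1000, "control": 1000})
        t = sample_proteome_layer(spec, meta, [], np.random.default_rng(4))
        counts = t.matrix[:, 0]
        n = 1000
        se = np.sqrt(n * p * (1 - p) / len(counts))
        assert abs(counts.mean() - n * p) < 3 * se

    def test_detected_median_near_169(self):
        d = default_design(31)
        spec = d.layers[1]
        meta = _meta({"CRC": 27, "control": 26})
        t = sample_proteome_layer(spec, meta, [], np.random.default_rng(5))
        detected = (t.matrix > 0).sum(1)
        assert 120 <= np.median(detected) <= 220

    def test_planted_proportion_ratio(self):
        base = np.full(3, 0.01)
        spec = LayerSpec("proteome", 3, base, depth_location=np.log(3000),
                         depth_sigma=0.0, overdispersion=0.0)
        meta = _meta({"CRC": 200, "control": 200})
        planted = [PlantedSignal("proteome", 1, ("CRC", "control"), np.log(2.0))]
        t = sample_proteome_layer(spec, meta, planted, np.random.default_rng(6))
        y = (meta.groups == "CRC").to_numpy()
        props = t.matrix / 3000.0
        ratio = props[y, 1].mean() / props[~y, 1].mean()
        assert 1.8 <= ratio <= 2.2


class TestAminoAcidLayer:
    def test_zero_effect_log_means_equal(self):
        spec = LayerSpec("amino_acid", 5, np.full(5, 10.0),
                         log_sigma=np.full(5, 0.4))
        meta = _meta({"CRC": 200, "control": 200})
        t = sample_amino_acid_layer(spec, meta, [], np.random.default_rng(7))
        y = (meta.groups == "CRC").to_numpy()
        la, lb = np.log(t.matrix[y, 0]), np.log(t.matrix[~y, 0])
        se = np.sqrt(la.var(ddof=1) / len(la) + lb.var(ddof=1) / len(lb))
        assert abs(la.mean() - lb.mean()) < 3 * se

    def test_quantified_median_near_26(self):
        d = default_design(41)
        spec = d.layers[2]
        meta = _meta({"CRC": 27, "control": 26})
        t = sample_amino_acid_layer(spec, meta, [], np.random.default_rng(8))
        quant = (t.matrix > 0).sum(1)
        assert 20 <= np.median(quant) <= 32

    def test_planted_log_shift_recovered(self):
        sigma = 0.5
        delta_sd = 1.2  # standardized shift
        spec = LayerSpec("amino_acid", 3, np.full(3, 20.0),
                         log_sigma=np.full(3, sigma))
        meta = _meta({"CRC": 200, "control": 200})
        planted = [PlantedSignal("amino_acid", 2, ("CRC", "control"), delta_sd)]
        t = sample_amino_acid_layer(spec, meta, planted, np.random.default_rng(9))
        y = (meta.groups == "CRC").to_numpy()
        la, lb = np.log(t.matrix[y, 2]), np.log(t.matrix[~y, 2])
        diff = la.mean() - lb.mean()
        se = np.sqrt(la.var(ddof=1) / len(la) + lb.var(ddof=1) / len(lb))
        assert abs(diff - delta_sd * sigma) < 3 * se

    def test_negative_variance_rejected(self):
        with pytest.raises(DesignError, match="log_sigma"):
            LayerSpec("amino_acid", 2, np.ones(2), log_sigma=np.array([0.5, -0.1]))


class TestLatentFactors:
    @staticmethod
    def _conc_table(rng, n, sd, name="amino_acid", prefix="AA"):
        vals = rng.normal(50.0, sd, size=(n, 3)).clip(1.0)
        df = pd.DataFrame(vals, index=[f"S{i}" for i in range(n)],
                          columns=[f"{prefix}{j}" for j in range(3)])
        return FeatureTable(name, df, "concentration")

    def test_target_r_06_recovered(self):
        n = 60
        rng = np.random.default_rng(10)
        t = self._conc_table(rng, n, sd=5.0)
        lam0 = loading_for_target_r(t.matrix[:, 0].std(ddof=1), 0.6)
        lam1 = loading_for_target_r(t.matrix[:, 1].std(ddof=1), 0.6)
        fac = LatentFactorSpec([("amino_acid", 0, lam0), ("amino_acid", 1, lam1)])
        out, edges = inject_latent_factors([t], [fac], np.random.default_rng(11))
        assert edges.iloc[0]["expected_r"] == pytest.approx(0.6, abs=0.01)
        r = np.corrcoef(out[0].matrix[:, 0], out[0].matrix[:, 1])[0, 1]
        assert 0.45 <= r <= 0.75  # Fisher-z interval for r=0.6, n=60

    def test_zero_variance_factor_leaves_tables_unchanged(self):
        rng = np.random.default_rng(12)
        t = self._conc_table(rng, 30, sd=4.0)
        fac = LatentFactorSpec([("amino_acid", 0, 2.0), ("amino_acid", 1, 2.0)],
                               factor_variance=0.0)
        out, edges = inject_latent_factors([t], [fac], np.random.default_rng(13))
        pd.testing.assert_frame_equal(out[0].values, t.values)
        assert (edges["expected_r"] == 0.0).all()

    def test_disjoint_factors_uncorrelated(self):
        rng = np.random.default_rng(14)
        t = self._conc_table(rng, 2000, sd=5.0)
        sd = 5.0
        lam = loading_for_target_r(sd, 0.5)
        f1 = LatentFactorSpec([("amino_acid", 0, lam)])
        f2 = LatentFactorSpec([("amino_acid", 1, lam)])
        out, edges = inject_latent_factors([t], [f1, f2], np.random.default_rng(15))
        assert edges.empty  # no within-factor pairs
        r = np.corrcoef(out[0].matrix[:, 0], out[0].matrix[:, 1])[0, 1]
        assert abs(r) < 0.08

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(16)
        t = self._conc_table(rng, 10, sd=2.0)
        fac = LatentFactorSpec([("amino_acid", 99, 1.0)])
        with pytest.raises(DesignError, match="out of range"):
            inject_latent_factors([t], [fac], np.random.default_rng(0))

    def test_closed_form_r_converges_fisher_z(self):
        # n = 2000: empirical r within the 1% Fisher-z band of expected r
        n = 2000
        rng = np.random.default_rng(17)
        t = self._conc_table(rng, n, sd=6.0)
        sd0 = t.matrix[:, 0].std(ddof=1)
        sd1 = t.matrix[:, 1].std(ddof=1)
        lam0 = loading_for_target_r(sd0, 0.5)
        lam1 = loading_for_target_r(sd1, 0.5)
        fac = LatentFactorSpec([("amino_acid", 0, lam0), ("amino_acid", 1, lam1)])
        out, edges = inject_latent_factors([t], [fac], np.random.default_rng(18))
        expected = edges.iloc[0]["expected_r"]
        r = np.corrcoef(out[0].matrix[:, 0], out[0].matrix[:, 1])[0, 1]
        z = (np.arctanh(r) - np.arctanh(expected)) * np.sqrt(n - 3)
        assert abs(z) < sps.norm.ppf(0.995)
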