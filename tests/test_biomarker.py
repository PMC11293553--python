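"""Random-forest protocol, attribution local accuracy and directional scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmgas.attribution import forest_attributions
from panmgas.biomarker import (
    ClassifierSpec,
    balanced_cohort,
    cross_cohort_validate,
    directional_shap,
    train_evaluate,
)
from panmgas.datatypes import AbundanceMatrix, SampleMetadata
from panmgas.quantify import QuantifyParams, downsize_counts, msp_abundance, to_relative
from panmgas.simulate import simulate_catalog, simulate_counts

from conftest import two_cohort_config


def quantified(cfg):
    cat = simulate_catalog(cfg)
    counts, md, truth = simulate_counts(cat, cfg)
    p = QuantifyParams(target_depth=cfg.depth_minimum, seed=cfg.seed)
    down, _ = downsize_counts(counts, p)
    return to_relative(msp_abundance(down, cat, p)), md, truth


class TestBalancedCohort:
    def _metadata(self, n_disease, n_healthy):
        rows = []
        for i in range(n_disease + n_healthy):
            sick = i < n_disease
            rows.append({
                "sample_id": f"s{i:03d}",
                "cohort_id": "coh_d" if sick else "coh_h",
                "country": "SE",
                "region_class": "western",
                "status": "diseased" if sick else "healthy",
                "disease_label": "CRC" if sick else "",
            })
        return SampleMetadata(pd.DataFrame(rows))

    def _abundance(self, n_samples, n_msps=5, seed=0):
        rng = np.random.default_rng(seed)
        arr = rng.lognormal(0, 1, (n_msps, n_samples))
        df = pd.DataFrame(arr / arr.sum(0), index=[f"m{i}" for i in range(n_msps)],
                          columns=[f"s{i:03d}" for i in range(n_samples)])
        return AbundanceMatrix(df, scale="relative")

    def test_larger_group_subsampled(self):
        X, y = balanced_cohort(self._abundance(200), self._metadata(80, 120), "CRC")
        assert (y == 1).sum() == 80 and (y == 0).sum() == 80

    def test_already_balanced_unchanged(self):
        X, y = balanced_cohort(self._abundance(160), self._metadata(80, 80), "CRC")
        assert len(y) == 160

    def test_same_seed_same_selection(self):
        ab, md = self._abundance(200), self._metadata(80, 120)
        X1, y1 = balanced_cohort(ab, md, "CRC", seed=4)
        X2, y2 = balanced_cohort(ab, md, "CRC", seed=4)
        assert list(X1.index) == list(X2.index)

    def test_small_group_warns(self, caplog):
        with caplog.at_level("WARNING", logger="panmgas"):
            balanced_cohort(self._abundance(20), self._metadata(8, 12), "CRC")
        assert "overfitting" in caplog.text


class TestTrainEvaluate:
    def test_perfectly_separable_feature(self):
        n = 60
        X = pd.DataFrame({
            "sep": np.r_[np.ones(n // 2), np.zeros(n // 2)],
            "noise": np.random.default_rng(0).random(n),
        }, index=[f"s{i}" for i in range(n)])
        y = pd.Series(np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int), index=X.index)
        h = train_evaluate(X, y, ClassifierSpec(n_trees=50, seed=1))
        assert h.auroc_test == 1.0

    def test_null_labels_give_chance_auroc(self):
        """Mean held-out AUROC over label-independent datasets sits near 0.5."""
        scores = []
        rng = np.random.default_rng(2)
        for rep in range(15):
            X = pd.DataFrame(rng.lognormal(0, 1, (60, 10)),
                             index=[f"s{i}" for i in range(60)])
            X.columns = [str(c) for c in X.columns]
            y = pd.Series(np.r_[np.ones(30), np.zeros(30)].astype(int), index=X.index)
            h = train_evaluate(X, y, ClassifierSpec(n_trees=100, seed=rep))
            scores.append(h.auroc_test)
        assert 0.4 <= float(np.mean(scores)) <= 0.6

    def test_single_class_is_fatal(self):
        X = pd.DataFrame(np.random.default_rng(1).random((10, 3)),
                         index=[f"s{i}" for i in range(10)])
        X.columns = [str(c) for c in X.columns]
        y = pd.Series(np.ones(10, dtype=int), index=X.index)
        with pytest.raises(ValueError, match="single class"):
            train_evaluate(X, y, ClassifierSpec(n_trees=10, seed=0))

    def test_deterministic_given_seed(self):
        cfg = two_cohort_config(seed=51, n_msps=15, n_per=25, planted=3,
                                genes_per_msp=20)
        rel, md, _ = quantified(cfg)
        X, y = balanced_cohort(rel, md, "CRC", seed=51)
        h1 = train_evaluate(X, y, ClassifierSpec(n_trees=80, seed=51))
        h2 = train_evaluate(X, y, ClassifierSpec(n_trees=80, seed=51))
        assert h1.auroc_test == h2.auroc_test
        s1, s2 = directional_shap(h1), directional_shap(h2)
        pd.testing.assert_frame_equal(s1, s2)


class TestAttribution:
    def test_local_accuracy(self):
        cfg = two_cohort_config(seed=52, n_msps=12, n_per=20, planted=2,
                                genes_per_msp=20)
        rel, md, _ = quantified(cfg)
        X, y = balanced_cohort(rel, md, "CRC", seed=52)
        h = train_evaluate(X, y, ClassifierSpec(n_trees=60, seed=52))
        attr, base = forest_attributions(h.model, h.X_scaled)
        proba = h.model.predict_proba(h.X_scaled)[:, 1]
        np.testing.assert_allclose(base + attr.sum(axis=1), proba, atol=1e-6)


class TestDirectionalScore:
    def test_planted_biomarkers_recovered_with_sign(self):
        cfg = two_cohort_config(seed=53, n_msps=20, n_per=50, planted=3, fold=4.0,
                                genes_per_msp=20)
        rel, md, truth = quantified(cfg)
        X, y = balanced_cohort(rel, md, "CRC", seed=53)
        h = train_evaluate(X, y, ClassifierSpec(n_trees=200, seed=53))
        scores = directional_shap(h)
        planted = {e.msp_id for e in truth.disease_effects}
        top = set(scores.head(6)["msp_id"])
        assert planted <= top
        assert (scores.set_index("msp_id").loc[sorted(planted), "D"] > 0).all()

    def test_monotone_attribution_signs(self):
        """The directional score equals mean |attribution| signed by the
        Spearman correlation between feature values and attributions."""
        rng = np.random.default_rng(7)
        n = 80
        f = rng.normal(0, 1, n)
        X = pd.DataFrame({"up": f, "noise": rng.normal(0, 1, n)},
                         index=[f"s{i}" for i in range(n)])
        y = pd.Series((f > 0).astype(int), index=X.index)
        h = train_evaluate(X, y, ClassifierSpec(n_trees=100, seed=7))
        scores = directional_shap(h).set_index("msp_id")
        assert scores.at["up", "sign"] == 1
        assert scores.at["up", "D"] == pytest.approx(
            scores.at["up", "mean_abs_attribution"]
        )

    def test_constant_feature_gets_zero(self):
        rng = np.random.default_rng(8)
        n = 60
        f = rng.normal(0, 1, n)
        X = pd.DataFrame({"live": f, "const": np.ones(n)},
                         index=[f"s{i}" for i in range(n)])
        y = pd.Series((f > 0).astype(int), index=X.index)
        h = train_evaluate(X, y, ClassifierSpec(n_trees=50, seed=8))
        scores = directional_shap(h).set_index("msp_id")
        assert scores.at["const", "D"] == 0.0


class TestCrossCohort:
    def _two_cohorts(self, seed, fold=4.0):
        cfg1 = two_cohort_config(seed=seed, n_msps=15, n_per=80, planted=5,
                                 fold=fold, genes_per_msp=20)
        cfg2 = two_cohort_config(seed=seed + 1000, n_msps=15, n_per=80, planted=5,
                                 fold=fold, genes_per_msp=20)
        rel1, md1, _ = quantified(cfg1)
        rel2, md2, _ = quantified(cfg2)
        X1, y1 = balanced_cohort(rel1, md1, "CRC", seed=seed)
        X2, y2 = balanced_cohort(rel2, md2, "CRC", seed=seed)
        h = train_evaluate(X1, y1, ClassifierSpec(n_trees=200, seed=seed))
        return h, X2, y2

    def test_same_effects_transfer(self):
        h, X2, y2 = self._two_cohorts(seed=54)
        out = cross_cohort_validate(h, X2, y2, repeats=5, seed=54)
        assert out["auroc"] >= 0.85
        assert "auroc_mean" in out and "auroc_sd" in out

    def test_effectless_external_cohort_is_chance(self):
        h, _, _ = self._two_cohorts(seed=55)
        cfg_null = two_cohort_config(seed=2055, n_msps=15, n_per=40, planted=0,
                                     genes_per_msp=20)
        rel, md, _ = quantified(cfg_null)
        Xn, yn = balanced_cohort(rel, md, "CRC", seed=55)
        out = cross_cohort_validate(h, Xn, yn)
        assert 0.35 <= out["auroc"] <= 0.65

    def test_label_flip_antisymmetry(self):
        h, X2, y2 = self._two_cohorts(seed=56)
        a = cross_cohort_validate(h, X2, y2)["auroc"]
        b = cross_cohort_validate(h, X2, 1 - y2)["auroc"]
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_missing_features_imputed_zero(self, caplog):
        h, X2, y2 = self._two_cohorts(seed=57)
        with caplog.at_level("WARNING", logger="panmgas"):
            out = cross_cohort_validate(h, X2.drop(columns=X2.columns[:3]), y2)
        assert "imputed 0" in caplog.text
        assert 0.0 <= out["auroc"] <= 1.0

    def test_disjoint_feature_space_fatal(self):
        h, X2, y2 = self._two_cohorts(seed=58)
        renamed = X2.rename(columns={c: f"other_{c}" for c in X2.columns})
        with pytest.raises(ValueError, match="no shared features"):
            cross_cohort_validate(h, renamed, y2)
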