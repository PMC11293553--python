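"""Wilcoxon effect sizes, cohort association calls and frequency rules."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from panmgas.association import (
    classify_frequency,
    cohort_association,
    default_pairing,
    wilcoxon_effect_size,
)
from panmgas.datatypes import AbundanceMatrix
from panmgas.quantify import QuantifyParams, downsize_counts, msp_abundance, to_relative
from panmgas.simulate import simulate_catalog, simulate_counts

from conftest import rel_abundance_from, two_cohort_config


def exact_rank_p(x, y, alternative="greater"):
    """Independent oracle: one-sided rank-sum p by enumerating every
    assignment of the pooled ranks to the first group (no ties)."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    stats_all = [
        sum(sorted(ranks.values())[i] for i in comb)
        for comb in combinations(range(n), len(x))
    ]
    if alternative == "greater":
        hits = sum(w >= w_obs for w in stats_all)
    else:
        hits = sum(w <= w_obs for w in stats_all)
    return hits / len(stats_all)


class TestWilcoxonEffectSize:
    def test_textbook_exact_case(self):
        p, z, es = wilcoxon_effect_size([4, 5, 6], [1, 2, 3], "greater")
        assert p == pytest.approx(1 / 20)
        assert es == pytest.approx(stats.norm.isf(0.05) / np.sqrt(6), abs=1e-12)

    def test_matches_enumeration_oracle_small(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(2, 5, 2)
            vals = rng.choice(100, size=n1 + n2, replace=False).astype(float)
            x, y = vals[:n1], vals[n1:]
            for alt in ("greater", "less"):
                p, _, _ = wilcoxon_effect_size(x, y, alt)
                assert p == pytest.approx(exact_rank_p(x, y, alt), abs=1e-10)

    def test_full_ties_give_zero_effect(self):
        p, z, es = wilcoxon_effect_size([3, 3, 3], [3, 3, 3], "greater")
        assert (p, z, es) == (0.5, 0.0, 0.0)

    def test_group_swap_with_flipped_alternative_is_identical(self):
        x, y = [1.0, 4.0, 2.5], [3.0, 0.5, 5.0, 2.0]
        assert wilcoxon_effect_size(x, y, "greater") == pytest.approx(
            wilcoxon_effect_size(y, x, "less")
        )

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="N >= 4"):
            wilcoxon_effect_size([1.0], [2.0, 3.0], "greater")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=8),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=8),
        st.floats(0.1, 50),
    )
    def test_monotone_in_location_shift(self, x, y, shift):
        """Adding a constant to every disease value never decreases the
        enrichment effect size."""
        _, _, es0 = wilcoxon_effect_size(x, y, "greater")
        _, _, es1 = wilcoxon_effect_size([v + shift for v in x], y, "greater")
        assert es1 >= es0 - 1e-12


class TestCohortAssociation:
    def test_planted_effect_recovered(self, small_dataset):
        cfg, (cat, counts, md, ann, truth) = small_dataset
        p = QuantifyParams(target_depth=10_000, seed=cfg.seed)
        down, _ = downsize_counts(counts, p)
        rel = to_relative(msp_abundance(down, cat, p))
        assoc = cohort_association(rel, md)
        planted = {e.msp_id for e in truth.disease_effects}
        found = set().union(*assoc.enriched.values())
        assert len(found & planted) >= 3  # fold-4 signal at n=30/30

    def test_all_zero_msp_skipped(self, small_dataset):
        cfg, (cat, counts, md, ann, truth) = small_dataset
        p = QuantifyParams(target_depth=10_000, seed=cfg.seed)
        down, _ = downsize_counts(counts, p)
        rel = to_relative(msp_abundance(down, cat, p))
        dead = rel.values.copy()
        dead.loc["msp_0029"] = 0.0
        dead = dead / dead.sum(axis=0)
        assoc = cohort_association(AbundanceMatrix(dead, scale="relative"), md)
        for cohort, skipped in assoc.skipped.items():
            assert "msp_0029" in skipped
        assert "msp_0029" not in set(assoc.effect_sizes["msp_id"])

    def test_cohort_without_controls_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        ab = rel_abundance_from(rng.lognormal(0, 1, (5, 10)))
        import pandas as pd
        from panmgas.datatypes import SampleMetadata
        md = SampleMetadata(pd.DataFrame(
            {
                "sample_id": ab.sample_ids,
                "cohort_id": ["coh_d"] * 10,
                "country": ["SE"] * 10,
                "region_class": ["western"] * 10,
                "status": ["diseased"] * 10,
                "disease_label": ["CRC"] * 10,
            }
        ))
        with caplog.at_level("WARNING", logger="panmgas"):
            pairing = default_pairing(md)
        assert pairing == {}
        assert "no healthy cohort" in caplog.text

    def test_label_permutation_removes_common_labels(self):
        """Permuting health status labels nulls the planted signal: no
        common_* label survives in >= 95% of permuted runs."""
        cfg = two_cohort_config(seed=31, n_msps=10, n_per=30, planted=3,
                                genes_per_msp=20)
        cat = simulate_catalog(cfg)
        counts, md, _ = simulate_counts(cat, cfg)
        p = QuantifyParams(target_depth=10_000, seed=31)
        down, _ = downsize_counts(counts, p)
        rel = to_relative(msp_abundance(down, cat, p))
        clean = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            shuffled = md.table.copy()
            perm = rng.permutation(len(shuffled))
            for col in ("cohort_id", "status", "disease_label"):
                shuffled[col] = shuffled[col].to_numpy()[perm]
            from panmgas.datatypes import SampleMetadata
            md_perm = SampleMetadata(shuffled.reset_index())
            assoc = cohort_association(rel, md_perm)
            freq = classify_frequency(assoc.enriched, assoc.depleted)
            if len(freq) == 0 or (freq["label"] == "none").all():
                clean += 1
        assert clean >= 9


class TestClassifyFrequency:
    @pytest.mark.parametrize(
        "n_e,n_d,label",
        [
            (4, 1, "common_enriched"),
            (2, 2, "none"),
            (0, 3, "common_depleted"),
            (3, 0, "common_enriched"),
            (2, 0, "none"),
        ],
    )
    def test_rule_examples(self, n_e, n_d, label):
        enriched = {f"ce{i}": {"m"} for i in range(n_e)}
        depleted = {f"cd{i}": {"m"} for i in range(n_d)}
        out = classify_frequency(enriched, depleted)
        assert out.loc[0, "label"] == label
        assert out.loc[0, "total_frequency"] == n_e + n_d
        assert out.loc[0, "subtracted_frequency"] == n_e - n_d

    def test_rule_matches_predicate_exhaustively(self):
        """label == common_enriched iff total >= 3 and subtracted >= 2 (and
        the mirrored rule for depleted) for all (e, d) in [0, 10]^2."""
        for e in range(11):
            for d in range(11):
                if e + d == 0:
                    continue
                enriched = {f"ce{i}": {"m"} for i in range(e)}
                depleted = {f"cd{i}": {"m"} for i in range(d)}
                got = classify_frequency(enriched, depleted).loc[0, "label"]
                total, sub = e + d, e - d
                if total >= 3 and sub >= 2:
                    expected = "common_enriched"
                elif total >= 3 and sub <= -2:
                    expected = "common_depleted"
                else:
                    expected = "none"
                assert got == expected, (e, d)

    def test_distinct_disease_count(self):
        enriched = {"c1": {"m"}, "c2": {"m"}, "c3": {"m"}}
        labels = {"c1": "CRC", "c2": "CRC", "c3": "T2D"}
        out = classify_frequency(enriched, {}, labels)
        assert out.loc[0, "n_distinct_diseases"] == 2
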