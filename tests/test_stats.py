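"""Correlation, signed-rank, multiplicity and ranking machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from optidens.stats_analysis import (
    METADATA_COLUMNS,
    PARAMETER_COLUMNS,
    bonferroni_adjust,
    breast_averaged,
    configuration_correlations,
    density_ranking,
    paired_config_comparison,
    pearson_with_p,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Full 2^n sign enumeration of the signed-rank distribution."""
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs + 1e-12)
    p_ge = np.mean(sums >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_hand_computed_half(self):
        r, _ = pearson_with_p([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = np.round(rng.standard_normal(n) * 3, 0)
            d = d[d != 0]
            if d.size == 0:
                continue
            w, p = wilcoxon_signed_rank(d, np.zeros_like(d))
            w_bf, p_bf = brute_force_wilcoxon(d)
            assert w == w_bf
            assert p == pytest.approx(p_bf, abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        _, p = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, mode="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60) + 0.5
        y = rng.standard_normal(60)
        _, p = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_swap_symmetry_leaves_p_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        wa, pa = wilcoxon_signed_rank(x, y)
        wb, pb = wilcoxon_signed_rank(y, x)
        n = 9
        assert wa + wb == n * (n + 1) / 2
        assert pa == pytest.approx(pb, abs=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.01, 5, 0.05), (0.5, 5, 1.0), (0.03, 1, 0.03)])
    def test_definition_and_cap(self, p, m, expected):
        assert bonferroni_adjust([p], m)[0] == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=10))
    def test_monotone_and_idempotent_at_cap(self, ps):
        adj = bonferroni_adjust(ps, 4)
        assert np.all(adj >= np.asarray(ps))
        assert np.all(bonferroni_adjust(adj, 1) == adj)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], 2)


def make_table(n_subjects=8, seed=0, identical_across_configs=False):
    """Small synthetic parameter table covering every protocol configuration."""
    rng = np.random.default_rng(seed)
    subject_level = {f"S{i:02d}": rng.random(len(PARAMETER_COLUMNS)) + 0.5 for i in range(n_subjects)}
    configs = [("sitting", "C", 2.0, "reflectance"), ("sitting", "C", 3.0, "reflectance"),
               ("sitting", "CC", np.nan, "transmittance")]
    configs += [("supine", p, d, "reflectance") for p in "OLI" for d in (2.0, 3.0)]
    rows = []
    for sid, base in subject_level.items():
        for breast in "RL":
            for posture, position, dist, mode in configs:
                values = base if identical_across_configs else base * (1 + 0.05 * rng.standard_normal(len(base)))
                rows.append(
                    dict(zip(METADATA_COLUMNS, [sid, breast, posture, position, dist, mode]))
                    | dict(zip(PARAMETER_COLUMNS, values))
                )
    return pd.DataFrame(rows)


class TestConfigurationCorrelations:
    def test_identity_data_gives_unit_correlations(self):
        table = make_table(identical_across_configs=True)
        report = configuration_correlations(table)
        assert np.allclose(report["r"], 1.0)

    def test_report_shape_is_seven_by_four(self):
        report = configuration_correlations(make_table())
        assert len(report) == 28
        assert report["m_family"].iloc[0] == 28
        assert set(report["parameter"]) == {"tHb", "SO2", "lipids", "water", "collagen", "a", "b"}

    def test_invariant_to_row_order_and_unit_rescaling(self):
        table = make_table()
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        rescaled = shuffled.copy()
        rescaled["water"] = rescaled["water"] * 1000.0  # unit change
        r0 = configuration_correlations(table)["r"].to_numpy()
        r1 = configuration_correlations(rescaled)["r"].to_numpy()
        np.testing.assert_allclose(r0, r1, atol=1e-12)

    def test_missing_configuration_rejected(self):
        table = make_table()
        with pytest.raises(ValueError, match="no rows"):
            configuration_correlations(table[table["mode"] != "transmittance"])


class TestPairedComparison:
    def test_identical_configurations_rejected(self):
        table = make_table()
        cfg = {"posture": "supine", "position": "O", "distance_cm": 3.0}
        with pytest.raises(ValueError, match="zero"):
            paired_config_comparison(table, cfg, cfg, "water")

    def test_swap_symmetry(self):
        table = make_table()
        cfg_a = {"posture": "supine", "position": "O", "distance_cm": 3.0}
        cfg_b = {"posture": "supine", "position": "I", "distance_cm": 3.0}
        wa, pa, _ = paired_config_comparison(table, cfg_a, cfg_b, "water")
        wb, pb, _ = paired_config_comparison(table, cfg_b, cfg_a, "water")
        assert pa == pytest.approx(pb, abs=1e-12)
        assert wa != wb or wa == wb == pytest.approx(len(set(table.subject_id)) * 9 / 4)

    def test_breast_averaging_is_mean_of_sides(self):
        table = make_table()
        avg = breast_averaged(table)
        one = table[(table.subject_id == "S00") & (table.posture == "supine")
                    & (table.position == "O") & (table.distance_cm == 3.0)]
        got = avg[(avg.subject_id == "S00") & (avg.posture == "supine")
                  & (avg.position == "O") & (avg.distance_cm == 3.0)]["water"].iloc[0]
        assert got == pytest.approx(one["water"].mean())


class TestDensityRanking:
    def test_reference_column_concordant_with_itself(self):
        table = make_table()
        result = density_ranking(table)
        conc = result["concordance"]
        ref_cell = conc[
            (conc.parameter == "OI") & (conc.breast == "R") & (conc.posture == "supine")
            & (conc.position == "O") & (conc.distance_cm == 3.0)
        ]
        assert ref_cell["concordance"].iloc[0] == pytest.approx(1.0)

    def test_order_is_ascending_reference_oi(self):
        table = make_table()
        result = density_ranking(table)
        sel = (table.posture == "supine") & (table.breast == "R") & (table.position == "O") \
            & (table.distance_cm == 3.0)
        oi = table[sel].set_index("subject_id")["OI"]
        assert result["order"] == oi.sort_values().index.tolist()

    def test_lipid_polarity_inverted(self):
        """A lipid column exactly anti-ordered to the reference OI scores
        full positive concordance."""
        table = make_table(identical_across_configs=True)
        sel = (table.posture == "supine") & (table.breast == "R") & (table.position == "O") \
            & (table.distance_cm == 3.0)
        ref_oi = table[sel].set_index("subject_id")["OI"]
        table = table.copy()
        table["lipids"] = -table["subject_id"].map(ref_oi)
        result = density_ranking(table)
        conc = result["concordance"]
        assert np.allclose(conc[conc.parameter == "lipids"]["concordance"], 1.0)

    def test_kendall_variant_runs(self):
        result = density_ranking(make_table(), method="kendall")
        assert np.isfinite(result["concordance"]["concordance"]).all()

    def test_missing_reference_rejected(self):
        table = make_table()
        trimmed = table[~((table.subject_id == "S00") & (table.breast == "R")
                          & (table.position == "O") & (table.distance_cm == 3.0)
                          & (table.posture == "supine"))]
        with pytest.raises(ValueError, match="missing"):
            density_ranking(trimmed)
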