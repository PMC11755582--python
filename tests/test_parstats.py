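"""PAR algebra and the statistical workflow against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from fasciatrack import (
    build_reports,
    compute_par,
    mann_whitney_u,
    mauchly_test,
    paired_t,
    par_from_table,
    rm_anova,
    simulate_par_cohort,
)
from oracles import (
    mann_whitney_exact_p,
    mauchly_by_hand,
    mixed_anova_by_hand,
    paired_t_by_hand,
)


class TestComputePar:
    def test_identical_proportions_give_zero(self):
        assert compute_par(4.0, 8.0, 5.0, 4.0, 8.0, 5.0) == 0.0

    def test_closed_form_half_minus_third(self):
        # rest (1,1,1), contracted TrA doubles: 2/4 - 1/3
        assert compute_par(1, 1, 1, 2, 1, 1) == pytest.approx(1 / 2 - 1 / 3)

    def test_group_mean_adim_value(self):
        assert compute_par(4.61, 9.34, 5.22, 5.44, 10.57, 5.40) == pytest.approx(
            0.0136, abs=1e-4
        )

    def test_scale_invariance(self, rng):
        x = rng.uniform(1.0, 12.0, size=6)
        for c in (0.5, 3.0, 100.0):
            assert compute_par(*(c * x)) == pytest.approx(compute_par(*x))

    def test_proportional_thickening_gives_zero(self, rng):
        x = rng.uniform(2.0, 10.0, size=3)
        assert compute_par(x[0], x[1], x[2], 1.3 * x[0], 1.3 * x[1], 1.3 * x[2]) == (
            pytest.approx(0.0)
        )

    def test_monotonic_in_contracted_tra(self):
        base = compute_par(4, 9, 5, 5, 10, 5.5)
        assert compute_par(4, 9, 5, 5.5, 10, 5.5) > base
        assert compute_par(4, 9, 5, 5, 10.5, 5.5) < base
        assert compute_par(4, 9, 5, 5, 10, 6.0) < base

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError, match="oi_contracted"):
            compute_par(4, 9, 5, 5, 0.0, 5.5)

    def test_vectorized_matches_table_helper(self, rng):
        df = pd.DataFrame(
            rng.uniform(2, 12, size=(10, 6)),
            columns=["OE_R", "OI_R", "TrA_R", "OE_C", "OI_C", "TrA_C"],
        )
        expected = [
            compute_par(r.TrA_R, r.OI_R, r.OE_R, r.TrA_C, r.OI_C, r.OE_C)
            for r in df.itertuples()
        ]
        assert np.allclose(par_from_table(df), expected)


class TestPairedT:
    def test_symmetric_differences_give_zero_t(self):
        rep = paired_t([2.0, 1.0, 2.0, 1.0], [1.0, 2.0, 1.0, 2.0])
        assert rep.statistic == pytest.approx(0.0)

    def test_constant_difference_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_five_pair_example_matches_hand_formula(self):
        a = [5.1, 4.8, 6.0, 5.5, 5.9]
        b = [4.9, 5.0, 5.2, 5.6, 5.1]
        rep = paired_t(a, b)
        t, p, d = paired_t_by_hand(a, b)
        assert rep.statistic == pytest.approx(t, abs=1e-12)
        assert rep.p_value == pytest.approx(p, abs=1e-12)
        assert rep.effect_size == pytest.approx(d, abs=1e-12)
        assert rep.df == (4.0,)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        rep = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert rep.statistic == 0.0

    def test_identical_samples_give_half_n_squared(self):
        rep = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == pytest.approx(4.5)  # 3*3/2

    def test_exact_p_matches_enumeration_4v4(self):
        a = [1.2, 3.4, 2.2, 5.0]
        b = [2.0, 4.1, 6.3, 7.2]
        rep = mann_whitney_u(a, b)
        assert rep.extra["method"] == "exact"
        assert rep.p_value == pytest.approx(mann_whitney_exact_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestMauchly:
    def test_two_levels_trivially_spherical(self):
        df = pd.DataFrame({
            "participant": list("aabb"), "repetition": [1, 2, 1, 2],
            "PAR": [0.1, 0.2, 0.15, 0.25],
        })
        rep = mauchly_test(df)
        assert rep.extra["W"] == 1.0
        assert rep.p_value == 1.0
        assert rep.extra["trivial"]

    def test_matches_hand_computation(self, rng):
        n, k = 15, 3
        wide = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        df = pd.DataFrame(wide, columns=[1, 2, 3]).assign(participant=range(n))
        long = df.melt(id_vars="participant", var_name="repetition", value_name="PAR")
        rep = mauchly_test(long)
        w, chi2, dof, p = mauchly_by_hand(wide)
        assert rep.extra["W"] == pytest.approx(w, abs=1e-3)
        assert rep.statistic == pytest.approx(chi2, abs=1e-3)
        assert rep.df == (float(dof),)
        assert rep.p_value == pytest.approx(p, abs=1e-3)

    def test_compound_symmetry_rarely_rejected(self, rng):
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            subject = rng.normal(0, 1, size=(20, 1))
            wide = subject + rng.normal(0, 1, size=(20, 3))
            df = pd.DataFrame(wide, columns=[1, 2, 3]).assign(participant=range(20))
            long = df.melt(id_vars="participant", var_name="repetition", value_name="PAR")
            if mauchly_test(long).p_value <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.10


class TestMixedAnova:
    def test_all_equal_values_give_zero_f(self):
        df = pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(6)], 3),
            "group": np.repeat(["RUSI", "Palpation"], 9),
            "repetition": list(range(1, 4)) * 6,
            "PAR": 0.02,
        })
        rep = rm_anova(df)
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_matches_hand_sums_of_squares(self, rng):
        df = simulate_par_cohort(rng, n_per_group=8, group_effect=0.02)
        rep = rm_anova(df)
        hand = mixed_anova_by_hand(df, "PAR", "repetition", "group", "participant")
        assert rep.statistic == pytest.approx(hand["F_interaction"], abs=1e-3)
        assert rep.p_value == pytest.approx(hand["p_interaction"], abs=1e-3)
        assert rep.effect_size == pytest.approx(hand["np2_interaction"], abs=1e-3)
        assert rep.df == hand["df_interaction"]

    def test_reporting_convention_degrees_of_freedom(self, rng):
        # 2 groups x 3 repetitions, 12 per group -> interaction df (2, 44)
        df = simulate_par_cohort(rng)
        rep = rm_anova(df)
        assert rep.df == (2.0, 44.0)

    def test_listwise_deletion_logged(self, rng):
        df = simulate_par_cohort(rng)
        df = df[~((df.participant == "R00") & (df.repetition == 2))]
        rep = rm_anova(df)
        assert rep.extra["n_dropped"] == 1
        assert rep.extra["n_subjects"] == 23

    def test_single_group_rejected(self, rng):
        df = simulate_par_cohort(rng)
        with pytest.raises(ValueError, match="2 groups"):
            rm_anova(df[df.group == "RUSI"])


class TestBuildReports:
    @staticmethod
    def _table(par_values, groups=("RUSI", "Palpation")):
        rows = []
        for pi, (pid_vals) in enumerate(par_values):
            for rep, v in enumerate(pid_vals, start=1):
                rows.append({
                    "participant": f"p{pi}", "group": groups[pi % len(groups)],
                    "exercise": "ADIM", "repetition": rep,
                    "OE_R": 5.0, "OI_R": 9.0, "TrA_R": 4.5,
                    "OE_C": 5.1, "OI_C": 9.5, "TrA_C": 5.0, "PAR": v,
                })
        return pd.DataFrame(rows)

    def test_two_participant_hand_arithmetic(self):
        table = self._table([(0.01, 0.02, 0.03), (0.03, 0.04, 0.05)])
        rep = build_reports(table)["par"]
        pooled = rep[(rep.group == "All participants") & (rep.repetition == "1-3")]
        assert pooled["mean"].iloc[0] == pytest.approx(0.03)
        # SD of the two participant means 0.02 and 0.04
        assert pooled["sd"].iloc[0] == pytest.approx(np.std([0.02, 0.04], ddof=1))
        rep1 = rep[(rep.group == "All participants") & (rep.repetition == "1")]
        assert rep1["mean"].iloc[0] == pytest.approx(0.02)

    def test_single_participant_ci_flagged(self):
        table = self._table([(0.01, 0.02, 0.03)], groups=("RUSI",))
        rep = build_reports(table)["par"]
        pooled = rep[(rep.group == "RUSI") & (rep.repetition == "1-3")]
        assert np.isnan(pooled["ci_low"].iloc[0])
        assert "n=1" in pooled["ci_flag"].iloc[0]

    def test_sampling_distribution_of_pooled_mean(self, rng):
        n = 12
        true_mean, sd = 0.03, 0.03
        par = rng.normal(true_mean, sd, size=(n, 3))
        table = self._table([tuple(row) for row in par])
        rep = build_reports(table)["par"]
        pooled = rep[(rep.group == "All participants") & (rep.repetition == "1-3")]
        se = sd / np.sqrt(n)
        assert abs(pooled["mean"].iloc[0] - true_mean) <= 3 * se

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_reports(pd.DataFrame())

    def test_contrast_table_matches_paired_t(self):
        table = self._table(
            [(0.01, 0.02, 0.03), (0.03, 0.01, 0.05), (0.00, 0.04, 0.02),
             (0.02, 0.05, 0.01)],
            groups=("RUSI",),
        )
        contrasts = build_reports(table)["repetition_contrasts"]
        row = contrasts[contrasts.contrast == "1 vs 2"].iloc[0]
        wide = table.pivot(index="participant", columns="repetition", values="PAR")
        rep = paired_t(wide[1].to_numpy(), wide[2].to_numpy())
        assert row.t == pytest.approx(rep.statistic)
        assert row.d == pytest.approx(rep.effect_size)
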