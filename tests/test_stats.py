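"""Statistics-layer tests: test policy, exactness, recovery, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from motorpool import (
    InsufficientDataError,
    category_distribution_compare,
    compare_groups,
    gen_cohort,
    get_preset,
    rm_anova_interaction,
    si_behavior_regression,
    synapse_compare,
)
from motorpool.stats import holm_correct


def exact_mw_p(a, b):
    """Brute-force two-tailed Mann-Whitney p by enumerating rank assignments."""
    a, b = list(a), list(b)
    combined = sorted(a + b)
    n1 = len(a)

    def u_of(sample_a):
        # U = number of (x in a, y in b) pairs with x > y (ties count 1/2)
        rest = list(combined)
        for x in sample_a:
            rest.remove(x)
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in sample_a for y in rest
        )

    u_obs = u_of(a)
    n = len(combined)
    mu = n1 * (n - n1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = u_of([combined[i] for i in idx])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_exact_mann_whitney_separated_triplets(self):
        gc = compare_groups([1, 2, 3], [4, 5, 6], policy="mann_whitney")
        assert gc.statistic == 0.0
        assert gc.p == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration_on_random_instances(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(3, 6))
            n2 = int(rng.integers(3, 11 - n1))
            a = np.round(rng.normal(size=n1), 2)
            b = np.round(rng.normal(0.5, 1, size=n2), 2)
            if np.unique(np.concatenate([a, b])).size < n1 + n2:
                continue  # enumeration oracle below covers the tie-free null
            gc = compare_groups(a, b, policy="mann_whitney")
            assert gc.p == pytest.approx(exact_mw_p(a, b), abs=1e-9)

    def test_identical_lists_give_p_one(self):
        gc = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gc.p == 1.0
        assert gc.statistic == pytest.approx(0.0)

    def test_constant_identical_groups_degenerate(self):
        gc = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert gc.p == 1.0 and gc.test_used == "degenerate"

    def test_auto_policy_routes_by_normality(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        assert compare_groups(a, b).test_used == "t"
        skewed_a = np.concatenate([np.ones(15) * 0.1, [40.0, 55.0, 70.0]])
        skewed_b = np.concatenate([np.ones(15) * 0.2, [45.0, 60.0, 80.0]])
        assert compare_groups(skewed_a, skewed_b).test_used == "mann_whitney"

    def test_summaries_match_hand_computation(self):
        gc = compare_groups([1.0, 2.0, 3.0], [4.0, 6.0, 8.0], policy="t")
        assert gc.summaries[0]["mean"] == 2.0
        assert gc.summaries[0]["sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert gc.summaries[1]["mean"] == 6.0
        assert gc.summaries[1]["n"] == 3

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [2.0, 3.0])

    def test_p_always_in_unit_interval(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(size=rng.integers(3, 15))
            for policy in ("auto", "t", "mann_whitney"):
                assert 0.0 <= compare_groups(a, b, policy=policy).p <= 1.0


def make_behavior(rng, means_by_group, n_per_group, noise_sd=2.0):
    rows = []
    for g, means in means_by_group.items():
        for a in range(n_per_group):
            for tp, mu in zip((4, 8, 12), means):
                rows.append(
                    dict(
                        animal_id=f"{g}{a}",
                        genotype=g,
                        timepoint_weeks=tp,
                        crossing_time_s=mu + rng.normal(0, noise_sd),
                    )
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_additive_structure_small_interaction(self, rng):
        # constant genotype offset over time: main effect large, interaction ~ null
        df = make_behavior(
            rng, {"wt": (10, 9, 8), "mut": (20, 19, 18)}, 8, noise_sd=1.0
        )
        gc = rm_anova_interaction(df)
        assert gc.p > 0.01  # interaction at chance level

    def test_crossed_structure_detected(self, rng):
        df = make_behavior(
            rng, {"wt": (10, 10, 10), "mut": (25, 17, 10)}, 8, noise_sd=1.5
        )
        gc = rm_anova_interaction(df)
        assert gc.p < 0.01

    def test_incomplete_subject_dropped_with_warning(self, rng):
        df = make_behavior(rng, {"wt": (10, 9, 8), "mut": (12, 11, 10)}, 4)
        df = df.drop(df[(df.animal_id == "wt0") & (df.timepoint_weeks == 12)].index)
        with pytest.warns(UserWarning, match="incomplete"):
            gc = rm_anova_interaction(df)
        assert 0 <= gc.p <= 1

    def test_published_effect_detected_in_most_replicates(self):
        """Normal-housing trajectories (mutant improving from ~25.6 s to
        ~18.3 s vs wildtype ~11.7 to ~9.4 s at the published group sizes)
        produce a detectable genotype x time interaction more often than not."""
        hits = 0
        n_rep = 25
        for k in range(n_rep):
            tables, _ = gen_cohort(
                [
                    get_preset("NH/wt/12wk", n_animals=14),
                    get_preset("NH/mut/12wk", n_animals=12),
                ],
                seed=3000 + k,
                include_series=False,
            )
            hits += rm_anova_interaction(tables.behavior).p < 0.05
        assert hits > n_rep / 2


class TestRegression:
    def test_perfect_line(self):
        slope, se, p = si_behavior_regression([0, 1, 2], [0, 1, 2])
        assert slope == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(InsufficientDataError):
            si_behavior_regression([1, 2, 3], [5, 5, 5], orientation="si_on_time")

    def test_orientation_swaps_roles(self, rng):
        si = rng.normal(1e-3, 2e-4, 30)
        ct = 10 + 5000 * si + rng.normal(0, 0.5, 30)
        s1, _, _ = si_behavior_regression(si, ct, orientation="si_on_time")
        s2, _, _ = si_behavior_regression(si, ct, orientation="time_on_si")
        assert s2 > 1  # seconds per SI unit
        assert s1 < 1  # SI units per second


class TestCategoryCompare:
    def make_pnn(self, fractions_by_group, n_animals=3, n_neurons=60):
        rows = []
        for (housing, genotype), fracs in fractions_by_group.items():
            for a in range(n_animals):
                counts = np.round(np.array(fracs) * n_neurons).astype(int)
                j = 0
                for cat, c in zip(("none", "weak", "strong"), counts):
                    for _ in range(c):
                        rows.append(
                            dict(
                                animal_id=f"{housing}_{genotype}_{a}",
                                housing=housing,
                                genotype=genotype,
                                neuron_id=j,
                                category=cat,
                            )
                        )
                        j += 1
        return pd.DataFrame(rows)

    def test_identical_fractions_give_null(self):
        groups = {
            (h, g): (0.65, 0.30, 0.05)
            for h in ("NH", "EE_birth")
            for g in ("wt", "mut")
        }
        out = category_distribution_compare(self.make_pnn(groups))
        for gc in out.values():
            assert gc.statistic == pytest.approx(0.0)
            assert gc.p == 1.0

    def test_shifted_group_detected(self, rng):
        tables_groups = [
            get_preset("NH/wt/4wk", n_animals=3),
            get_preset("NH/mut/4wk", n_animals=3),
            get_preset("EE_birth/wt/4wk", n_animals=3),
            get_preset("EE_birth/mut/4wk", n_animals=3, pnn_probs=(0.2, 0.6, 0.2)),
        ]
        hits = 0
        for k in range(20):
            tables, _ = gen_cohort(tables_groups, seed=700 + k, include_series=False)
            out = category_distribution_compare(tables.pnn)
            hits += out["none"].p < 0.05
        assert hits > 10


class TestSynapseCompare:
    def test_identical_animal_means_null(self):
        rows = []
        for housing in ("NH", "EE_birth"):
            for a in range(3):
                for j in range(5):
                    rows.append(
                        dict(
                            animal_id=f"{housing}{a}",
                            genotype="wt",
                            housing=housing,
                            neuron_id=j,
                            excitatory_count=8 + j,
                            inhibitory_count=120 + j,
                        )
                    )
        out = synapse_compare(pd.DataFrame(rows))
        for gc in out.values():
            assert gc.p == pytest.approx(1.0)

    def test_published_excitatory_difference_detected(self):
        hits = 0
        for k in range(20):
            tables, _ = gen_cohort(
                [get_preset("NH/wt/12wk"), get_preset("EE_birth/wt/12wk")],
                seed=1500 + k,
                include_series=False,
            )
            out = synapse_compare(tables.synapse)
            hits += out[("wt", "EE_birth", "NH", "excitatory_count")].p < 0.05
        assert hits > 10

    def test_too_few_animals_rejected(self):
        rows = [
            dict(animal_id=f"{h}{a}", genotype="wt", housing=h, neuron_id=0,
                 excitatory_count=5, inhibitory_count=100)
            for h in ("NH", "EE_birth")
            for a in range(2)
        ]
        with pytest.raises(InsufficientDataError):
            synapse_compare(pd.DataFrame(rows))


class TestCalibration:
    """Type-I error of the main tests under their null, moderate replicate counts."""

    def test_compare_groups_type_one_error(self, rng):
        rejections = sum(
            compare_groups(rng.normal(size=8), rng.normal(size=8)).p < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09

    def test_regression_type_one_error(self, rng):
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=20)
            y = rng.normal(size=20)  # slope 0
            _, _, p = si_behavior_regression(y, x)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


def test_holm_correction_monotone():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_correct(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.04)
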