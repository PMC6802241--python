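"""Annual-cycle simulation: closed forms, kernel correctness, CRN, mortality."""

import numpy as np
import pytest
from scipy.stats import binomtest

from edsim.microsim import (
    BASELINE,
    FULL_TREATMENT,
    NO_INCIDENCE,
    NO_TREATMENT,
    CohortHistories,
    PersonContext,
    ScenarioSpec,
    annual_outcome_distribution,
    ed_mortality_probability,
    relapse_probability,
    run_counterfactuals,
    simulate_cohort,
    treated_remission_probability,
)
from edsim.parameters import LifeTable, ParameterSet
from edsim.states import N_AGES, EDState, Sex


class TestClosedForms:
    def test_relapse_first_year_exact(self):
        assert relapse_probability(0.213, 0.52, 1) == pytest.approx(0.213)

    def test_relapse_second_year_decay(self):
        expected = 0.213 * np.exp(-0.52)
        assert relapse_probability(0.213, 0.52, 2) == pytest.approx(expected)
        assert expected == pytest.approx(0.126633, abs=1e-5)

    def test_relapse_zero_decay_constant(self):
        for y in (1, 5, 30):
            assert relapse_probability(0.3, 0.0, y) == pytest.approx(0.3)

    def test_relapse_nonincreasing(self):
        vals = [relapse_probability(0.4, 0.7, y) for y in range(1, 20)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_relapse_invalid_year(self):
        with pytest.raises(ValueError):
            relapse_probability(0.2, 0.5, 0)

    def test_treated_remission_rate_scale(self):
        assert treated_remission_probability(0.085, 8.00) == \
            pytest.approx(1 - 0.915 ** 8)
        assert 1 - 0.915 ** 8 == pytest.approx(0.508675, abs=1e-5)

    def test_treated_remission_identity_and_zero(self):
        assert treated_remission_probability(0.3, 1.0) == pytest.approx(0.3)
        assert treated_remission_probability(0.0, 5.0) == 0.0
        assert treated_remission_probability(1.0, 5.0) == 1.0

    def test_treated_remission_bounds(self):
        p = treated_remission_probability(0.9, 9.9)
        assert 0.9 <= p <= 1.0

    def test_ed_mortality_rate_scale(self):
        assert ed_mortality_probability(0.001, 6.71) == \
            pytest.approx(1 - 0.999 ** 6.71)
        assert 1 - 0.999 ** 6.71 == pytest.approx(0.0066904, abs=1e-6)

    def test_ed_mortality_identity_and_zero(self):
        assert ed_mortality_probability(0.002, 1.0) == pytest.approx(0.002)
        assert ed_mortality_probability(0.0, 4.0) == 0.0


class TestOutcomeDistribution:
    def test_all_zero_params_persist(self, anchor_bounds):
        ps = anchor_bounds.build(np.zeros(8))
        ps = ParameterSet(**{**ps.__dict__,
                             "remission": np.zeros((2, 4)),
                             "crossover": np.zeros((2, 4, 4)),
                             "efficacy": np.ones((2, 4)),
                             "smr": np.ones((2, 4)),
                             "life_table": LifeTable(np.zeros((2, N_AGES)))})
        dist = annual_outcome_distribution(EDState.AN, "M", 20, None, ps, BASELINE)
        assert dist[EDState.AN] == pytest.approx(1.0)

    def test_incidence_off_stays_healthy(self, ps_means):
        q = ps_means.life_table.prob(Sex.FEMALE, 10)
        dist = annual_outcome_distribution(
            EDState.HEALTHY, "F", 10, None, ps_means, NO_INCIDENCE)
        assert dist[EDState.HEALTHY] == pytest.approx(1 - q)
        assert dist[EDState.DECEASED] == pytest.approx(q)

    def test_an_male_hand_oracle(self, anchor_bounds):
        """AN male at the printed calibrated means, q_bg = 0.002, summed by hand."""
        mid = (anchor_bounds.lower() + anchor_bounds.upper()) / 2
        ps = anchor_bounds.build(mid)
        ps = ParameterSet(**{**ps.__dict__,
                             "life_table": LifeTable(np.full((2, N_AGES), 0.002))})
        dist = annual_outcome_distribution(EDState.AN, "M", 30, None, ps, BASELINE)
        q_ed = 1 - 0.998 ** 6.71
        p_rem = 0.282 * (1 - (1 - 0.078) ** 7.59) + (1 - 0.282) * 0.078
        assert dist[EDState.DECEASED] == pytest.approx(q_ed, abs=1e-12)
        assert dist[EDState.HEALTHY] == pytest.approx((1 - q_ed) * p_rem, abs=1e-12)
        assert dist[EDState.BED] == pytest.approx((1 - q_ed) * 0.012, abs=1e-12)
        assert dist[EDState.BN] == pytest.approx(0.0, abs=1e-12)
        assert dist[EDState.OSFED] == pytest.approx((1 - q_ed) * 0.040, abs=1e-12)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_relapse_uses_most_recent_ed(self, ps_means):
        ctx = PersonContext(True, EDState.OSFED, 3)
        dist = annual_outcome_distribution(
            EDState.HEALTHY, "F", 25, ctx, ps_means, BASELINE)
        pr = relapse_probability(ps_means.relapse("OSFED", "F").p_first,
                                 ps_means.relapse("OSFED", "F").decay, 3)
        q = ps_means.life_table.prob(Sex.FEMALE, 25)
        assert dist[EDState.OSFED] == pytest.approx((1 - q) * pr)
        assert dist[EDState.AN] == 0.0


class TestSimulateCohort:
    def test_determinism(self, ps_means):
        a = simulate_cohort(ps_means, BASELINE, 2000, 7)
        b = simulate_cohort(ps_means, BASELINE, 2000, 7)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.treated, b.treated)

    def test_zero_incidence_no_ed_and_life_table_deaths(self, anchor_bounds):
        ps = anchor_bounds.build(np.zeros(8))
        h = simulate_cohort(ps, BASELINE, 20_000, 11)
        assert not (h.states[(h.states >= 1) & (h.states <= 4)]).any()
        # deaths within binomial noise of the pure life-table expectation
        q = ps.life_table.q
        for sx in (0, 1):
            p_dead = 1 - np.prod(1 - q[sx])
            n = int((h.sex == sx).sum())
            dead = int((h.age_at_death[h.sex == sx] >= 0).sum())
            assert binomtest(dead, n, p_dead).pvalue > 0.005

    def test_absorbing_death(self, small_cohort):
        dead = small_cohort.states == int(EDState.DECEASED)
        # once deceased, deceased at every later age
        assert np.all(dead[:, :-1] <= dead[:, 1:])

    def test_bookkeeping_matches_independent_rederivation(self, ps_sampled):
        h = simulate_cohort(ps_sampled, BASELINE, 5000, 21)
        rederived = CohortHistories.from_states(h.states, h.sex)
        np.testing.assert_array_equal(h.first_onset, rederived.first_onset)
        np.testing.assert_array_equal(h.n_episodes, rederived.n_episodes)
        np.testing.assert_array_equal(h.n_episodes_ed, rederived.n_episodes_ed)
        np.testing.assert_array_equal(h.first_entry, rederived.first_entry)
        np.testing.assert_array_equal(h.age_at_death, rederived.age_at_death)
        c, rc = h.counts, rederived.counts
        np.testing.assert_array_equal(c.alive, rc.alive)
        np.testing.assert_array_equal(c.in_state, rc.in_state)
        np.testing.assert_array_equal(c.ever_any, rc.ever_any)
        np.testing.assert_array_equal(c.ever_any_alive, rc.ever_any_alive)
        np.testing.assert_array_equal(c.ever_ed, rc.ever_ed)
        np.testing.assert_array_equal(c.onsets, rc.onsets)

    def test_relapse_destination_is_most_recent_ed(self, ps_sampled):
        h = simulate_cohort(ps_sampled, BASELINE, 4000, 33)
        checked = 0
        for i in np.nonzero(h.n_episodes >= 2)[0][:200]:
            row = h.states[i]
            last_ed = None
            for a in range(1, N_AGES + 1):
                prev, cur = row[a - 1], row[a]
                if prev == 0 and 1 <= cur <= 4 and last_ed is not None:
                    assert cur == last_ed  # relapse returns to most recent ED
                    checked += 1
                if 1 <= cur <= 4:
                    last_ed = cur
        assert checked > 0

    def test_smr_one_reduces_to_life_table(self, ps_means):
        """With all SMRs at 1, total mortality is indistinguishable from the
        background life-table process (two-sided binomial test, alpha=0.01)."""
        ps = ParameterSet(**{**ps_means.__dict__, "smr": np.ones((2, 4))})
        h = simulate_cohort(ps, BASELINE, 50_000, 17)
        q = ps.life_table.q
        for sx in (0, 1):
            p_dead = 1 - np.prod(1 - q[sx])
            n = int((h.sex == sx).sum())
            dead = int((h.age_at_death[h.sex == sx] >= 0).sum())
            assert binomtest(dead, n, p_dead).pvalue > 0.005

    def test_odd_cohort_size_rejected(self, ps_means):
        with pytest.raises(ValueError, match="even"):
            simulate_cohort(ps_means, BASELINE, 1001, 0)


def _reduced_two_ed_params() -> ParameterSet:
    """AN/BN-only model with constant rates (decay 0 => fully Markov)."""
    inc = np.zeros((2, 4, N_AGES))
    inc[:, 0, :] = 0.05   # AN
    inc[:, 1, :] = 0.03   # BN
    cross = np.zeros((2, 4, 4))
    cross[:, 0, 1] = 0.10  # AN -> BN
    cross[:, 1, 0] = 0.05  # BN -> AN
    return ParameterSet(
        incidence=inc,
        relapse_p_first=np.full((2, 4), 0.30),
        relapse_decay=np.zeros((2, 4)),
        remission=np.full((2, 4), 0.20),
        coverage=np.full((2, 4), 0.50),
        efficacy=np.full((2, 4), 2.0),
        crossover=cross,
        smr=np.broadcast_to([3.0, 2.0, 1.0, 1.0], (2, 4)).copy(),
        life_table=LifeTable(np.full((2, N_AGES), 0.005)),
    )


class TestSmallInstanceOracle:
    def test_simulation_matches_enumerated_chain(self):
        """Simulated occupancy over 3 ages matches exhaustive enumeration of
        the expanded Markov chain within 3 Monte-Carlo SEs."""
        ps = _reduced_two_ed_params()
        # expanded states: healthy-naive, AN, BN, healthy-post-AN,
        # healthy-post-BN, dead
        def step(p_vec, age):
            nxt = np.zeros(6)
            # healthy-naive
            d = annual_outcome_distribution(EDState.HEALTHY, "M", age, None,
                                            ps, BASELINE)
            nxt[0] += p_vec[0] * d[EDState.HEALTHY]
            nxt[1] += p_vec[0] * d[EDState.AN]
            nxt[2] += p_vec[0] * d[EDState.BN]
            nxt[5] += p_vec[0] * d[EDState.DECEASED]
            # ED states
            for src, code in ((1, EDState.AN), (2, EDState.BN)):
                d = annual_outcome_distribution(code, "M", age, None, ps, BASELINE)
                nxt[1] += p_vec[src] * d[EDState.AN]
                nxt[2] += p_vec[src] * d[EDState.BN]
                nxt[3 if src == 1 else 4] += p_vec[src] * d[EDState.HEALTHY]
                nxt[5] += p_vec[src] * d[EDState.DECEASED]
            # healthy-post (relapse only, decay 0 so clock irrelevant)
            for src, last in ((3, EDState.AN), (4, EDState.BN)):
                ctx = PersonContext(True, last, 1)
                d = annual_outcome_distribution(EDState.HEALTHY, "M", age, ctx,
                                                ps, BASELINE)
                nxt[src] += p_vec[src] * d[EDState.HEALTHY]
                nxt[1 if last is EDState.AN else 2] += p_vec[src] * d[last]
                nxt[5] += p_vec[src] * d[EDState.DECEASED]
            nxt[5] += p_vec[5]
            return nxt

        p_vec = np.array([1.0, 0, 0, 0, 0, 0])
        marginals = []
        for age in range(3):
            p_vec = step(p_vec, age)
            assert p_vec.sum() == pytest.approx(1.0, abs=1e-12)
            marginals.append({
                "healthy": p_vec[0] + p_vec[3] + p_vec[4],
                "AN": p_vec[1], "BN": p_vec[2], "dead": p_vec[5]})

        n = 200_000
        h = simulate_cohort(ps, BASELINE, n, 5)
        for age, expect in zip(range(1, 4), marginals):
            col = h.states[:, age]
            observed = {
                "healthy": np.mean(col == 0),
                "AN": np.mean(col == 1),
                "BN": np.mean(col == 2),
                "dead": np.mean(col == 5)}
            for key, p in expect.items():
                se = max(np.sqrt(p * (1 - p) / n), 1e-9)
                assert abs(observed[key] - p) <= 3 * se + 1e-12, \
                    f"age {age} {key}: {observed[key]:.5f} vs {p:.5f}"


class TestCounterfactuals:
    def test_duplicate_names_rejected(self, ps_means):
        with pytest.raises(ValueError, match="duplicate"):
            run_counterfactuals(ps_means, [BASELINE, BASELINE], 100, 0)

    def test_fewer_than_two_rejected(self, ps_means):
        with pytest.raises(ValueError, match="at least 2"):
            run_counterfactuals(ps_means, [BASELINE], 100, 0)

    def test_same_settings_identical_outputs(self, ps_means):
        twin = ScenarioSpec("baseline_twin", "current", True)
        runs = run_counterfactuals(ps_means, [BASELINE, twin], 2000, 9)
        np.testing.assert_array_equal(runs["baseline"].states,
                                      runs["baseline_twin"].states)

    def test_crn_identity_for_ed_free_persons(self, ps_means):
        """Persons who never enter an ED state in baseline have identical
        histories in the no-incidence scenario."""
        runs = run_counterfactuals(ps_means, [BASELINE, NO_INCIDENCE], 10_000, 13)
        base, noinc = runs["baseline"], runs["no_incidence"]
        never = base.first_onset < 0
        assert never.any()
        np.testing.assert_array_equal(base.states[never], noinc.states[never])
        np.testing.assert_array_equal(base.age_at_death[never],
                                      noinc.age_at_death[never])

    def test_deaths_averted_equals_person_level_pairing(self, ps_means):
        """Under CRN the aggregate deaths-averted contrast equals the sum of
        per-person paired death indicators."""
        from edsim.outcomes import deaths_averted

        runs = run_counterfactuals(ps_means, [BASELINE, NO_INCIDENCE], 20_000, 29)
        base, prev = runs["baseline"], runs["no_incidence"]
        paired = np.sum((base.age_at_death >= 0).astype(int)
                        - (prev.age_at_death >= 0).astype(int))
        assert deaths_averted(base, prev) == pytest.approx(
            paired * 100_000 / 20_000)
        # most ED-attributable deaths are deaths in baseline only
        assert paired >= 0

    def test_treatment_and_prevention_orderings(self, ps_means):
        """Over 20 seeds: full treatment <= no treatment deaths in
        expectation, and no-incidence <= baseline deaths in expectation."""
        d_none, d_full, d_base, d_prev = [], [], [], []
        for seed in range(20):
            runs = run_counterfactuals(
                ps_means, [BASELINE, NO_TREATMENT, FULL_TREATMENT, NO_INCIDENCE],
                10_000, seed)
            d_none.append(runs["no_treatment"].deaths_by_40)
            d_full.append(runs["full_treatment"].deaths_by_40)
            d_base.append(runs["baseline"].deaths_by_40)
            d_prev.append(runs["no_incidence"].deaths_by_40)
        assert np.mean(d_none) > np.mean(d_full)
        assert np.mean(d_base) > np.mean(d_prev)
        assert np.mean(d_none) >= np.mean(d_base)
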