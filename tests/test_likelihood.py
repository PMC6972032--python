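"""Panel likelihood: segmenting, closed forms, oracles and invariants."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import hipmsm as hm
from hipmsm.likelihood import segment_interval
from hipmsm.model import InputError, StateSpace, TransitionStructure


def _history(baseline_age, times_states, covs=None, death_time=None):
    covs = covs or [{} for _ in times_states]
    obs = [
        hm.PanelObservation(t=t, age=baseline_age + t, state=s, covariates=c)
        for (t, s), c in zip(times_states, covs)
    ]
    return hm.SubjectHistory("s1", obs, death_time)


@pytest.fixture(scope="module")
def two_state_ae():
    """Minimal survival model: states {A, E}, one transition A->E."""
    space = StateSpace(states=("A", "E"), absorbing=frozenset({"E"}))
    structure = TransitionStructure((("A", "E"),), space)

    def params(q, gamma=None):
        return hm.ModelParameters.from_dicts(
            structure, hm.CovariateSpec(), {("A", "E"): q},
            gamma={("A", "E"): gamma} if gamma is not None else None,
        )

    return structure, params


class TestSegmentInterval:
    def test_subject_already_over_65(self):
        h = _history(70.0, [(0.0, "A"), (6.0, "A")])
        plan = segment_interval(h, 0.0, 6.0)
        assert len(plan) == 1
        assert plan[0].duration == 6.0 and plan[0].age_ge_65

    def test_split_at_the_65th_birthday(self):
        h = _history(63.0, [(0.0, "A"), (6.0, "A")])
        plan = segment_interval(h, 0.0, 6.0)
        assert [s.duration for s in plan] == [2.0, 4.0]
        assert [s.age_ge_65 for s in plan] == [False, True]

    def test_turning_65_exactly_at_interval_end_stays_under(self):
        h = _history(59.0, [(0.0, "A"), (6.0, "A")])
        plan = segment_interval(h, 0.0, 6.0)
        assert len(plan) == 1 and not plan[0].age_ge_65

    def test_covariates_carried_from_interval_start(self):
        h = _history(50.0, [(0.0, "A"), (6.0, "A")],
                     covs=[{"obesity": 1.0}, {"obesity": 0.0}])
        plan = segment_interval(h, 0.0, 6.0)
        assert plan[0].covariates == {"obesity": 1.0}

    def test_bad_intervals_rejected(self):
        h = _history(50.0, [(0.0, "A"), (6.0, "A")])
        with pytest.raises(InputError):
            segment_interval(h, 6.0, 6.0)
        with pytest.raises(InputError):
            segment_interval(h, 1.0, 6.0)  # t0 not an observation time

    def test_durations_sum_to_interval_length(self):
        h = _history(61.3, [(0.0, "A"), (7.7, "A")])
        plan = segment_interval(h, 0.0, 7.7)
        assert sum(s.duration for s in plan) == pytest.approx(7.7, abs=1e-12)


class TestIntervalLoglik:
    def test_vanishing_intensities_give_log_one_for_staying(self, structure):
        spec = hm.CovariateSpec()
        q0 = {tr: 1e-18 for tr in structure.transitions}
        params = hm.ModelParameters.from_dicts(structure, spec, q0)
        h = _history(50.0, [(0.0, "B"), (6.0, "B")])
        assert hm.interval_loglik(params, h, 0.0, "B", 6.0, "B") == pytest.approx(0.0, abs=1e-10)

    def test_two_state_survival_closed_form(self, two_state_ae):
        _, make = two_state_ae
        h = _history(50.0, [(0.0, "A"), (2.0, "A")])
        ll = hm.interval_loglik(make(0.5), h, 0.0, "A", 2.0, "A")
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_structurally_impossible_pair_is_minus_inf(self, structure):
        spec = hm.CovariateSpec()
        params = hm.ModelParameters.from_dicts(
            structure, spec, {tr: 0.05 for tr in structure.transitions}
        )
        h = _history(50.0, [(0.0, "D"), (6.0, "A")])
        assert hm.interval_loglik(params, h, 0.0, "D", 6.0, "A") == -np.inf

    def test_matches_monte_carlo_frequency(self, truth3):
        # panel pair (A, D) over 6 years, covariates fixed, vs 2x10^5 chains
        z = {"obesity": 1.0, "dm": 0.0, "cvd": 1.0}
        h = _history(65.0, [(0.0, "A"), (6.0, "D")], covs=[z, z])
        ll = hm.interval_loglik(truth3, h, 0.0, "A", 6.0, "D")
        Q = hm.build_intensity_matrix(truth3, z, age_ge_65=True)
        n = 200_000
        final, _ = hm.simulate_endpoint([(Q, 6.0)], 0, n, np.random.default_rng(31))
        p_hat = np.mean(final == 3)
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(np.exp(ll) - p_hat) < 3 * se


class TestDeathLoglik:
    def test_survival_density_closed_form(self, two_state_ae):
        _, make = two_state_ae
        h = _history(50.0, [(0.0, "A")], death_time=2.0)
        ll = hm.death_loglik(make(0.3), h, 0.0, "A", 2.0)
        assert ll == pytest.approx(np.log(np.exp(-0.6) * 0.3), abs=1e-12)

    def test_no_death_intensities_gives_minus_inf(self):
        space = StateSpace()
        structure = TransitionStructure(
            (("A", "B"), ("A", "C"), ("B", "D"), ("C", "A"), ("C", "D"), ("D", "B")),
            space,
        )
        params = hm.ModelParameters.from_dicts(
            structure, hm.CovariateSpec(), {tr: 0.1 for tr in structure.transitions}
        )
        h = _history(50.0, [(0.0, "A")], death_time=3.0)
        assert hm.death_loglik(params, h, 0.0, "A", 3.0) == -np.inf

    def test_death_time_must_follow_last_visit(self, truth3):
        z = {"obesity": 0.0, "dm": 0.0, "cvd": 0.0}
        h = _history(50.0, [(0.0, "A")], covs=[z])
        with pytest.raises(InputError):
            hm.death_loglik(truth3, h, 0.0, "A", 0.0)

    def test_death_density_matches_simulation(self, truth3):
        # empirical deaths in a window vs the integrated model density
        z = {"obesity": 0.0, "dm": 1.0, "cvd": 0.0}
        h = _history(62.0, [(0.0, "C")], covs=[z], death_time=1.0)  # placeholder death
        Qy = hm.build_intensity_matrix(truth3, z, age_ge_65=False)
        Qo = hm.build_intensity_matrix(truth3, z, age_ge_65=True)
        n = 200_000
        _, dt_death = hm.simulate_endpoint(
            [(Qy, 3.0), (Qo, 9.0)], 2, n, np.random.default_rng(8)
        )
        lo, hi = 4.0, 6.0
        p_hat = np.mean((dt_death >= lo) & (dt_death < hi))
        dens = lambda t: np.exp(hm.death_loglik(truth3, h, 0.0, "C", t))
        p_model, _ = quad(dens, lo, hi)
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(p_model - p_hat) < 3 * se


class TestTotalLoglik:
    def test_empty_cohort_is_zero(self, truth3):
        assert hm.total_loglik(truth3, []) == 0.0

    def test_additivity_over_identical_subjects(self, truth3):
        z = {"obesity": 0.0, "dm": 0.0, "cvd": 0.0}
        h1 = _history(58.0, [(0.0, "A"), (5.5, "C")], covs=[z, z], death_time=9.0)
        h2 = hm.SubjectHistory("s2", h1.observations, h1.death_time)
        single = hm.total_loglik(truth3, [h1])
        assert hm.total_loglik(truth3, [h1, h2]) == pytest.approx(2 * single, rel=1e-12)

    def test_single_timepoint_subjects_warn_and_contribute_nothing(self, truth3):
        z = {"obesity": 0.0, "dm": 0.0, "cvd": 0.0}
        h1 = _history(58.0, [(0.0, "A"), (5.5, "C")], covs=[z, z])
        lone = hm.SubjectHistory("s9", [hm.PanelObservation(0.0, 50.0, "A", z)])
        with pytest.warns(UserWarning, match="<2 time points"):
            ll = hm.total_loglik(truth3, [h1, lone])
        assert ll == pytest.approx(hm.total_loglik(truth3, [h1]))

    def test_matches_independent_reimplementation(self, truth3, small_cohort):
        """Brute-force oracle sharing no matrix routines with the package."""

        def oracle(params, cohort, threshold=65.0):
            idx = {s: i for i, s in enumerate("ABCDE")}
            total = 0.0
            for h in cohort:
                pts = [(o.t, o.state, o.covariates, o.age) for o in h.observations]
                for (t0, s0, z0, age0), (t1, s1, _, _) in zip(pts, pts[1:]):
                    total += np.log(
                        _pair_prob(params, t0, t1, s0, s1, z0, age0, threshold, idx)
                    )
                if h.death_time is not None:
                    t0, s0, z0, age0 = pts[-1]
                    td = h.death_time
                    P = _interval_matrix(params, t0, td, z0, age0, threshold)
                    Qd = _Q(params, z0, (age0 + td - t0) >= threshold)
                    total += np.log(sum(P[idx[s0], idx[k]] * Qd[idx[k], 4]
                                        for k in "ABCD"))
            return total

        def _Q(params, z, old):
            n = 5
            Q = np.zeros((n, n))
            for i, (r, s) in enumerate(params.structure.transitions):
                eta = params.log_q0[i]
                for k, name in enumerate(params.covariates.names):
                    eta += params.beta[i, k] * z[name]
                if old and params.gamma is not None:
                    eta += params.gamma[i]
                Q["ABCDE".index(r), "ABCDE".index(s)] = np.exp(eta)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            return Q

        def _interval_matrix(params, t0, t1, z, age0, threshold):
            cross = t0 + (threshold - age0)
            if cross <= t0 or cross >= t1:
                return expm(_Q(params, z, age0 >= threshold) * (t1 - t0))
            return expm(_Q(params, z, False) * (cross - t0)) @ expm(
                _Q(params, z, True) * (t1 - cross)
            )

        def _pair_prob(params, t0, t1, s0, s1, z, age0, threshold, idx):
            return _interval_matrix(params, t0, t1, z, age0, threshold)[idx[s0], idx[s1]]

        cohort = [h for h in small_cohort if h.n_timepoints >= 2][:50]
        assert hm.total_loglik(truth3, cohort) == pytest.approx(
            oracle(truth3, cohort), abs=1e-9
        )


class TestInvariants:
    def test_markov_property_three_visit_product(self, truth3):
        z = {"obesity": 0.0, "dm": 1.0, "cvd": 0.0}
        h = _history(60.0, [(0.0, "A"), (6.0, "C"), (12.0, "D")], covs=[z] * 3)
        total = sum(
            hm.interval_loglik(truth3, h, t0, s0, t1, s1)
            for (t0, s0), (t1, s1) in [((0.0, "A"), (6.0, "C")), ((6.0, "C"), (12.0, "D"))]
        )
        assert hm.subject_loglik(truth3, h) == pytest.approx(total, rel=1e-12)

    def test_total_probability_over_interval(self, truth3):
        # sum of all living-state probabilities plus death probability is 1
        z = {"obesity": 1.0, "dm": 0.0, "cvd": 0.0}
        h = _history(61.0, [(0.0, "C"), (6.3, "C")], covs=[z, z])
        living = sum(
            np.exp(hm.interval_loglik(truth3, h, 0.0, "C", 6.3, s1))
            for s1 in "ABCD"
        )
        plan = segment_interval(h, 0.0, 6.3)
        P = hm.path_probability(
            (hm.build_intensity_matrix(truth3, s.covariates, s.age_ge_65), s.duration)
            for s in plan
        )
        p_death = P[hm.STATES.index("C"), hm.STATES.index("E")]
        assert living + p_death == pytest.approx(1.0, abs=1e-8)

    def test_interval_ignores_covariates_recorded_at_its_end(self, truth3):
        z0 = {"obesity": 0.0, "dm": 0.0, "cvd": 0.0}
        z1 = {"obesity": 1.0, "dm": 1.0, "cvd": 1.0}
        h_a = _history(60.0, [(0.0, "A"), (6.0, "C")], covs=[z0, z0])
        h_b = _history(60.0, [(0.0, "A"), (6.0, "C")], covs=[z0, z1])
        assert hm.interval_loglik(truth3, h_a, 0.0, "A", 6.0, "C") == pytest.approx(
            hm.interval_loglik(truth3, h_b, 0.0, "A", 6.0, "C"), rel=1e-14
        )

    def test_monotone_comorbidity_validation(self):
        with pytest.raises(InputError, match="dm"):
            _history(
                60.0,
                [(0.0, "A"), (6.0, "A")],
                covs=[{"dm": 1.0}, {"dm": 0.0}],  # diabetes cannot resolve
            )

    def test_observation_time_ordering_enforced(self):
        with pytest.raises(InputError):
            _history(60.0, [(6.0, "A"), (0.0, "A")])
        with pytest.raises(InputError):
            _history(60.0, [(0.0, "A"), (6.0, "A")], death_time=5.0)

    def test_find_impossible_pairs_flags_unreachable_records(self, structure):
        z = {}
        good = _history(60.0, [(0.0, "A"), (6.0, "D")], covs=[z, z])  # multi-jump ok
        bad = hm.SubjectHistory(
            "bad",
            [hm.PanelObservation(0.0, 60.0, "D", z), hm.PanelObservation(6.0, 66.0, "A", z)],
        )
        flagged = hm.find_impossible_pairs([good, bad], structure)
        assert [f[0] for f in flagged] == ["bad"]
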