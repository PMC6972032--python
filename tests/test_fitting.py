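"""Crude initialization, MLE, hazard-ratio tables and count tables."""

import warnings

import numpy as np
import pytest

import hipmsm as hm
from hipmsm._engine import LikelihoodEngine
from hipmsm.fitting import REPORTED_TRANSITIONS, FitError
from hipmsm.model import InputError

from conftest import fit_quiet


def _simple_history(sid, times_states, z=None, death_time=None, age0=55.0):
    z = z or {}
    obs = [hm.PanelObservation(t, age0 + t, s, z) for t, s in times_states]
    return hm.SubjectHistory(sid, obs, death_time)


class TestCrudeInit:
    def test_single_observed_pair(self, structure):
        h = _simple_history("a", [(0.0, "A"), (4.0, "B")])
        with pytest.warns(UserWarning):
            init = hm.crude_initial_values([h], structure, floor=1e-3)
        i_ab = structure.transition_index("A", "B")
        assert np.exp(init.log_q0[i_ab]) == pytest.approx(0.25)
        others = np.delete(np.exp(init.log_q0), i_ab)
        assert np.allclose(others, 1e-3)

    def test_no_events_all_floored(self, structure):
        h = _simple_history("a", [(0.0, "A"), (4.0, "A"), (8.0, "A")])
        with pytest.warns(UserWarning):
            init = hm.crude_initial_values([h], structure, floor=1e-3)
        # A->A pairs give person-time but no events anywhere
        assert np.allclose(np.exp(init.log_q0), 1e-3)

    def test_hand_counted_rates(self, structure):
        # 3 subjects: 2 A->C pairs over 4+6 person-years in A, 1 C->D over 5y in C,
        # one death from C after 3 further years
        cohort = [
            _simple_history("a", [(0.0, "A"), (4.0, "C")]),
            _simple_history("b", [(0.0, "A"), (6.0, "C"), (11.0, "D")]),
            _simple_history("c", [(0.0, "C")], death_time=3.0),
        ]
        with pytest.warns(UserWarning):
            init = hm.crude_initial_values(cohort, structure, floor=1e-3)
        q = {tr: np.exp(init.log_q0[i]) for i, tr in enumerate(structure.transitions)}
        assert q[("A", "C")] == pytest.approx(2 / 10)
        assert q[("C", "D")] == pytest.approx(1 / 8)  # C time: 5 (b) + 3 (c death)
        assert q[("C", "E")] == pytest.approx(1 / 8)
        assert q[("A", "B")] == pytest.approx(1e-3)

    def test_empty_cohort_rejected(self, structure):
        with pytest.raises(InputError):
            hm.crude_initial_values([], structure)


class TestWaldTable:
    def test_null_estimate_gives_unit_ahr_with_symmetric_ci(self):
        ahr, lo, hi = hm.wald_ci(0.0, 0.25)
        assert ahr == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)  # symmetric on log scale

    def test_literature_scale_example(self):
        # beta 0.2852, SE 0.1385 -> 1.33 (1.01, 1.74) at the printed precision
        ahr, lo, hi = hm.wald_ci(0.2852, 0.1385)
        assert round(ahr, 2) == 1.33
        assert round(lo, 2) == 1.01
        assert round(hi, 2) == 1.74

    def test_degenerate_se_collapses_ci(self):
        ahr, lo, hi = hm.wald_ci(np.log(2.0), 1e-12)
        assert ahr == pytest.approx(2.0)
        assert lo == pytest.approx(2.0, rel=1e-9)
        assert hi == pytest.approx(2.0, rel=1e-9)


class TestTransitionCounts:
    def test_empty_cohort_all_zero(self):
        counts = hm.transition_count_table([], "obesity")
        assert all(v == (0, 0) for v in counts.values())

    def test_single_subject_hand_count(self):
        z1 = {"obesity": 1.0}
        h = _simple_history("a", [(0.0, "A"), (5.0, "C"), (10.0, "A")], z=z1)
        counts = hm.transition_count_table([h], "obesity")
        assert counts[("A", "C")] == (1, 0)
        assert counts[("C", "A")] == (1, 0)
        assert counts[("A", "B")] == (0, 0)

    def test_non_binary_exposure_rejected(self):
        h = _simple_history("a", [(0.0, "A"), (5.0, "C")], z={"obesity": 0.5})
        with pytest.raises(InputError):
            hm.transition_count_table([h], "obesity")

    def test_matches_brute_force_tally(self, small_cohort):
        counts = hm.transition_count_table(small_cohort, "dm")
        for tr in REPORTED_TRANSITIONS:
            exp = [0, 0]
            for h in small_cohort:
                for o0, o1 in zip(h.observations, h.observations[1:]):
                    if (o0.state, o1.state) == tr:
                        exp[0 if o0.covariates["dm"] else 1] += 1
            assert counts[tr] == tuple(exp)


class TestFitMle:
    def test_impossible_records_abort_with_diagnostic(self, structure):
        bad = hm.SubjectHistory(
            "bad",
            [hm.PanelObservation(0.0, 60.0, "D", {}), hm.PanelObservation(6.0, 66.0, "A", {})],
        )
        with pytest.raises(FitError, match="bad"):
            hm.fit_mle([bad], structure)

    def test_analytic_score_matches_finite_differences(self, truth3, small_cohort):
        eng = LikelihoodEngine(
            small_cohort, truth3.structure, truth3.covariates.names
        )
        theta = eng.pack(truth3.log_q0, np.column_stack([truth3.beta, truth3.gamma]))
        _, g = eng.negloglik_grad(theta)
        h = 1e-6
        for i in range(0, len(theta), 5):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (eng.negloglik(tp) - eng.negloglik(tm)) / (2 * h)
            assert abs(g[i] - fd) / max(1e-6, abs(fd)) < 1e-3

    def test_engine_fast_path_agrees_with_reference_loglik(self, truth3, small_cohort):
        eng = LikelihoodEngine(small_cohort, truth3.structure, truth3.covariates.names)
        theta = eng.pack(truth3.log_q0, np.column_stack([truth3.beta, truth3.gamma]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = hm.total_loglik(truth3, small_cohort)
        assert eng.loglik(theta) == pytest.approx(ref, abs=1e-9)

    def test_reparameterization_invariance(self, truth3):
        # covariate x vs 2x: halved coefficient, identical maximized loglik.
        # Needs an interior MLE, hence enough events per exposure cell.
        cfg = hm.CohortConfig(n_subjects=500, seed=21, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        df2 = df.copy()
        df2["obesity"] = 2.0 * df2["obesity"]
        spec = hm.CovariateSpec(("obesity",), ("time-dependent",))
        fits = []
        for frame in (df, df2):
            cohort = hm.dataframe_to_cohort(frame)
            fits.append(fit_quiet(cohort, truth3.structure, spec, age_changepoint=False,
                                  compute_information=False, gtol=1e-8))
        f1, f2 = fits
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        i = truth3.structure.transition_index("A", "C")
        assert f1.params.beta[i, 0] == pytest.approx(2 * f2.params.beta[i, 0], abs=1e-4)

    def test_adding_a_covariate_never_decreases_loglik(self, truth3):
        cfg = hm.CohortConfig(n_subjects=150, seed=22, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        cohort = hm.dataframe_to_cohort(df)
        f0 = fit_quiet(cohort, truth3.structure, hm.CovariateSpec(),
                       age_changepoint=False, compute_information=False)
        spec1 = hm.CovariateSpec(("obesity",), ("time-dependent",))
        f1 = fit_quiet(cohort, truth3.structure, spec1, age_changepoint=False,
                       compute_information=False)
        assert f1.loglik >= f0.loglik - 1e-6

    def test_refit_on_self_simulated_data_does_not_improve(self, truth3):
        # self-consistency: the MLE maximizes its own likelihood
        cfg = hm.CohortConfig(n_subjects=200, seed=23, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        cohort = hm.dataframe_to_cohort(df)
        spec = hm.CovariateSpec(("obesity",), ("time-dependent",))
        fit = fit_quiet(cohort, truth3.structure, spec, age_changepoint=False,
                        compute_information=False)
        eng = LikelihoodEngine(cohort, truth3.structure, ("obesity",),
                               age_changepoint=False)
        # any perturbation of the MLE lowers the likelihood
        rng = np.random.default_rng(0)
        for _ in range(5):
            pert = fit.theta + rng.normal(0, 0.05, size=len(fit.theta))
            assert eng.loglik(pert) <= fit.loglik + 1e-9

    def test_sparse_transition_frozen_and_flagged(self, structure):
        # D never observed as a source: D->B and D->E must freeze
        cohort = [
            _simple_history(f"s{i}", [(0.0, "A"), (6.0, "B" if i % 2 else "A"), (12.0, "B")],
                            z={"x": float(i % 2)})
            for i in range(30)
        ] + [_simple_history("d", [(0.0, "C"), (6.0, "C")], z={"x": 0.0}, death_time=9.0)]
        fit = fit_quiet(cohort, structure, hm.CovariateSpec(("x",), ("static",)),
                        age_changepoint=False)
        frozen = set(fit.frozen_transitions)
        assert ("D", "B") in frozen and ("D", "E") in frozen
        rows = hm.hazard_ratio_table(fit, ["x"])
        db = [r for r in rows if r.transition == ("D", "B")][0]
        assert not db.estimable and "frozen" in db.note

    def test_recovery_of_planted_effect_within_sampling_error(self, truth3):
        cfg = hm.CohortConfig(n_subjects=1200, seed=29, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        cohort = hm.dataframe_to_cohort(df)
        fit = fit_quiet(cohort, truth3.structure, truth3.covariates)
        assert fit.converged
        b, se = fit.beta_and_se("obesity", "A", "C")
        assert np.isfinite(se) and se < 0.6
        assert abs(b - np.log(1.33)) < 3 * se
        assert fit.information_pd

    def test_determinism_identical_data_identical_estimates(self, truth3):
        cfg = hm.CohortConfig(n_subjects=150, seed=33, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        cohort = hm.dataframe_to_cohort(df)
        spec = hm.CovariateSpec(("obesity",), ("time-dependent",))
        f1 = fit_quiet(cohort, truth3.structure, spec, compute_information=False)
        f2 = fit_quiet(cohort, truth3.structure, spec, compute_information=False)
        assert np.array_equal(f1.theta, f2.theta)


class TestHazardRatioTable:
    def test_reported_transitions_and_row_shape(self, truth3):
        cfg = hm.CohortConfig(n_subjects=300, seed=41, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        cohort = hm.dataframe_to_cohort(df)
        fit = fit_quiet(cohort, truth3.structure, truth3.covariates)
        counts = {c: hm.transition_count_table(cohort, c) for c in ("obesity", "dm")}
        rows = hm.hazard_ratio_table(fit, ["obesity", "dm"], counts=counts)
        assert len(rows) == 6 * 2
        assert [r.transition for r in rows[::2]] == list(REPORTED_TRANSITIONS)
        for r in rows:
            if r.estimable and r.ci_lower is not None:
                assert 0 < r.ci_lower <= r.ahr <= r.ci_upper
                assert r.significant == (r.ci_lower > 1.0 or r.ci_upper < 1.0)
            assert r.n_exposed is not None and r.n_unexposed is not None

    def test_death_transitions_suppressed_by_default(self, truth3):
        cfg = hm.CohortConfig(n_subjects=200, seed=42, truth=truth3)
        df, _ = hm.generate_cohort(cfg)
        cohort = hm.dataframe_to_cohort(df)
        fit = fit_quiet(cohort, truth3.structure, truth3.covariates)
        rows = hm.hazard_ratio_table(fit, ["obesity"])
        assert all(r.transition[1] != "E" for r in rows)
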