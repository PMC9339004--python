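"""Encoding model: regressor construction, likelihood, fitting, CV."""

import numpy as np
import pytest
from scipy import optimize, sparse

from lipglm import glm, synth
from lipglm.task import TaskConfig, derive_stimulus_vars, sample_trial


def _tiny_rs(small_trials, variables=("stimulus_onset", "weight"), n=10, **kw):
    trials, dvs = small_trials
    return glm.build_regressors(trials[:n], dvs[:n], variables, **kw)


def _model(rs, intercept=0.0, kernels=None):
    kernels = kernels or {}
    return glm.KernelModel(
        variables=rs.variables,
        intercept=intercept,
        kernels={v: kernels.get(v, np.zeros(rs.kernel_lags(v))) for v in rs.variables},
        nll=np.nan,
        converged=True,
        n_iter=0,
    )


class TestBuildRegressors:
    def test_impulse_stimulus_onset_placement(self, small_trials):
        rs = _tiny_rs(small_trials, n=3)
        X = rs.matrix().toarray()
        col = rs.col_slices["stimulus_onset"].start  # lag 0
        for ti in range(3):
            trial_rows = X[rs.trial_starts[ti] : rs.trial_starts[ti] + rs.trial_lens[ti], col]
            nz = np.flatnonzero(trial_rows)
            assert nz.tolist() == list(rs.stim_onset_bins)
            assert np.all(trial_rows[nz] == 1.0)

    def test_impulse_evidence_amplitude(self, small_trials):
        trials, dvs = small_trials
        rs = _tiny_rs(small_trials, variables=("evidence",), n=2)
        X = rs.matrix().toarray()
        col = rs.col_slices["evidence"].start
        for ti in range(2):
            rows = X[rs.trial_starts[ti] : rs.trial_starts[ti] + rs.trial_lens[ti], col]
            got = rows[list(rs.stim_onset_bins)]
            assert got == pytest.approx(dvs[ti].evidence)

    def test_regressors_zero_before_onset(self, small_trials):
        rs = _tiny_rs(small_trials, variables=("weight",), n=2)
        X = rs.matrix().toarray()
        sl = rs.col_slices["weight"]
        first = rs.stim_onset_bins[0]
        assert np.all(X[: first, sl.start] == 0)

    def test_boxcar_truncated_at_trial_end(self, small_trials):
        rs = _tiny_rs(small_trials, variables=("weight",), n=2,
                      regressor_mode="boxcar", boxcar_kernel_support=10)
        X = rs.matrix().tocsc()
        sl = rs.col_slices["weight"]
        # epoch-6 onset bin 286 + 150-bin boxcar would reach bin 436; trials
        # end at <= 396 bins, so every lag-0 column stops at the trial end.
        col = X[:, sl.start].toarray().ravel()
        for ti in range(2):
            seg = col[rs.trial_starts[ti] : rs.trial_starts[ti] + rs.trial_lens[ti]]
            assert len(seg) == rs.trial_lens[ti]
        assert rs.kernel_lags("weight") == 10

    def test_unknown_variable_rejected(self, small_trials):
        with pytest.raises(KeyError, match="unknown variable"):
            _tiny_rs(small_trials, variables=("weight", "licking"))


class TestLikelihood:
    def test_closed_form_zero_counts(self, small_trials):
        rs = _tiny_rs(small_trials, n=4)
        zero_counts = [np.zeros(n, dtype=int) for n in rs.trial_lens]
        m = _model(rs, intercept=0.0)  # lambda = 1 sp/s
        nll, _ = glm.nll_and_gradient(m, rs, zero_counts)
        assert nll == pytest.approx(0.01 * rs.n_bins_total, rel=1e-12)

    def test_closed_form_single_spike(self, small_trials):
        rs = _tiny_rs(small_trials, n=4)
        counts = [np.zeros(n, dtype=int) for n in rs.trial_lens]
        counts[0][0] = 1
        m = _model(rs, intercept=np.log(2.0))  # delta*lambda = 0.02
        nll, _ = glm.nll_and_gradient(m, rs, counts)
        expected = 0.02 * rs.n_bins_total - np.log(0.02)
        assert nll == pytest.approx(expected, rel=1e-12)
        # the single-bin contribution itself: 0.02 - log 0.02 ~= 3.932
        assert 0.02 - np.log(0.02) == pytest.approx(3.932, abs=5e-4)

    def test_gradient_matches_finite_differences(self, small_trials):
        rs = _tiny_rs(small_trials, n=3)
        trials, dvs = small_trials
        spec = synth.make_neuron_spec("weight_neg_transient", baseline_rate=25.0)
        counts = synth.simulate_spike_counts(spec, trials[:3], dvs[:3], rng=3,
                                             regressor_set=rs)
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.05, rs.n_cols)
        beta[0] = np.log(20)
        m = glm.KernelModel.from_vector(beta, rs, 0, True, 0)
        nll, g = glm.nll_and_gradient(m, rs, counts)
        eps = 1e-6
        for j in rng.choice(rs.n_cols, 25, replace=False):
            b2 = beta.copy()
            b2[j] += eps
            m2 = glm.KernelModel.from_vector(b2, rs, 0, True, 0)
            n2, _ = glm.nll_and_gradient(m2, rs, counts)
            fd = (n2 - nll) / eps
            assert fd == pytest.approx(g[j], rel=1e-5, abs=1e-5)


class TestFit:
    def test_zero_spikes_degenerate(self, small_trials):
        rs = _tiny_rs(small_trials, n=4)
        zero = [np.zeros(n, dtype=int) for n in rs.trial_lens]
        with pytest.raises(glm.DegenerateDataError):
            glm.fit_kernels(zero, rs)

    def test_oracle_equivalence_small_problem(self, small_trials):
        """Newton fit agrees with an independent L-BFGS solve of the same NLL
        on a dense toy design."""
        trials, dvs = small_trials
        rs = glm.build_regressors(trials[:6], dvs[:6], ("weight", "evidence"),
                                  shape_support=20)
        spec = synth.NeuronSpec(
            baseline_log_rate=np.log(30),
            kernels={"weight": np.linspace(-0.4, 0, 150),
                     "evidence": np.linspace(0, 0.4, 150)},
        )
        counts = synth.simulate_spike_counts(spec, trials[:6], dvs[:6], rng=9)
        ours = glm.fit_kernels(counts, rs, glm.FitConfig(tol_nll=1e-13, tol_grad=1e-9))

        Xd = rs.matrix().toarray()
        y = np.concatenate(counts).astype(float)

        def f(b):
            eta = Xd @ b
            mu = 0.01 * np.exp(eta)
            return mu.sum() - y @ eta - y.sum() * np.log(0.01), Xd.T @ (mu - y)

        res = optimize.minimize(f, np.zeros(rs.n_cols), jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
        assert res.success
        assert np.max(np.abs(ours.coef_vector(rs) - res.x)) < 1e-4

    def test_null_neuron_recovery(self, shape_set_sw, task_config):
        rng = np.random.default_rng(55)
        trials = [sample_trial(shape_set_sw, task_config, rng, i) for i in range(500)]
        dvs = [derive_stimulus_vars(t, shape_set_sw) for t in trials]
        rs = glm.build_regressors(trials, dvs, ("stimulus_onset", "weight"))
        spec = synth.make_neuron_spec("null", baseline_rate=20.0)
        counts = synth.simulate_spike_counts(spec, trials, dvs, rng=rng, regressor_set=rs)
        m = glm.fit_kernels(counts, rs)
        assert m.intercept == pytest.approx(np.log(20.0), abs=0.05)
        # per-lag sampling noise: ~0.04 from event counts, inflated by the
        # intercept/onset-kernel trade-off; weight amplitudes < 1 carry less
        # information still
        assert np.sqrt(np.mean(m.kernels["stimulus_onset"] ** 2)) < 0.1
        assert np.sqrt(np.mean(m.kernels["weight"] ** 2)) < 0.15

    def test_planted_kernel_recovery(self, shape_set_sw, task_config):
        rng = np.random.default_rng(56)
        trials = [sample_trial(shape_set_sw, task_config, rng, i) for i in range(1000)]
        agent = synth.AgentSpec(shape_set_sw.subjective_weights)
        trials = synth.simulate_choices(trials, agent, rng)
        dvs = [derive_stimulus_vars(t, shape_set_sw) for t in trials]
        spec = synth.combine_specs(
            [synth.make_neuron_spec("weight_neg_transient", 0.3, 30.0),
             synth.make_neuron_spec("evidence_sustained", 0.3, 30.0)]
        )
        rs = glm.build_regressors(trials, dvs, "full")
        counts = synth.simulate_spike_counts(spec, trials, dvs, rng=rng, regressor_set=rs)
        m = glm.fit_kernels(counts, rs)
        for v in ("weight", "evidence"):
            c = np.corrcoef(m.kernels[v], spec.kernels[v])[0, 1]
            assert c > 0.8, f"{v} kernel recovery corr {c:.3f}"

    def test_refit_from_optimum_is_fixed_point(self, small_trials):
        trials, dvs = small_trials
        rs = _tiny_rs(small_trials, n=20)
        spec = synth.make_neuron_spec("weight_neg_transient", baseline_rate=25.0)
        counts = synth.simulate_spike_counts(spec, trials[:20], dvs[:20], rng=2,
                                             regressor_set=rs)
        tight = glm.FitConfig(tol_nll=1e-13, tol_grad=1e-8)
        m1 = glm.fit_kernels(counts, rs, tight)
        m2 = glm.fit_kernels(counts, rs, tight, init=m1)
        assert m2.n_iter == 0
        assert abs(m2.nll - m1.nll) < 1e-8

    def test_recovery_improves_with_data(self, shape_set_sw, task_config):
        rmse = {200: [], 1000: []}
        for seed in range(4):
            rng = np.random.default_rng(600 + seed)
            trials = [sample_trial(shape_set_sw, task_config, rng, i) for i in range(1000)]
            dvs = [derive_stimulus_vars(t, shape_set_sw) for t in trials]
            spec = synth.make_neuron_spec("weight_neg_transient", 0.3, 25.0)
            rs = glm.build_regressors(trials, dvs, ("stimulus_onset", "weight"))
            counts = synth.simulate_spike_counts(spec, trials, dvs, rng=rng,
                                                 regressor_set=rs)
            for n in (200, 1000):
                m = glm.fit_kernels(counts[:n], rs.subset(np.arange(n)))
                rmse[n].append(
                    np.sqrt(np.mean((m.kernels["weight"] - spec.kernels["weight"]) ** 2))
                )
        assert np.mean(rmse[1000]) < np.mean(rmse[200])

    def test_truncation_equals_masked_padded_design(self, small_trials):
        """Evaluating the truncated design equals evaluating a padded design
        restricted to the real bins."""
        trials, dvs = small_trials
        rs = _tiny_rs(small_trials, n=5)
        spec = synth.make_neuron_spec("weight_neg_transient", baseline_rate=25.0)
        counts = synth.simulate_spike_counts(spec, trials[:5], dvs[:5], rng=4,
                                             regressor_set=rs)
        m = glm.fit_kernels(counts, rs)
        nll, _ = glm.nll_and_gradient(m, rs, counts)

        pad = 40
        rs_pad = glm.RegressorSet(
            variables=rs.variables,
            supports=dict(rs.supports),
            values={v: a.copy() for v, a in rs.values.items()},
            trial_lens=rs.trial_lens + pad,
            stim_onset_bins=rs.stim_onset_bins,
        )
        Xp = rs_pad.matrix()
        beta = m.coef_vector(rs_pad)
        eta = Xp @ beta
        mask = np.zeros(rs_pad.n_bins_total, dtype=bool)
        for ti in range(rs_pad.n_trials):
            s = rs_pad.trial_starts[ti]
            mask[s : s + rs.trial_lens[ti]] = True
        y = np.concatenate(counts).astype(float)
        mu = 0.01 * np.exp(eta[mask])
        nll_masked = mu.sum() - y @ eta[mask] - y.sum() * np.log(0.01)
        assert nll_masked == pytest.approx(nll, rel=1e-12)


class TestPredictAndCV:
    def test_constant_rate_for_zero_kernels(self, small_trials):
        rs = _tiny_rs(small_trials, n=3)
        m = _model(rs, intercept=np.log(17.0))
        lam = glm.predict_rate(m, rs)
        for l in lam:
            assert np.allclose(l, 17.0)

    def test_moment_match_at_mle(self, small_trials):
        trials, dvs = small_trials
        rs = _tiny_rs(small_trials, n=30)
        spec = synth.make_neuron_spec("weight_neg_transient", baseline_rate=25.0)
        counts = synth.simulate_spike_counts(spec, trials[:30], dvs[:30], rng=6,
                                             regressor_set=rs)
        m = glm.fit_kernels(counts, rs, glm.FitConfig(tol_nll=1e-13, tol_grad=1e-8))
        lam = glm.predict_rate(m, rs)
        expected = sum(l.sum() for l in lam) * rs.delta_s
        observed = sum(c.sum() for c in counts)
        assert expected == pytest.approx(observed, rel=1e-6)

    def test_log_linearity(self, small_trials):
        rs = _tiny_rs(small_trials, variables=("weight",), n=2)
        k = np.zeros(150)
        k[5] = 0.2
        m1 = _model(rs, intercept=np.log(10), kernels={"weight": k})
        m2 = _model(rs, intercept=np.log(10), kernels={"weight": 2 * k})
        r1 = np.concatenate(glm.predict_rate(m1, rs)) / 10.0
        r2 = np.concatenate(glm.predict_rate(m2, rs)) / 10.0
        assert np.allclose(r2, r1**2)

    def test_cv_fold_determinism(self, small_trials):
        trials, dvs = small_trials
        rs = _tiny_rs(small_trials, n=25)
        spec = synth.make_neuron_spec("null", baseline_rate=20.0)
        counts = synth.simulate_spike_counts(spec, trials[:25], dvs[:25], rng=7,
                                             regressor_set=rs)
        a = glm.crossvalidate(counts, rs, k_folds=5, seed=3)
        b = glm.crossvalidate(counts, rs, k_folds=5, seed=3)
        assert a["fold_assignment"] == b["fold_assignment"]
        assert a["mean_test_nll"] == b["mean_test_nll"]

    def test_cv_encoding_neuron_beats_intercept(self, shape_set_sw, task_config):
        rng = np.random.default_rng(77)
        trials = [sample_trial(shape_set_sw, task_config, rng, i) for i in range(200)]
        dvs = [derive_stimulus_vars(t, shape_set_sw) for t in trials]
        rs = glm.build_regressors(trials, dvs, ("stimulus_onset", "weight"))
        spec = synth.make_neuron_spec("weight_neg_transient", 0.6, 25.0)
        counts = synth.simulate_spike_counts(spec, trials, dvs, rng=rng, regressor_set=rs)
        cv = glm.crossvalidate(counts, rs, k_folds=5, seed=1)
        wins = sum(
            f["test_nll"] < f["intercept_only_test_nll"] for f in cv["folds"]
        )
        assert wins >= 4

    def test_cv_null_neuron_no_systematic_win(self, null_dataset):
        ds = null_dataset
        rs = glm.build_regressors(ds.trials[:100], ds.derived_vars[:100],
                                  ("stimulus_onset", "weight"))
        wins = 0
        for rep in range(10):
            spec = synth.make_neuron_spec("null", baseline_rate=20.0)
            counts = synth.simulate_spike_counts(
                spec, ds.trials[:100], ds.derived_vars[:100], rng=900 + rep,
                regressor_set=rs)
            cv = glm.crossvalidate(counts, rs, k_folds=5, seed=rep)
            wins += cv["mean_test_nll"] < cv["mean_intercept_only_test_nll"]
        # a 301-parameter model fit to noise should not beat the flat model
        assert wins <= 5

    def test_cv_too_few_trials(self, small_trials):
        rs = _tiny_rs(small_trials, n=3)
        counts = [np.ones(n, dtype=int) for n in rs.trial_lens]
        with pytest.raises(ValueError):
            glm.crossvalidate(counts, rs, k_folds=5)
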