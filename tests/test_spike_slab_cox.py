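import numpy as np
import pytest
from scipy import optimize

from survsel.cox_core import PreparedCox, partial_log_likelihood
from survsel.data import SurvivalDataset
from survsel.penalized_cox import PenaltySpec, fit_penalized_cox, make_folds
from survsel.selection_rules import ci_rule
from survsel.sim_designs import SimulationDesign, generate_replicate
from survsel.spike_slab_cox import (
    SpikeSlabSpec,
    _em_ssvs,
    fit_gsslasso_cox,
    fit_sslasso_cox,
    fit_ssvs_cox,
    posterior_se,
)

from .conftest import toy_dataset


@pytest.fixture(scope="module")
def folds_small(small_replicate_module):
    data, _ = small_replicate_module
    return make_folds(data.n, data.event, 5, seed=0)


@pytest.fixture(scope="module")
def small_replicate_module():
    from .conftest import SMALL_DESIGN
    return generate_replicate(SMALL_DESIGN, seed=11)


class TestSpec:
    def test_ssvs_c_is_inverse_tau(self):
        assert SpikeSlabSpec("ssvs", tau=0.05).c == pytest.approx(20.0)

    def test_rejects_bad_scales(self):
        with pytest.raises(ValueError):
            SpikeSlabSpec("ssvs", tau=-1.0)
        with pytest.raises(ValueError):
            SpikeSlabSpec("sslasso", s0=2.0, s1=1.0)
        with pytest.raises(ValueError):
            SpikeSlabSpec("boom", tau=0.1)


class TestDegeneracies:
    def test_sslasso_equal_scales_is_lasso(self, small_replicate_module, folds_small):
        # s0 = s1 = s collapses the mixture to DE(0, s): the posterior
        # mode is the Cox lasso at lambda = 1/s
        data, _ = small_replicate_module
        s = 0.05
        fs = fit_sslasso_cox(data, s0_grid=[s], s1=s, fold_labels=folds_small)
        fl = fit_penalized_cox(data, PenaltySpec("lasso", lam=1.0 / s))
        assert np.abs(fs.beta_hat - fl.beta).max() < 1e-4

    def test_gsslasso_singleton_groups_is_sslasso(self, small_replicate_module,
                                                  folds_small):
        data, _ = small_replicate_module
        fss = fit_sslasso_cox(data, s0_grid=[0.02], fold_labels=folds_small)
        fgs = fit_gsslasso_cox(data, groups=np.arange(data.p), s0_grid=[0.02],
                               fold_labels=folds_small)
        assert np.abs(fgs.beta_hat - fss.beta_hat).max() < 1e-6

    def test_ssvs_tau_one_is_ridge_posterior(self):
        # c = 1/tau = 1 collapses spike and slab to N(0,1): the posterior
        # mode maximizes pl(beta) - 0.5 beta'beta (independent oracle:
        # scipy optimization)
        d = toy_dataset(seed=2, n=80, p=3, beta=(0.8, -0.8, 0.0))
        pc = PreparedCox.from_dataset(d)
        beta, *_ = _em_ssvs(pc, tau=1.0)

        def neg_obj(b):
            return -(pc.pl(b) - 0.5 * b @ b)

        res = optimize.minimize(neg_obj, np.zeros(3), method="BFGS")
        assert np.abs(beta - res.x).max() < 1e-4

    def test_s0_to_zero_pure_noise_all_zero(self):
        rng = np.random.default_rng(5)
        d = SurvivalDataset(time=rng.exponential(1, 100),
                            event=rng.integers(0, 2, 100),
                            X=rng.standard_normal((100, 10)))
        fit = fit_sslasso_cox(d, s0_grid=[1e-4], fold_labels=np.zeros(100, dtype=int))
        assert np.all(fit.beta_hat == 0)

    def test_zero_events_beta_zero(self):
        d = SurvivalDataset(time=np.arange(1.0, 21), event=np.zeros(20),
                            X=np.random.default_rng(0).standard_normal((20, 4)))
        fit = fit_ssvs_cox(d, tau_grid=[0.01], fold_labels=np.zeros(20, dtype=int))
        assert np.all(fit.beta_hat == 0)


class TestEMBehaviour:
    def test_traces_nondecreasing(self, small_replicate_module, folds_small):
        data, _ = small_replicate_module
        fits = [
            fit_ssvs_cox(data, tau_grid=[0.01], fold_labels=folds_small),
            fit_sslasso_cox(data, s0_grid=[0.02], fold_labels=folds_small),
            fit_gsslasso_cox(data, s0_grid=[0.02], fold_labels=folds_small),
        ]
        for fit in fits:
            tr = np.array(fit.extras["trace"])
            assert np.all(np.diff(tr) >= -1e-6 * (np.abs(tr[:-1]) + 1.0)), fit.method

    def test_strong_variable_high_gamma(self, strong_toy_data):
        folds = make_folds(strong_toy_data.n, strong_toy_data.event, 5, seed=0)
        fit = fit_sslasso_cox(strong_toy_data, s0_grid=[0.05], fold_labels=folds)
        assert fit.gamma_post[0] > 0.5
        assert fit.gamma_post[1] > 0.5

    def test_gamma_monotone_in_abs_beta(self, small_replicate_module, folds_small):
        # monotone in |beta| up to ties (|beta| equal within 1e-7)
        data, _ = small_replicate_module
        fit = fit_sslasso_cox(data, s0_grid=[0.02], fold_labels=folds_small)
        ab = np.abs(fit.extras["beta_std"])
        order = np.argsort(ab)
        ab, g = ab[order], fit.gamma_post[order]
        for i in range(len(g) - 1):
            if ab[i + 1] - ab[i] > 1e-7:
                assert g[i + 1] >= g[i] - 1e-9


    def test_grouped_p_post_peaks_on_signal_block(self):
        # all true variables inside one block -> that group's p_post is max
        design = SimulationDesign(design_id=2, n=300, p=40, q=4,
                                  beta_range=(-1.0, -0.5), rho=0.5, block_size=10,
                                  censor_rate_c=0.17, support_in_one_block=True, seed=0)
        data, tm = generate_replicate(design, seed=3)
        assert tm.support.max() < 10
        folds = make_folds(data.n, data.event, 5, seed=0)
        fit = fit_gsslasso_cox(data, s0_grid=[0.05], fold_labels=folds)
        assert np.argmax(fit.p_post) == 0

    def test_gamma_and_p_in_unit_interval(self, small_replicate_module, folds_small):
        data, _ = small_replicate_module
        fit = fit_gsslasso_cox(data, s0_grid=[0.02], fold_labels=folds_small)
        assert np.all((fit.gamma_post >= 0) & (fit.gamma_post <= 1))
        assert np.all((fit.p_post >= 0) & (fit.p_post <= 1))
        assert len(fit.p_post) == len(np.unique(data.groups))

    def test_cv_selects_from_grid(self, small_replicate_module, folds_small):
        data, _ = small_replicate_module
        fit = fit_sslasso_cox(data, s0_grid=[0.01, 0.05], fold_labels=folds_small)
        assert fit.chosen_scale in (0.01, 0.05)
        dev = fit.hyperparams["cv_deviance"]
        assert fit.chosen_scale == fit.hyperparams["scale_grid"][int(np.argmin(dev))]


class TestParameterRecovery:
    def test_high_signal_independent_covariates(self):
        # sign recovery and mean absolute bias < 0.15 at rho=0
        biases = []
        for seed in range(3):
            design = SimulationDesign(design_id=2, n=450, p=50, q=5,
                                      beta_range=(-1.0, -0.5), rho=0.0,
                                      block_size=10, censor_rate_c=0.17, seed=seed)
            data, tm = generate_replicate(design, seed=seed)
            folds = make_folds(data.n, data.event, 5, seed=seed)
            fit = fit_sslasso_cox(data, s0_grid=[0.05], fold_labels=folds)
            est = fit.beta_hat[tm.support]
            assert np.all(est < 0)
            biases.append(np.abs(est - tm.beta[tm.support]).mean())
        assert np.mean(biases) < 0.15


class TestPosteriorSE:
    def test_duplicate_columns_equal_se(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        d = SurvivalDataset(time=rng.exponential(1, 60), event=np.ones(60),
                            X=np.c_[x, x])
        pc = PreparedCox.from_dataset(d)
        se = posterior_se(np.array([2.0, 2.0]), pc, np.array([0.1, 0.1]))
        assert se[0] == pytest.approx(se[1])

    def test_information_doubling_shrinks_se(self):
        d = toy_dataset(seed=7, n=200, p=2, beta=(0.5, -0.5))
        d2 = SurvivalDataset(time=np.r_[d.time, d.time], event=np.r_[d.event, d.event],
                             X=np.r_[d.X, d.X])
        prec = np.array([1.0, 1.0])
        beta = np.array([0.3, -0.3])
        se1 = posterior_se(prec, PreparedCox.from_dataset(d), beta)
        se2 = posterior_se(prec, PreparedCox.from_dataset(d2), beta)
        # prior precision is fixed, likelihood information doubles
        assert np.all(se2 < se1)
        assert np.allclose(se2, se1 / np.sqrt(2), rtol=0.06)

    def test_spiked_zero_coefficient_never_selected(self):
        # huge prior curvature at a zero coefficient -> tiny SE -> the CI
        # rule cannot select it
        d = toy_dataset(seed=8, n=100, p=2, beta=(0.8, 0.0))
        fit = fit_sslasso_cox(d, s0_grid=[0.005],
                              fold_labels=make_folds(d.n, d.event, 5, seed=0))
        zero = np.flatnonzero(fit.beta_hat == 0)
        if len(zero):
            sel = ci_rule(fit.beta_hat, fit.se, alpha=0.05)
            assert not set(zero.tolist()) & set(sel.tolist())

    def test_se_strictly_positive(self, small_replicate_module, folds_small):
        data, _ = small_replicate_module
        fit = fit_gsslasso_cox(data, s0_grid=[0.02], fold_labels=folds_small)
        assert np.all(fit.se > 0)


class TestValidation:
    def test_gsslasso_requires_groups(self):
        d = toy_dataset(seed=0)
        with pytest.raises(ValueError, match="group"):
            fit_gsslasso_cox(d, s0_grid=[0.02],
                             fold_labels=np.zeros(d.n, dtype=int))

    def test_bad_grids_rejected(self):
        d = toy_dataset(seed=0)
        with pytest.raises(ValueError):
            fit_ssvs_cox(d, tau_grid=[-0.1])
        with pytest.raises(ValueError):
            fit_sslasso_cox(d, s0_grid=[2.0], s1=1.0)
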