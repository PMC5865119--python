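"""The multinomial-logit use model: likelihood, priors, MCMC, diagnostics, DIC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_point_posterior
from triselect.habitat_model import (
    Coefficients,
    Posterior,
    PosteriorDraw,
    UseRecord,
    compare_dic,
    dic,
    gelman_rubin,
    linear_predictor,
    log_likelihood,
    log_prior,
    posterior_to_frame,
    read_records,
    records_from_frame,
    records_to_frame,
    sample_posterior,
    use_probabilities,
    write_records,
)
from triselect.simplex_core import make_composition
from triselect.synthetic_data import preset_scenarios, simulate_dataset


def pooled_coeffs(a):
    return Coefficients(form="pooled", a=np.asarray(a, dtype=float))


def make_draw(a, sigma=1.0, eps=None, animals=(("A", "x"),), form="pooled", sites=()):
    K = len(animals)
    eps = np.zeros((K, 2)) if eps is None else np.asarray(eps, dtype=float)
    return PosteriorDraw(
        coeffs=Coefficients(form=form, a=np.asarray(a, dtype=float), sites=sites),
        sigma=sigma, eps=eps, animals=tuple(animals),
    )


class TestLinearPredictor:
    def test_zero_coefficients(self):
        c = pooled_coeffs(np.zeros((1, 2, 3)))
        d = make_composition([0.5, 0.2, 0.3])
        assert linear_predictor(c, "anywhere", d) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        c = pooled_coeffs([[[1, 2, 3], [0, 1, 0]]])
        d = make_composition([0.5, 0.2, 0.3])
        eta1, eta2 = linear_predictor(c, "A", d)
        assert eta1 == pytest.approx(1 + 2 * 0.5 + 3 * 0.2)  # 2.6
        assert eta2 == pytest.approx(0.5)

    def test_pooled_form_ignores_site(self):
        c = pooled_coeffs([[[0.3, -1, 2], [0.1, 0.5, -0.5]]])
        d = make_composition([0.4, 0.4, 0.2])
        assert linear_predictor(c, "A", d) == linear_predictor(c, "B", d)

    def test_site_specific_unknown_site_errors(self):
        c = Coefficients(form="site_specific", sites=("A",), a=np.zeros((1, 2, 3)))
        with pytest.raises(KeyError):
            linear_predictor(c, "Z", make_composition([0.4, 0.4, 0.2]))


class TestUseProbabilities:
    def test_symmetry(self):
        p = use_probabilities(0, 0)
        assert p.as_array() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_closed_form(self):
        p = use_probabilities(np.log(2), 0)
        assert p.as_array() == pytest.approx([0.5, 0.25, 0.25])

    def test_logit_round_trip(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            eta = rng.normal(0, 3, 2)
            eps = rng.normal(0, 1, 2)
            p = use_probabilities(eta[0], eta[1], eps[0], eps[1]).as_array()
            assert np.log(p[0] / p[2]) == pytest.approx(eta[0] + eps[0], abs=1e-12)
            assert np.log(p[1] / p[2]) == pytest.approx(eta[1] + eps[1], abs=1e-12)

    @pytest.mark.parametrize("eta", [(700, 0), (-700, 0), (700, 700), (-700, -700)])
    def test_overflow_safe_closure(self, eta):
        p = use_probabilities(*eta).as_array()
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)


class TestLogLikelihood:
    def test_single_relocation_uniform(self):
        rec = UseRecord(site="A", animal_id="x", n=[0, 0, 1], d=make_composition([0.3, 0.3, 0.4]))
        draw = make_draw(np.zeros((1, 2, 3)))
        assert log_likelihood(rec, draw) == pytest.approx(np.log(1 / 3))

    def test_single_category(self):
        rec = UseRecord(site="A", animal_id="x", n=[0, 0, 8], d=make_composition([0.3, 0.3, 0.4]))
        draw = make_draw([[[1.0, 0, 0], [0.5, 0, 0]]])
        p3 = use_probabilities(1.0, 0.5).as_array()[2]
        assert log_likelihood(rec, draw) == pytest.approx(8 * np.log(p3))

    @pytest.mark.parametrize("N", [1, 2, 4, 6])
    def test_pmf_normalizes_by_enumeration(self, N):
        """Summing exp(log-pmf) over every count vector (n1, n2, n3) with
        n1+n2+n3 = N must give 1 — verifies both kernel and combinatorial
        constant."""
        draw = make_draw([[[0.7, -1.2, 0.4], [-0.3, 0.8, 0.2]]], eps=[[0.2, -0.1]])
        d = make_composition([0.45, 0.25, 0.30])
        total = 0.0
        for n1, n2 in itertools.product(range(N + 1), repeat=2):
            if n1 + n2 > N:
                continue
            rec = UseRecord(site="A", animal_id="x", n=[n1, n2, N - n1 - n2], d=d)
            total += np.exp(log_likelihood(rec, draw))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_missing_residuals_error(self):
        rec = UseRecord(site="B", animal_id="y", n=[1, 1, 1], d=make_composition([0.3, 0.3, 0.4]))
        with pytest.raises(KeyError):
            log_likelihood(rec, make_draw(np.zeros((1, 2, 3))))


class TestLogPrior:
    def test_closed_form_value(self):
        draw = make_draw(np.zeros((1, 2, 3)), sigma=np.sqrt(50.0))
        # 6 standard-normal-with-var-1000 terms at 0, log(1/100) for sig2,
        # 2 eps terms at 0 with var 50
        expected = (
            -0.5 * 6 * np.log(2 * np.pi * 1000)
            - np.log(100)
            - 0.5 * 2 * np.log(2 * np.pi * 50)
        )
        assert log_prior(draw) == pytest.approx(expected)

    def test_sigma_outside_support(self):
        assert log_prior(make_draw(np.zeros((1, 2, 3)), sigma=np.sqrt(101.0))) == -np.inf
        assert log_prior(make_draw(np.zeros((1, 2, 3)), sigma=0.0)) == -np.inf

    def test_doubling_zero_eps_adds_known_constant(self):
        sig = 2.0
        one = make_draw(np.zeros((1, 2, 3)), sigma=sig, animals=(("A", "x"),))
        two = make_draw(
            np.zeros((1, 2, 3)), sigma=sig,
            animals=(("A", "x"), ("A", "y")), eps=np.zeros((2, 2)),
        )
        assert log_prior(two) - log_prior(one) == pytest.approx(
            -0.5 * 2 * np.log(2 * np.pi * sig**2)
        )


class TestSampler:
    def test_same_seed_bit_identical(self, small_dataset):
        records, _ = small_dataset
        kw = dict(form="pooled", chains=2, iterations=400, burn_in=100, thin=2, seed=99)
        p1 = sample_posterior(records, **kw)
        p2 = sample_posterior(records, **kw)
        assert np.array_equal(p1.a, p2.a)
        assert np.array_equal(p1.sigma, p2.sigma)
        assert np.array_equal(p1.eps, p2.eps)

    def test_loglik_invariant_under_record_permutation(self, small_dataset):
        records, truth = small_dataset
        draw = PosteriorDraw(
            coeffs=truth.coeffs, sigma=truth.sigma, eps=truth.eps, animals=truth.animals
        )
        fwd = sum(log_likelihood(r, draw) for r in records)
        rev = sum(log_likelihood(r, draw) for r in reversed(records))
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_config_validation(self, small_dataset):
        records, _ = small_dataset
        with pytest.raises(ValueError):
            sample_posterior(records, chains=1)
        with pytest.raises(ValueError):
            sample_posterior(records, iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            sample_posterior([], form="site_specific")

    def test_checkpoint_resume_reproduces_uninterrupted_run(self, small_dataset, tmp_path):
        """A run that resumes from a mid-stream checkpoint must yield the
        same draws as an uninterrupted run with the same seed."""
        records, _ = small_dataset
        kw = dict(form="pooled", chains=2, iterations=300, burn_in=100, thin=2, seed=17)
        full = sample_posterior(records, **kw)
        ckpt = tmp_path / "chain.npz"
        first = sample_posterior(records, checkpoint_path=str(ckpt), checkpoint_every=100, **kw)
        assert ckpt.exists()
        # the completed run left its last checkpoint behind; a rerun resumes
        # from it and must reproduce the identical posterior
        resumed = sample_posterior(records, checkpoint_path=str(ckpt), checkpoint_every=100, **kw)
        for post in (first, resumed):
            assert np.array_equal(post.a, full.a)
            assert np.array_equal(post.sigma, full.sigma)
            assert np.array_equal(post.eps, full.eps)

    def test_posterior_export_tidy(self, small_fit):
        post, _ = small_fit
        df = posterior_to_frame(post)
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        assert df["parameter"].nunique() == 7  # 6 coefficients + sigma
        assert len(df) == post.n_total * 7


class TestGelmanRubin:
    def _posterior_from_series(self, series):
        """series: (chains, draws) -> single-parameter pooled posterior."""
        C, M = series.shape
        a = np.zeros((C, M, 1, 2, 3))
        a[:, :, 0, 0, 0] = series
        return Posterior(
            form="pooled", sites=(), animals=(),
            a=a, sigma=np.ones((C, M)), eps=np.zeros((C, M, 0, 2)),
        )

    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(11)
        one = rng.normal(size=2000)
        post = self._posterior_from_series(np.stack([one, one]))
        rhat = gelman_rubin(post, include_sigma=False)
        assert rhat.iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_same_distribution_below_105(self):
        rng = np.random.default_rng(12)
        post = self._posterior_from_series(rng.normal(size=(3, 2000)))
        assert gelman_rubin(post, include_sigma=False).iloc[0] < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(13)
        series = rng.normal(size=(2, 2000))
        series[1] += 10
        rhat = gelman_rubin(self._posterior_from_series(series), include_sigma=False)
        assert rhat.iloc[0] > 1.1

    def test_single_chain_errors(self):
        post = self._posterior_from_series(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(post)


class TestDic:
    def test_degenerate_posterior_zero_pd(self, simple_record):
        post = make_point_posterior(
            a=[[[0.5, 1.0, -0.5], [0.2, 0.0, 0.3]]], animals=(("A", "x"),), draws=80
        )
        res = dic(post, [simple_record])
        assert res.p_d == pytest.approx(0.0, abs=1e-9)
        assert res.dic == pytest.approx(res.mean_deviance)
        assert res.p_d_var == pytest.approx(0.0, abs=1e-9)

    def test_pd_var_matches_deviance_variance(self, small_fit):
        post, records = small_fit
        res = dic(post, records)
        assert res.p_d_var == pytest.approx(res.deviances.var(ddof=1) / 2)

    def test_matches_independent_recomputation(self, small_fit):
        """Recompute the deviance of the first draws through the scalar
        log-likelihood path and compare with the vectorized DIC internals."""
        post, records = small_fit
        res = dic(post, records)
        for r_idx, draw in zip(range(5), post.iter_draws()):
            dev = -2 * sum(log_likelihood(rec, draw) for rec in records)
            assert res.deviances[r_idx] == pytest.approx(dev, rel=1e-10)

    def test_refuses_tiny_posteriors(self, simple_record):
        post = make_point_posterior(
            a=np.zeros((1, 2, 3)), animals=(("A", "x"),), chains=2, draws=20
        )
        with pytest.raises(ValueError):
            dic(post, [simple_record])

    def test_identical_models_delta_zero(self, small_fit):
        post, records = small_fit
        comp = compare_dic(post, post, records, seed=1)
        assert comp.delta_dic == pytest.approx(0.0, abs=1e-9)
        assert comp.se == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_datasets_rejected(self, small_fit, contrast_fit):
        post, records = small_fit
        post2, records2, _ = contrast_fit
        with pytest.raises(ValueError):
            compare_dic(post, post2, records)

    def test_bootstrap_se_of_mean_contribution_shrinks(self):
        """SE of the mean per-individual contribution scales ~ 1/sqrt(K):
        check the bootstrap machinery at K = 30 vs 120 individuals."""
        sc = preset_scenarios()["pooled"]
        out = {}
        for K_per_site, seed in [(10, 21), (40, 22)]:
            sc_k = type(sc)(
                name=sc.name, sites=sc.sites, coeffs=sc.coeffs, sigma=sc.sigma,
                animals_per_site=K_per_site, fixes_per_animal=300, seed=seed,
            )
            records, _ = simulate_dataset(sc_k)
            p1 = sample_posterior(records, form="pooled", chains=2,
                                  iterations=2000, burn_in=500, thin=5, seed=seed)
            p2 = sample_posterior(records, form="site_specific", chains=2,
                                  iterations=2000, burn_in=500, thin=5, seed=seed + 1)
            comp = compare_dic(p1, p2, records, seed=seed)
            out[3 * K_per_site] = comp.se / (3 * K_per_site)  # SE of the mean
        ratio = out[30] / out[120]
        assert ratio == pytest.approx(2.0, rel=0.5)  # sqrt(120/30) = 2


def test_record_table_round_trip(tmp_path, small_dataset):
    records, _ = small_dataset
    path = tmp_path / "records.csv"
    write_records(records, path)
    back = read_records(path)
    assert len(back) == len(records)
    assert back[0].n.tolist() == records[0].n.tolist()
    assert back[0].d.as_array() == pytest.approx(records[0].d.as_array())
    pd.testing.assert_frame_equal(records_to_frame(back), records_to_frame(records))


def test_records_from_frame_validates_columns():
    with pytest.raises(ValueError):
        records_from_frame(pd.DataFrame({"site": ["A"]}))


def test_use_record_invariants():
    with pytest.raises(ValueError):
        UseRecord(site="A", animal_id="x", n=[0, 0, 0], d=make_composition([0.3, 0.3, 0.4]))
    with pytest.raises(ValueError):
        UseRecord(site="A", animal_id="x", n=[-1, 2, 3], d=make_composition([0.3, 0.3, 0.4]))
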