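"""Bayesian multinomial-logit model of within-home-range habitat use.

For animal *i* in site *s* with availability composition ``d`` and ``N``
relocations split into counts ``n`` over (shrub, pole, cws):

    n_{s,i} ~ Multinomial(N_{s,i}, p_{s,i})
    log(p_{s,i,h} / p_{s,i,3}) = f_h(d_{s,i,1}, d_{s,i,2}) + eps_{s,i,h}
    eps_{s,i,h} ~ Normal(0, sigma^2)                      h in {1, 2}

with cws (h = 3) the reference habitat.  Two linear predictors are
supported: *pooled* — coefficients (a0, a1, a2) per logit shared by all
sites — and *site_specific* — one coefficient triple per logit per site.
The per-individual Gaussian residual eps absorbs extra-multinomial
variance from temporally autocorrelated fixes.

Priors are weakly informative: a ~ Normal(0, variance 1000) and
sigma^2 ~ Uniform(0, 100).  Posterior sampling is Metropolis-within-Gibbs:
adaptive random-walk updates for each coefficient block, jointly proposed
per-individual residual pairs with record-wise acceptance, and an exact
Gibbs draw for sigma^2 from its truncated inverse-gamma conditional.
Chains are advanced together as a batch dimension, so runs are fast and
bit-reproducible for a given seed.

Model comparison uses the conditional DIC (deviance evaluated given the
sampled residuals, the flavor BUGS-family software reports for this
parameterization), with a nonparametric bootstrap over individuals for
the standard error of a DIC difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simplex_core import Composition, make_composition

Form = Literal["pooled", "site_specific"]

#: prior variance of the linear-predictor coefficients a
PRIOR_VAR_A = 1000.0
#: upper bound of the uniform prior on sigma^2
SIG2_MAX = 100.0

LOGIT_LABELS = ("shrub", "pole")  # logits h=1,2 relative to cws


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UseRecord:
    """One animal's availability composition and relocation counts."""

    site: str
    animal_id: str
    n: np.ndarray  # counts (shrub, pole, cws)
    d: Composition

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        if self.n.shape != (3,) or np.any(self.n < 0):
            raise ValueError("n must be 3 non-negative counts")
        if self.n.sum() < 1:
            raise ValueError("record must contain at least one relocation")

    @property
    def N(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class Coefficients:
    """Linear-predictor coefficients.

    ``a`` has shape (S, 2, 3): site x logit x (intercept, d_shrub slope,
    d_pole slope); S = 1 and ``sites = ()`` for the pooled form.
    """

    form: Form
    a: np.ndarray
    sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        S = len(self.sites) if self.form == "site_specific" else 1
        if a.shape != (S, 2, 3):
            raise ValueError(f"coefficient array must have shape ({S}, 2, 3), got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("coefficients must be finite")

    def site_index(self, site: str) -> int:
        if self.form == "pooled":
            return 0
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r} for site-specific coefficients") from None


@dataclass(frozen=True)
class PosteriorDraw:
    """One MCMC sample: coefficients, overdispersion SD, residuals."""

    coeffs: Coefficients
    sigma: float
    eps: np.ndarray                      # (K, 2) aligned with `animals`
    animals: tuple[tuple[str, str], ...]  # (site, animal_id) per row of eps

    def eps_for(self, record: UseRecord) -> np.ndarray:
        try:
            k = self.animals.index((record.site, record.animal_id))
        except ValueError:
            raise KeyError(
                f"draw carries no residuals for {(record.site, record.animal_id)}"
            ) from None
        return self.eps[k]


@dataclass
class Posterior:
    """Posterior sample for one model form, stored per chain."""

    form: Form
    sites: tuple[str, ...]
    animals: tuple[tuple[str, str], ...]
    a: np.ndarray       # (chains, draws, S, 2, 3)
    sigma: np.ndarray   # (chains, draws)
    eps: np.ndarray     # (chains, draws, K, 2)
    chain_meta: dict = field(default_factory=dict)
    data_key: tuple = ()

    @property
    def n_chains(self) -> int:
        return self.a.shape[0]

    @property
    def n_draws(self) -> int:
        """Kept draws per chain."""
        return self.a.shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    def flat_a(self) -> np.ndarray:
        return self.a.reshape(self.n_total, *self.a.shape[2:])

    def flat_sigma(self) -> np.ndarray:
        return self.sigma.reshape(self.n_total)

    def flat_eps(self) -> np.ndarray:
        return self.eps.reshape(self.n_total, *self.eps.shape[2:])

    def coefficient_labels(self) -> list[str]:
        labels = []
        S = self.a.shape[2]
        for s in range(S):
            for h, hl in enumerate(LOGIT_LABELS):
                for j in range(3):
                    name = f"a{j}[{hl}]"
                    if self.form == "site_specific":
                        name = f"a{j}[{hl},{self.sites[s]}]"
                    labels.append(name)
        return labels

    def iter_draws(self) -> Iterable[PosteriorDraw]:
        sites = self.sites if self.form == "site_specific" else ()
        for a, sig, eps in zip(self.flat_a(), self.flat_sigma(), self.flat_eps()):
            yield PosteriorDraw(
                coeffs=Coefficients(form=self.form, a=a, sites=sites),
                sigma=float(sig), eps=eps, animals=self.animals,
            )

    def mean_coefficients(self) -> Coefficients:
        sites = self.sites if self.form == "site_specific" else ()
        return Coefficients(form=self.form, a=self.flat_a().mean(axis=0), sites=sites)


def records_to_frame(records: Sequence[UseRecord]) -> pd.DataFrame:
    rows = [
        dict(site=r.site, animal_id=r.animal_id,
             n_shrub=int(r.n[0]), n_pole=int(r.n[1]), n_cws=int(r.n[2]),
             d_shrub=r.d.p_shrub, d_pole=r.d.p_pole, d_cws=r.d.p_cws)
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


RECORD_COLUMNS = ["site", "animal_id", "n_shrub", "n_pole", "n_cws",
                  "d_shrub", "d_pole", "d_cws"]


def records_from_frame(df: pd.DataFrame) -> list[UseRecord]:
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"use-record table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            UseRecord(
                site=str(row.site), animal_id=str(row.animal_id),
                n=np.array([row.n_shrub, row.n_pole, row.n_cws]),
                d=make_composition([row.d_shrub, row.d_pole, row.d_cws]),
            )
        )
    return records


def read_records(path) -> list[UseRecord]:
    return records_from_frame(pd.read_csv(path, comment="#"))


def write_records(records: Sequence[UseRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _data_key(records: Sequence[UseRecord]) -> tuple:
    return tuple(
        (r.site, r.animal_id, tuple(int(v) for v in r.n),
         tuple(np.round(r.d.as_array(), 12)))
        for r in records
    )


# ---------------------------------------------------------------------------
# Model primitives
# ---------------------------------------------------------------------------

def linear_predictor(coeffs: Coefficients, site: str, d: Composition) -> tuple[float, float]:
    """Mean multinomial logits (eta_1, eta_2) for availability ``d``:
    eta_h = a0_h + a1_h * d_shrub + a2_h * d_pole."""
    s = coeffs.site_index(site)
    x = np.array([1.0, d.p_shrub, d.p_pole])
    eta = coeffs.a[s] @ x
    return float(eta[0]), float(eta[1])


def use_probabilities(
    eta1: float, eta2: float, eps1: float = 0.0, eps2: float = 0.0
) -> Composition:
    """Invert the multinomial logit (reference habitat cws, logit 0).

    Overflow-safe for arbitrarily large |eta + eps|.
    """
    z = np.array([eta1 + eps1, eta2 + eps2, 0.0])
    z -= z.max()
    ez = np.exp(z)
    p = ez / ez.sum()
    return Composition(*p)


def log_likelihood(record: UseRecord, draw: PosteriorDraw) -> float:
    """Multinomial log-pmf of the record's counts under one posterior draw."""
    eta = linear_predictor(draw.coeffs, record.site, record.d)
    eps = draw.eps_for(record)
    p = use_probabilities(eta[0], eta[1], eps[0], eps[1]).as_array()
    n = record.n
    logc = gammaln(record.N + 1) - gammaln(n + 1).sum()
    with np.errstate(divide="ignore"):
        logp = np.where(n > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    if np.any((n > 0) & (p <= 0)):
        return -np.inf
    return float(logc + (n * logp).sum())


def log_prior(
    draw: PosteriorDraw,
    prior_var: float = PRIOR_VAR_A,
    sig2_max: float = SIG2_MAX,
) -> float:
    """Joint log-prior: a ~ N(0, prior_var), sigma^2 ~ U(0, sig2_max),
    eps ~ N(0, sigma^2)."""
    sig2 = draw.sigma**2
    if not 0 < sig2 < sig2_max:
        return -np.inf
    a = draw.coeffs.a
    lp = -0.5 * a.size * math.log(2 * math.pi * prior_var) - 0.5 * (a**2).sum() / prior_var
    lp += -math.log(sig2_max)
    m = draw.eps.size
    lp += -0.5 * m * math.log(2 * math.pi * sig2) - 0.5 * (draw.eps**2).sum() / sig2
    return float(lp)


# ---------------------------------------------------------------------------
# Vectorized likelihood internals
# ---------------------------------------------------------------------------

def _ll_from_logits(te: np.ndarray, n12: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Per-record multinomial log-likelihood kernel (constant dropped).

    ``te``: total logits eta + eps, shape (..., K, 2); the reference logit
    is 0.  Returns shape (..., K).
    """
    m = np.maximum(te.max(axis=-1), 0.0)
    lse = m + np.log(
        np.exp(te[..., 0] - m) + np.exp(te[..., 1] - m) + np.exp(-m)
    )
    return (te * n12).sum(axis=-1) - N * lse


def _prepare(records: Sequence[UseRecord], form: Form):
    sites = tuple(sorted({r.site for r in records}))
    S = len(sites) if form == "site_specific" else 1
    K = len(records)
    X = np.array([[1.0, r.d.p_shrub, r.d.p_pole] for r in records]) if K else np.zeros((0, 3))
    n = np.array([r.n for r in records], dtype=float) if K else np.zeros((0, 3))
    site_idx = (
        np.array([sites.index(r.site) for r in records], dtype=int)
        if form == "site_specific" and K
        else np.zeros(K, dtype=int)
    )
    animals = tuple((r.site, r.animal_id) for r in records)
    return sites, S, K, X, n, site_idx, animals


def batched_loglik(
    a: np.ndarray, eps: np.ndarray, X: np.ndarray, n: np.ndarray, site_idx: np.ndarray
) -> np.ndarray:
    """Record log-likelihood (constant dropped) for batched parameters.

    ``a``: (R, S, 2, 3); ``eps``: (R, K, 2) -> (R, K).
    """
    A = a[:, site_idx]                      # (R, K, 2, 3)
    eta = np.einsum("rkhj,kj->rkh", A, X)
    te = eta + eps
    return _ll_from_logits(te, n[:, :2], n.sum(axis=1))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def sample_posterior(
    records: Sequence[UseRecord],
    form: Form = "site_specific",
    chains: int = 3,
    iterations: int = 5000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    prior_var: float = PRIOR_VAR_A,
    sig2_max: float = SIG2_MAX,
    checkpoint_path: str | None = None,
    checkpoint_every: int = 10_000,
) -> Posterior:
    """Draw from the posterior by Metropolis-within-Gibbs.

    ``iterations`` counts total updates per chain including ``burn_in``;
    one sample in every ``thin`` post-burn-in iterations is kept.  All
    chains share one seeded generator and advance together, so the same
    seed reproduces the chains bit for bit.  Proposal scales adapt toward
    a target acceptance rate during burn-in only, preserving detailed
    balance afterwards.

    With ``checkpoint_path``, sampler state (including the generator) is
    saved every ``checkpoint_every`` iterations and an interrupted run
    resumes from the last checkpoint, producing the same draws as an
    uninterrupted one — intended for publication-scale schedules (millions
    of iterations).
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if not (0 < burn_in < iterations):
        raise ValueError("need 0 < burn_in < iterations")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if form == "site_specific" and len(records) == 0:
        raise ValueError("site-specific form needs at least one record per site")

    rng = np.random.default_rng(seed)
    sites, S, K, X, n, site_idx, animals = _prepare(records, form)
    n12 = n[:, :2]
    Ntot = n.sum(axis=1)
    C = chains

    # state
    a = np.zeros((C, S, 2, 3))
    eps = np.zeros((C, K, 2))
    sig2 = np.ones(C)
    eta = np.einsum("ckhj,kj->ckh", a[:, site_idx], X) if K else np.zeros((C, K, 2))
    ll = _ll_from_logits(eta + eps, n12, Ntot) if K else np.zeros((C, K))

    # coefficient blocks: one per (site, logit)
    blocks = [(s, h) for s in range(S) for h in range(2)]
    block_idx = [np.nonzero(site_idx == s)[0] if form == "site_specific" else np.arange(K)
                 for s, _ in blocks]
    B = len(blocks)
    log_scale = np.full((B, C), math.log(0.1))
    log_scale_eps = np.full(C, math.log(0.1))
    target_a, target_eps = 0.28, 0.35
    acc_a = np.zeros((B, C))
    acc_eps = np.zeros(C)
    n_after = 0

    # adaptive proposal covariance per block per chain (Haario-style AM):
    # running first/second moments of the block samples feed a scaled
    # empirical covariance; frozen after burn-in to preserve detailed balance
    am_start = 200
    sum_x = np.zeros((B, C, 3))
    sum_xx = np.zeros((B, C, 3, 3))
    chol = np.broadcast_to(np.eye(3), (B, C, 3, 3)).copy()
    use_cov = False

    # translation moves: shift a coefficient block and compensate the
    # residuals of its records so the likelihood is untouched; this samples
    # the a/eps trade-off direction that blocked updates mix slowly along
    log_scale_shift = np.full((B, C), math.log(0.1))

    M = (iterations - burn_in + thin - 1) // thin
    a_store = np.empty((C, M, S, 2, 3))
    sig_store = np.empty((C, M))
    eps_store = np.empty((C, M, K, 2))

    alpha = K - 1.0  # inverse-gamma shape of the sigma^2 conditional (m/2 - 1)

    m_take = 0
    start_t = 0
    if checkpoint_path is not None and not str(checkpoint_path).endswith(".npz"):
        checkpoint_path = str(checkpoint_path) + ".npz"
    ckpt_cfg = dict(
        seed=seed, chains=chains, iterations=iterations, burn_in=burn_in,
        thin=thin, form=form, K=K, S=S, data_key=hash(_data_key(records)),
    )

    def _save_checkpoint(t_next: int) -> None:
        np.savez(
            checkpoint_path,
            config=np.array([ckpt_cfg], dtype=object),
            rng_state=np.array([rng.bit_generator.state], dtype=object),
            t_next=t_next, a=a, eps=eps, sig2=sig2,
            log_scale=log_scale, log_scale_eps=log_scale_eps,
            log_scale_shift=log_scale_shift,
            sum_x=sum_x, sum_xx=sum_xx, chol=chol, use_cov=use_cov,
            acc_a=acc_a, acc_eps=acc_eps, n_after=n_after, m_take=m_take,
            a_store=a_store[:, :m_take], sig_store=sig_store[:, :m_take],
            eps_store=eps_store[:, :m_take],
        )

    if checkpoint_path is not None:
        from pathlib import Path

        if Path(checkpoint_path).exists():
            data = np.load(checkpoint_path, allow_pickle=True)
            if data["config"][0] == ckpt_cfg:
                a, eps, sig2 = data["a"], data["eps"], data["sig2"]
                log_scale = data["log_scale"]
                log_scale_eps = data["log_scale_eps"]
                log_scale_shift = data["log_scale_shift"]
                sum_x, sum_xx, chol = data["sum_x"], data["sum_xx"], data["chol"]
                use_cov = bool(data["use_cov"])
                acc_a, acc_eps = data["acc_a"], data["acc_eps"]
                n_after = int(data["n_after"])
                m_take = int(data["m_take"])
                a_store[:, :m_take] = data["a_store"]
                sig_store[:, :m_take] = data["sig_store"]
                eps_store[:, :m_take] = data["eps_store"]
                rng.bit_generator.state = data["rng_state"][0]
                start_t = int(data["t_next"])
                eta = (
                    np.einsum("ckhj,kj->ckh", a[:, site_idx], X)
                    if K else np.zeros((C, K, 2))
                )
                ll = _ll_from_logits(eta + eps, n12, Ntot) if K else np.zeros((C, K))

    for t in range(start_t, iterations):
        if checkpoint_path is not None and t > start_t and t % checkpoint_every == 0:
            _save_checkpoint(t)
        adapting = t < burn_in
        gamma = (t + 1) ** -0.6 if adapting else 0.0

        if adapting and t >= am_start and t % 25 == 0 and t > 0:
            # refresh the proposal cholesky from the accumulated moments
            mean = sum_x / t
            cov = sum_xx / t - np.einsum("bci,bcj->bcij", mean, mean)
            cov = cov * (2.38**2 / 3.0) + 1e-8 * np.eye(3)
            try:
                chol = np.linalg.cholesky(cov)
                if not use_cov:
                    log_scale[:] = 0.0  # scale now lives in the covariance
                use_cov = True
            except np.linalg.LinAlgError:
                pass

        # --- coefficient blocks ---------------------------------------
        for b, (s, h) in enumerate(blocks):
            idx = block_idx[b]
            cur = a[:, s, h, :]                                   # (C, 3)
            z = rng.standard_normal((C, 3))
            if use_cov:
                step = np.einsum("cij,cj->ci", chol[b], z)
            else:
                step = z
            prop = cur + step * np.exp(log_scale[b])[:, None]
            dlp = -0.5 * ((prop**2).sum(1) - (cur**2).sum(1)) / prior_var
            if len(idx):
                Xs = X[idx]
                te = (eta[:, idx, :] + eps[:, idx, :]).copy()     # (C, Ks, 2)
                eta_new_h = prop @ Xs.T                           # (C, Ks)
                te[:, :, h] = eta_new_h + eps[:, idx, h]
                ll_new = _ll_from_logits(te, n12[idx], Ntot[idx])
                dll = (ll_new - ll[:, idx]).sum(axis=1)
            else:
                dll = np.zeros(C)
            accept = np.log(rng.random(C)) < dll + dlp
            if accept.any():
                rows = np.nonzero(accept)[0]
                a[rows, s, h, :] = prop[rows]
                if len(idx):
                    eta[np.ix_(rows, idx, [h])] = eta_new_h[rows][:, :, None]
                    ll[np.ix_(rows, idx)] = ll_new[rows]
            if adapting:
                log_scale[b] += gamma * (accept.astype(float) - target_a)
            else:
                acc_a[b] += accept

        # --- translation moves (likelihood-invariant) -----------------
        if K:
            for b, (s, h) in enumerate(blocks):
                idx = block_idx[b]
                if not len(idx):
                    continue
                cur = a[:, s, h, :]
                delta = rng.standard_normal((C, 3)) * np.exp(log_scale_shift[b])[:, None]
                prop = cur + delta
                shift = delta @ X[idx].T                          # (C, Ks)
                eps_new = eps[:, idx, h] - shift
                dlp = -0.5 * ((prop**2).sum(1) - (cur**2).sum(1)) / prior_var
                dlp += -0.5 * (eps_new**2 - eps[:, idx, h] ** 2).sum(1) / sig2
                accept = np.log(rng.random(C)) < dlp
                if accept.any():
                    rows = np.nonzero(accept)[0]
                    a[rows, s, h, :] = prop[rows]
                    eps[np.ix_(rows, idx, [h])] = eps_new[rows][:, :, None]
                    eta[np.ix_(rows, idx, [h])] += shift[rows][:, :, None]
                if adapting:
                    log_scale_shift[b] += gamma * (accept.astype(float) - target_a)

        # --- residual pairs (record-wise Metropolis) ------------------
        if K:
            prop_eps = eps + rng.standard_normal((C, K, 2)) * np.exp(log_scale_eps)[:, None, None]
            ll_new = _ll_from_logits(eta + prop_eps, n12, Ntot)
            dlp = -0.5 * ((prop_eps**2).sum(-1) - (eps**2).sum(-1)) / sig2[:, None]
            accept = np.log(rng.random((C, K))) < (ll_new - ll) + dlp
            eps = np.where(accept[:, :, None], prop_eps, eps)
            ll = np.where(accept, ll_new, ll)
            rate = accept.mean(axis=1)
            if adapting:
                log_scale_eps += gamma * (rate - target_eps)
            else:
                acc_eps += rate

        # --- sigma^2: exact Gibbs from truncated inverse-gamma --------
        if K == 0:
            sig2 = rng.uniform(0.0, sig2_max, size=C)
        elif alpha > 0:
            beta = 0.5 * (eps**2).sum(axis=(1, 2))
            # 1/sig2 ~ Gamma(alpha, 1/beta) truncated to > 1/sig2_max
            new = 1.0 / rng.gamma(alpha, 1.0 / beta)
            bad = new >= sig2_max
            for _ in range(100):
                if not bad.any():
                    break
                new[bad] = 1.0 / rng.gamma(alpha, 1.0 / beta[bad])
                bad = new >= sig2_max
            sig2 = np.where(new < sig2_max, new, sig2)
        else:
            # K == 1: improper-looking but integrable conditional; random walk
            lsig2 = np.log(sig2)
            prop = lsig2 + 0.5 * rng.standard_normal(C)
            s2p = np.exp(prop)
            beta = 0.5 * (eps**2).sum(axis=(1, 2))
            logpost = lambda s2: -K * np.log(s2) - beta / s2 + np.log(s2)  # + Jacobian
            accept = (s2p < sig2_max) & (
                np.log(rng.random(C)) < logpost(s2p) - logpost(sig2)
            )
            sig2 = np.where(accept, s2p, sig2)

        if adapting:
            ab = np.stack([a[:, s, h, :] for s, h in blocks])  # (B, C, 3)
            sum_x += ab
            sum_xx += np.einsum("bci,bcj->bcij", ab, ab)

        if not adapting and (t - burn_in) % thin == 0:
            a_store[:, m_take] = a
            sig_store[:, m_take] = np.sqrt(sig2)
            eps_store[:, m_take] = eps
            m_take += 1
        if not adapting:
            n_after += 1

    meta = dict(
        iterations=iterations, burn_in=burn_in, thin=thin, seed=seed,
        chains=chains, prior_var=prior_var, sig2_max=sig2_max,
        accept_a=(acc_a / max(n_after, 1)).mean(axis=1).tolist(),
        accept_eps=float((acc_eps / max(n_after, 1)).mean()) if K else None,
    )
    return Posterior(
        form=form, sites=sites, animals=animals,
        a=a_store[:, :m_take], sigma=sig_store[:, :m_take], eps=eps_store[:, :m_take],
        chain_meta=meta, data_key=_data_key(records),
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(post: Posterior, include_sigma: bool = True) -> pd.Series:
    """Classic potential scale reduction factor per scalar parameter.

    R-hat near 1 indicates the chains have mixed; values above 1.1 are
    conventionally flagged as unconverged.
    """
    if post.n_chains < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    names = post.coefficient_labels()
    C, M = post.n_chains, post.n_draws
    series = post.a.reshape(C, M, -1)
    if include_sigma:
        series = np.concatenate([series, post.sigma[:, :, None]], axis=2)
        names = names + ["sigma"]
    means = series.mean(axis=1)                        # (C, P)
    W = series.var(axis=1, ddof=1).mean(axis=0)        # (P,)
    B_over_M = means.var(axis=0, ddof=1)               # B / M
    with np.errstate(divide="ignore", invalid="ignore"):
        vhat = (M - 1) / M * W + B_over_M
        rhat = np.sqrt(vhat / W)
    rhat = np.where(W == 0, 1.0, rhat)
    return pd.Series(rhat, index=names, name="rhat")


def unconverged(rhat: pd.Series, threshold: float = 1.1) -> pd.Series:
    return rhat[rhat > threshold]


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float
    p_d_var: float
    per_individual: np.ndarray  # per-record conditional DIC contributions
    deviances: np.ndarray       # deviance per draw


def _align_records(post: Posterior, records: Sequence[UseRecord]) -> list[UseRecord]:
    by_key = {(r.site, r.animal_id): r for r in records}
    if set(by_key) != set(post.animals) or len(records) != len(post.animals):
        raise ValueError("records do not match the individuals the posterior was fitted to")
    return [by_key[k] for k in post.animals]


def dic(post: Posterior, records: Sequence[UseRecord]) -> DicResult:
    """Conditional DIC: DIC = Dbar + pD with pD = Dbar - D(theta_bar).

    The deviance is evaluated given the sampled residuals; the plug-in
    point theta_bar uses posterior means of the coefficients and
    residuals on the sampled scale.  ``p_d_var`` = var(D)/2 is reported
    as the variance-based alternative.
    """
    if post.n_total < 100:
        raise ValueError("too few draws for a stable DIC (need >= 100)")
    recs = _align_records(post, records)
    _, S, K, X, n, site_idx, _ = _prepare(recs, post.form)
    logc = (gammaln(n.sum(axis=1) + 1) - gammaln(n + 1).sum(axis=1))
    ll = batched_loglik(post.flat_a(), post.flat_eps(), X, n, site_idx) + logc
    dev_k = -2.0 * ll                                  # (R, K)
    dbar_k = dev_k.mean(axis=0)
    a_bar = post.flat_a().mean(axis=0, keepdims=True)
    eps_bar = post.flat_eps().mean(axis=0, keepdims=True)
    dhat_k = -2.0 * (batched_loglik(a_bar, eps_bar, X, n, site_idx)[0] + logc)
    per_individual = 2.0 * dbar_k - dhat_k
    deviances = dev_k.sum(axis=1)
    dbar = float(dbar_k.sum())
    dhat = float(dhat_k.sum())
    return DicResult(
        dic=2 * dbar - dhat,
        p_d=dbar - dhat,
        mean_deviance=dbar,
        p_d_var=float(deviances.var(ddof=1) / 2.0),
        per_individual=per_individual,
        deviances=deviances,
    )


@dataclass(frozen=True)
class DicComparison:
    delta_dic: float   # DIC(f1) - DIC(f2); positive favors f2
    se: float
    dic_f1: DicResult
    dic_f2: DicResult


def compare_dic(
    post_f1: Posterior,
    post_f2: Posterior,
    records: Sequence[UseRecord],
    n_boot: int = 1000,
    seed: int = 0,
) -> DicComparison:
    """DIC difference between the pooled and site-specific fits.

    The SE is a nonparametric bootstrap over individuals (the independent
    units of the model) of the summed per-individual DIC contributions.
    """
    key = _data_key(records)
    if set(post_f1.animals) != set(post_f2.animals):
        raise ValueError("posteriors were fitted to different individuals")
    if post_f1.data_key and post_f2.data_key and set(post_f1.data_key) != set(post_f2.data_key):
        raise ValueError("posteriors were fitted to different datasets")
    if set(k[:2] for k in key) != set(post_f1.animals):
        raise ValueError("records do not match the fitted datasets")
    d1 = dic(post_f1, records)
    d2 = dic(post_f2, records)
    order = {k: i for i, k in enumerate(post_f1.animals)}
    reorder = np.array([order[k] for k in post_f2.animals])
    c1 = d1.per_individual
    c2 = np.empty_like(d2.per_individual)
    c2[reorder] = d2.per_individual  # align f2 contributions to f1's animal order
    contrib = c1 - c2
    K = len(contrib)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, K, size=(n_boot, K))
    sums = contrib[idx].sum(axis=1)
    se = float(sums.std(ddof=1))
    return DicComparison(
        delta_dic=float(d1.dic - d2.dic), se=se, dic_f1=d1, dic_f2=d2
    )


# ---------------------------------------------------------------------------
# Posterior export
# ---------------------------------------------------------------------------

def posterior_to_frame(post: Posterior) -> pd.DataFrame:
    """Tidy draw table: chain, iteration, parameter, value."""
    names = post.coefficient_labels() + ["sigma"]
    C, M = post.n_chains, post.n_draws
    series = np.concatenate(
        [post.a.reshape(C, M, -1), post.sigma[:, :, None]], axis=2
    )
    chain = np.repeat(np.arange(C), M * len(names))
    iteration = np.tile(np.repeat(np.arange(M), len(names)), C)
    parameter = np.tile(names, C * M)
    return pd.DataFrame(
        dict(chain=chain, iteration=iteration, parameter=parameter,
             value=series.reshape(-1))
    )


def write_posterior(post: Posterior, path) -> None:
    posterior_to_frame(post).to_csv(path, index=False)
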