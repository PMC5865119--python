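"""Posterior-predictive goodness-of-fit checks and residual summaries.

For each parameter vector sampled by MCMC, a hypothetical replicate of
the dataset is simulated from the fitted multinomial model (using that
draw's own residuals).  The observed count for every animal x habitat
cell is then compared with the equal-tailed credible interval of its
simulated distribution; well-fitting models leave (at least) the nominal
fraction of observed counts inside.  Interval endpoints are empirical
order statistics, so with discrete counts and closed-interval membership
the realized coverage is conservative (above nominal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("triselect")

from .habitat_model import Posterior, UseRecord, _align_records, _prepare
from .simplex_core import HABITATS


def _use_probs(post: Posterior, records: list[UseRecord]) -> np.ndarray:
    """Per-draw use probabilities, shape (R, K, 3), using each draw's eps."""
    _, S, K, X, n, site_idx, _ = _prepare(records, post.form)
    A = post.flat_a()[:, site_idx]                     # (R, K, 2, 3)
    eta = np.einsum("rkhj,kj->rkh", A, X) + post.flat_eps()
    z = np.concatenate([eta, np.zeros_like(eta[..., :1])], axis=-1)
    z -= z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def posterior_predictive(
    post: Posterior,
    records: list[UseRecord],
    n_rep: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Simulate replicate count datasets from the fitted model.

    Returns an integer array of shape (n_rep, K, 3).  Posterior draws are
    cycled (or subsampled) to supply one parameter vector per replicate;
    counts are Multinomial(N_k, p_k(theta^r)) per animal.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    recs = _align_records(post, records)
    P = _use_probs(post, recs)                          # (R, K, 3)
    R = P.shape[0]
    idx = np.arange(n_rep) % R
    N = np.array([r.N for r in recs])
    rng = np.random.default_rng(seed)
    pvals = P[idx]                                      # (n_rep, K, 3)
    return rng.multinomial(np.broadcast_to(N, (n_rep, len(recs))), pvals)


@dataclass(frozen=True)
class PpcResult:
    """Per-cell credible intervals of simulated counts and their coverage."""

    table: pd.DataFrame  # site, animal_id, habitat, observed, lo, hi, inside
    coverage: float
    level: float
    n_rep: int


def ppc_coverage(
    sim: np.ndarray,
    post: Posterior,
    records: list[UseRecord],
    level: float = 0.95,
) -> PpcResult:
    """Coverage of equal-tailed credible intervals over animal x habitat cells.

    Endpoints are order statistics of the simulated counts (lower endpoint
    at the alpha/2 empirical quantile rounded down, upper rounded up), and
    membership is closed, so every bound is an achievable integer count.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    recs = _align_records(post, records)
    n_rep, K, H = sim.shape
    if n_rep < 1000:
        logger.warning(
            "ppc_coverage on %d replicates; interval endpoints are noisy below 1,000",
            n_rep,
        )
    assert K == len(recs) and H == 3
    alpha = 1.0 - level
    lo = np.quantile(sim, alpha / 2, axis=0, method="inverted_cdf")
    hi = np.quantile(sim, 1 - alpha / 2, axis=0, method="higher")
    obs = np.array([r.n for r in recs])
    inside = (obs >= lo) & (obs <= hi)
    rows = []
    for k, r in enumerate(recs):
        for h, hab in enumerate(HABITATS):
            rows.append(
                dict(site=r.site, animal_id=r.animal_id, habitat=hab,
                     observed=int(obs[k, h]), lo=int(lo[k, h]), hi=int(hi[k, h]),
                     inside=bool(inside[k, h]))
            )
    table = pd.DataFrame(rows)
    return PpcResult(
        table=table, coverage=float(inside.mean()), level=level, n_rep=n_rep
    )


def pearson_residuals(post: Posterior, records: list[UseRecord]) -> pd.DataFrame:
    """Standardized residuals (observed - expected) / sqrt(N p (1 - p))
    under the plug-in multinomial at the posterior mean use probabilities."""
    recs = _align_records(post, records)
    P = _use_probs(post, recs).mean(axis=0)             # (K, 3)
    obs = np.array([r.n for r in recs], dtype=float)
    N = obs.sum(axis=1, keepdims=True)
    expected = N * P
    var = N * P * (1 - P)
    resid = np.where(var > 0, (obs - expected) / np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
    rows = []
    for k, r in enumerate(recs):
        for h, hab in enumerate(HABITATS):
            rows.append(
                dict(site=r.site, animal_id=r.animal_id, habitat=hab,
                     observed=obs[k, h], expected=expected[k, h],
                     residual=resid[k, h])
            )
    return pd.DataFrame(rows)


def write_ppc_report(result: PpcResult, csv_path, json_path=None) -> None:
    result.table.to_csv(csv_path, index=False)
    if json_path is not None:
        import json

        with open(json_path, "w") as fh:
            json.dump(
                dict(coverage=result.coverage, level=result.level, n_rep=result.n_rep),
                fh, indent=2,
            )
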