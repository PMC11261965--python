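"""Variational posterior over model parameters and the sequential SBI loop.

The posterior family is a logit-normal on the prior box: a full-covariance
Gaussian over latent ``z`` (Cholesky-parametrized) pushed through a
coordinate-wise sigmoid onto the log10-parameter box
``[log10(low), log10(high)]^d``.  Every sample therefore lies strictly
inside the prior support by construction, and the full covariance lets the
family align with the ridges that equilibrium models typically leave
between an equilibrium constant and its efficiency (a mean-field family
collapses such ridges and becomes overconfident in every marginal).  The
family is fitted by maximizing a Monte-Carlo evidence lower bound (ELBO)

    ELBO(mu, L) = E_q[ log p(x | theta) ] - KL( q || prior ),

with a fixed set of base normal draws (common random numbers), which makes
the objective deterministic in the variational parameters and lets a
quasi-Newton optimizer handle it; the entropy and prior terms are analytic.

Sequential rounds follow the usual surrogate-likelihood recipe: round 1
trains the surrogate on prior draws, later rounds draw fresh parameters
from the current posterior, simulate, retrain on the aggregated pair set,
and refit the posterior.  Median distance and posterior-predictive coverage
are recorded per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .exceptions import TrainingError, ValidationError
from .surrogate import SurrogateLikelihood, train_surrogate, _context_features
from .synthetic import Dataset, PriorSpec, sample_prior

__all__ = ["VariationalPosterior", "RoundHistory", "fit_posterior", "run_rounds"]

_LOG2PI = float(np.log(2.0 * np.pi))


def _softplus(z):
    return np.logaddexp(0.0, z)


@dataclass
class VariationalPosterior:
    """Sigmoid-transformed full-covariance Gaussian over the log-uniform prior box.

    ``chol`` is the lower-triangular Cholesky factor of the latent
    covariance; a diagonal ``chol`` recovers the mean-field family.
    """

    mu: np.ndarray
    chol: np.ndarray
    low_log10: float
    high_log10: float
    elbo_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.chol = np.atleast_2d(np.asarray(self.chol, dtype=float))
        d = self.mu.size
        if self.chol.shape == (d,) or (self.chol.shape == (1, d) and d > 1):
            self.chol = np.diag(np.ravel(self.chol))
        if self.chol.shape != (d, d):
            raise ValidationError(
                f"chol must be ({d}, {d}) or a length-{d} diagonal, got {self.chol.shape}"
            )
        if np.any(np.diag(self.chol) <= 0):
            raise ValidationError("chol must have positive diagonal")
        self.chol = np.tril(self.chol)

    @property
    def dimension(self) -> int:
        return self.mu.size

    @property
    def _width(self) -> float:
        return self.high_log10 - self.low_log10

    def _to_log10(self, z: np.ndarray) -> np.ndarray:
        return self.low_log10 + self._width * special.expit(z)

    def _from_log10(self, t: np.ndarray) -> np.ndarray:
        u = (t - self.low_log10) / self._width
        u = np.clip(u, 1e-15, 1 - 1e-15)
        return special.logit(u)

    def sample_log10(self, n: int, seed=0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        z = self.mu + rng.standard_normal((n, self.dimension)) @ self.chol.T
        return self._to_log10(z)

    def sample(self, n: int, seed=0) -> np.ndarray:
        """Draw ``n`` parameter vectors on the linear scale (always in support)."""
        return 10.0 ** self.sample_log10(n, seed)

    def log_density_log10(self, theta_log10: np.ndarray) -> np.ndarray:
        """Log-density of log10(theta) under the transformed family."""
        from scipy.linalg import solve_triangular

        t = np.atleast_2d(np.asarray(theta_log10, dtype=float))
        z = self._from_log10(t)
        w = solve_triangular(self.chol, (z - self.mu).T, lower=True).T
        log_det = float(np.sum(np.log(np.diag(self.chol))))
        log_norm = -0.5 * (np.sum(w**2, axis=1) + self.dimension * _LOG2PI) - log_det
        log_jac = np.log(self._width) - _softplus(-z) - _softplus(z)
        return log_norm - log_jac.sum(axis=1)

    def marginal_log_density_log10(self, index: int, t) -> np.ndarray:
        """Marginal log-density of one log10-coordinate.

        The latent marginal of coordinate ``index`` is Normal with variance
        given by the corresponding row of the Cholesky factor.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        z = self._from_log10(t)
        sig = float(np.sqrt(np.sum(self.chol[index] ** 2)))
        log_norm = -0.5 * (((z - self.mu[index]) / sig) ** 2 + _LOG2PI) - np.log(sig)
        log_jac = np.log(self._width) - _softplus(-z) - _softplus(z)
        return log_norm - log_jac

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        """Log-density of theta on the linear scale (includes the 10^t Jacobian)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if np.any(theta <= 0):
            raise ValidationError("theta must be positive")
        t = np.log10(theta)
        return self.log_density_log10(t) - (np.log(theta) + np.log(np.log(10.0))).sum(axis=1)

    def mean_log10(self, n: int = 4096, seed: int = 0) -> np.ndarray:
        return self.sample_log10(n, seed).mean(axis=0)

    def sd_log10(self, n: int = 4096, seed: int = 0) -> np.ndarray:
        return self.sample_log10(n, seed).std(axis=0)


@dataclass
class RoundHistory:
    """Per-round diagnostics of the sequential loop."""

    records: list = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(dict(kwargs))

    def __len__(self):
        return len(self.records)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


DEFAULT_VI_CONFIG = {
    "n_elbo_draws": 192,
    "n_init_candidates": 512,
    "maxiter": 300,
    "seed": 0,
    "log_sigma_bounds": (-5.0, 2.5),
    # full covariance for small parameter vectors; the mean-field fallback
    # kicks in when the Cholesky parameter count would dominate the run
    "full_rank": None,
    "full_rank_max_dim": 12,
}


def _as_loglik_fn(surrogate, data):
    """Normalize the likelihood argument to a batched callable over linear theta."""
    if callable(surrogate) and not isinstance(surrogate, SurrogateLikelihood):
        return surrogate
    if data is None:
        raise ValidationError("a Dataset is required when passing a surrogate")

    def fn(thetas):
        return surrogate.dataset_loglik(thetas, data)

    return fn


def fit_posterior(
    surrogate,
    prior: PriorSpec,
    data: Dataset | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> VariationalPosterior:
    """Fit the variational posterior by deterministic ELBO maximization.

    ``surrogate`` is either a trained :class:`SurrogateLikelihood` (with
    ``data``) or any callable mapping an (S, d) array of linear-scale
    parameter vectors to S joint log-likelihood values — e.g. an exact
    likelihood on a toy problem.
    """
    cfg = dict(DEFAULT_VI_CONFIG)
    cfg.update(config or {})
    if seed is not None:
        cfg["seed"] = seed
    rng = np.random.default_rng(cfg["seed"])
    loglik = _as_loglik_fn(surrogate, data)

    d = prior.dimension
    lo, hi = prior.log10_bounds
    width = hi - lo
    z0 = rng.standard_normal((int(cfg["n_elbo_draws"]), d))
    log_prior_const = prior.log_density_log10()

    full_rank = cfg["full_rank"]
    if full_rank is None:
        full_rank = d <= int(cfg["full_rank_max_dim"])
    tril = np.tril_indices(d, -1)
    n_off = tril[0].size if full_rank else 0

    def build_chol(log_diag, off):
        L = np.zeros((d, d))
        L[np.diag_indices(d)] = np.exp(log_diag)
        if n_off:
            L[tril] = off
        return L

    def unpack(x):
        return x[:d], x[d:2 * d], x[2 * d:]

    def neg_elbo(x):
        mu, log_diag, off = unpack(x)
        z = mu + z0 @ build_chol(log_diag, off).T
        s = special.expit(z)
        theta = 10.0 ** (lo + width * s)
        ll = np.nan_to_num(loglik(theta), nan=-1e8, neginf=-1e8, posinf=-1e8)
        # entropy of q in log10-theta space: H[N(mu, LL^T)] + E log|jacobian|;
        # log s = -softplus(-z), log(1-s) = -softplus(z) avoid saturation
        log_jac = np.log(width) - _softplus(-z) - _softplus(z)
        entropy = np.sum(log_diag) + 0.5 * d * (1.0 + _LOG2PI) + np.mean(log_jac.sum(axis=1))
        return -(float(np.mean(ll)) + log_prior_const + entropy)

    # moment-matched initialization from the best prior-draw candidates
    cand = sample_prior(prior, int(cfg["n_init_candidates"]), rng)
    cand_ll = loglik(cand)
    top = np.argsort(cand_ll)[-max(8, len(cand_ll) // 16):]
    u = (np.log10(cand[top]) - lo) / width
    z_top = special.logit(np.clip(u, 1e-9, 1 - 1e-9))
    mu0 = z_top.mean(axis=0)
    sig0 = np.clip(z_top.std(axis=0), 0.2, 2.0)
    x0 = np.concatenate([mu0, np.log(sig0), np.zeros(n_off)])

    lb, ub = cfg["log_sigma_bounds"]
    bounds = ([(None, None)] * d + [(lb, ub)] * d
              + [(-np.exp(ub), np.exp(ub))] * n_off)
    trace = []

    def cb(xk):
        trace.append(-neg_elbo(xk))

    res = optimize.minimize(
        neg_elbo, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": int(cfg["maxiter"])}, callback=cb,
    )
    if not np.isfinite(res.fun):
        raise TrainingError("variational objective diverged", trace=trace)
    mu, log_diag, off = unpack(res.x)
    return VariationalPosterior(
        mu=mu, chol=build_chol(log_diag, off),
        low_log10=lo, high_log10=hi, elbo_trace=trace,
    )


DEFAULT_ROUND_CONFIG = {
    "sims_per_round": 512,
    "n_predictive": 200,
    "ppc_level": 0.95,
    "aggregate_pairs": True,
    "surrogate": {},
    "vi": {},
}


def run_rounds(
    simulator,
    prior: PriorSpec,
    data: Dataset,
    n_rounds: int,
    config: dict | None = None,
    seed: int = 0,
):
    """Sequential surrogate-likelihood inference.

    ``simulator(theta, contexts, rng)`` must return one noisy observation
    vector over ``contexts`` for a linear-scale parameter vector ``theta``.
    Each round spends ``sims_per_round`` simulator calls: parameter draws
    (from the prior in round 1, from the current posterior afterwards) are
    paired with one experimental context each, cycling through the panel.
    Returns ``(posterior, history)``; the history has one record per round
    with the round's median distance and posterior-predictive coverage on
    the observed data.
    """
    from .metrics import median_distance, posterior_predictive_sims, ppc_coverage

    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    cfg = dict(DEFAULT_ROUND_CONFIG)
    cfg.update(config or {})
    rng = np.random.default_rng(seed)

    feats = np.stack([_context_features(c) for c in data.contexts])
    n_ctx = feats.shape[0]
    all_thetas, all_feats, all_xs = [], [], []
    posterior = None
    history = RoundHistory()

    for r in range(1, n_rounds + 1):
        try:
            S = int(cfg["sims_per_round"])
            thetas = (
                sample_prior(prior, S, rng)
                if posterior is None
                else posterior.sample(S, rng.integers(2**31))
            )
            ctx_idx = np.arange(S) % n_ctx
            xs = np.empty(S)
            for s_i in range(S):
                ci = int(ctx_idx[s_i])
                xs[s_i] = simulator(thetas[s_i], [data.contexts[ci]], rng)[0]
            all_thetas.append(np.log10(thetas))
            all_feats.append(feats[ctx_idx])
            all_xs.append(xs)
            if not cfg["aggregate_pairs"]:
                all_thetas, all_feats, all_xs = all_thetas[-1:], all_feats[-1:], all_xs[-1:]

            sur_cfg = dict(cfg["surrogate"])
            sur_cfg.setdefault("seed", int(rng.integers(2**31)))
            surrogate = train_surrogate(
                (10.0 ** np.vstack(all_thetas), np.vstack(all_feats), np.concatenate(all_xs)),
                sur_cfg,
            )
            vi_cfg = dict(cfg["vi"])
            vi_cfg.setdefault("seed", int(rng.integers(2**31)))
            posterior = fit_posterior(surrogate, prior, data, vi_cfg)

            sims = posterior_predictive_sims(
                posterior, simulator, data.contexts,
                n_draws=int(cfg["n_predictive"]), seed=int(rng.integers(2**31)),
            )
            md = median_distance(data.observations, sims)
            ppc = ppc_coverage(data.observations, sims, level=float(cfg["ppc_level"]))
            history.append(
                round=r, median_distance=md, ppc=ppc,
                heldout_loglik=surrogate.heldout_loglik,
                null_loglik=surrogate.null_loglik,
                elbo=posterior.elbo_trace[-1] if posterior.elbo_trace else np.nan,
                seed=int(seed),
            )
        except (TrainingError, ValidationError) as err:
            raise TrainingError(f"round {r} failed: {err}") from err
    return posterior, history
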