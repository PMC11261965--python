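"""Factorized conditional surrogate of the likelihood.

The joint likelihood of a panel of independent experiments factorizes as
``p(x | theta) = prod_n p(x_n | theta, c_n)`` where ``c_n`` are the
conditioning variables (receptor totals, ligand dose) of experiment ``n``.

The per-experiment conditional density is a Gaussian on an asinh-transformed
response scale: ``asinh(x) | theta, c ~ Normal(m(theta, c), s(theta, c)^2)``
with a multilayer-perceptron mean ``m`` and (optionally heteroscedastic)
log-sd ``s``, both regressions on ``(log10 theta, c)``.  The asinh transform
is linear near zero and logarithmic for large responses, so one network can
cover readouts spanning several decades; densities reported in the original
response space include the change-of-variables Jacobian and therefore
integrate to one.

Parameters are conditioned in log10 space: the log-uniform prior spans six
decades and the equilibrium response is far closer to linear in log K than
in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import TrainingError, ValidationError
from .onestep import CellContext
from .synthetic import Dataset

__all__ = ["SurrogateLikelihood", "train_surrogate", "joint_loglik"]

_LOG2PI = float(np.log(2.0 * np.pi))
_CTX_EPS = 1e-6  # floor before log-transforming context totals
# E[log |N(0,1)|]; converts a regression on log|residual| into a log-sd estimate
_HALF_NORMAL_LOG_MEAN = -0.6351814227307392


def _context_features(context) -> np.ndarray:
    if isinstance(context, CellContext):
        context = context.features()
    return np.log10(np.asarray(context, dtype=float) + _CTX_EPS)


def _design(theta_log10: np.ndarray, ctx_feats: np.ndarray) -> np.ndarray:
    return np.hstack([np.atleast_2d(theta_log10), np.atleast_2d(ctx_feats)])


class _RescaledPipeline:
    """Wraps a fitted pipeline to predict on the original (standardized-off) scale."""

    def __init__(self, pipeline, offset, scale):
        self._pipeline = pipeline
        self._offset = offset
        self._scale = scale

    def predict(self, X):
        return self._pipeline.predict(X) * self._scale + self._offset


@dataclass
class SurrogateLikelihood:
    """Trained conditional Gaussian surrogate of ``p(x | theta, context)``.

    Evaluation contract: :meth:`logpdf` returns the conditional log-density
    of a scalar observation (in the original response space, Jacobian
    included); sampling contract: :meth:`sample` draws an observation given
    ``(theta, context)``.  ``theta`` is always on the linear (concentration)
    scale at the interface and transformed to log10 internally; contexts may
    be :class:`CellContext` objects or pre-built feature rows.
    """

    mean_model: _RescaledPipeline
    sd_model: object  # _RescaledPipeline predicting log sd, or None
    sigma: float  # homoscedastic fallback / floor (asinh scale)
    theta_dim: int
    context_dim: int
    sd_cap: float = np.inf  # largest residual sd seen in training (extrapolation guard)
    transform: str = "asinh"
    heldout_loglik: float = np.nan
    null_loglik: float = np.nan
    training_meta: dict = field(default_factory=dict)

    # -- response transform ------------------------------------------------
    def _fwd(self, x):
        return np.arcsinh(x) if self.transform == "asinh" else np.asarray(x, float)

    def _inv(self, u):
        return np.sinh(u) if self.transform == "asinh" else np.asarray(u, float)

    def _log_jac(self, x):
        # d asinh(x) / dx = 1 / sqrt(1 + x^2)
        if self.transform == "asinh":
            return -0.5 * np.log1p(np.asarray(x, float) ** 2)
        return np.zeros_like(np.asarray(x, float))

    # -- internals ---------------------------------------------------------
    def _features(self, theta: np.ndarray, contexts) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if theta.shape[1] != self.theta_dim:
            raise ValidationError(
                f"theta has {theta.shape[1]} coordinates, surrogate expects {self.theta_dim}"
            )
        if np.any(theta <= 0):
            raise ValidationError("theta must be positive (log10 conditioning)")
        if isinstance(contexts, CellContext):
            feats = _context_features(contexts)
        elif isinstance(contexts, (list, tuple)) and contexts and isinstance(contexts[0], CellContext):
            feats = np.stack([_context_features(c) for c in contexts])
        else:
            feats = np.asarray(contexts, dtype=float)
        feats = np.atleast_2d(feats)
        if feats.shape[1] != self.context_dim:
            raise ValidationError(
                f"context has {feats.shape[1]} features, surrogate expects {self.context_dim}"
            )
        if theta.shape[0] == 1 and feats.shape[0] > 1:
            theta = np.repeat(theta, feats.shape[0], axis=0)
        if feats.shape[0] == 1 and theta.shape[0] > 1:
            feats = np.repeat(feats, theta.shape[0], axis=0)
        return _design(np.log10(theta), feats)

    def _moments(self, X) -> tuple[np.ndarray, np.ndarray]:
        mean = np.asarray(self.mean_model.predict(X), dtype=float)
        if self.sd_model is not None:
            sd = np.exp(np.asarray(self.sd_model.predict(X), dtype=float))
            sd = np.clip(sd, self.sigma, self.sd_cap)
        else:
            sd = np.full_like(mean, self.sigma)
        return mean, sd

    def conditional_mean(self, theta, contexts) -> np.ndarray:
        """Predicted mean response (original scale) for each (theta, context) row.

        For the asinh transform the back-transformed mean is exact:
        ``E[sinh(U)] = sinh(m) exp(s^2/2)`` for ``U ~ Normal(m, s^2)``.
        """
        mean, sd = self._moments(self._features(theta, contexts))
        if self.transform == "asinh":
            return np.sinh(mean) * np.exp(0.5 * sd**2)
        return mean

    def logpdf(self, x, theta, contexts) -> np.ndarray:
        """Conditional log-density in the original response space."""
        mean, sd = self._moments(self._features(theta, contexts))
        x = np.asarray(x, dtype=float)
        u = self._fwd(x)
        return (
            -0.5 * (_LOG2PI + ((u - mean) / sd) ** 2)
            - np.log(sd)
            + self._log_jac(x)
        )

    def sample(self, theta, contexts, seed=0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        mean, sd = self._moments(self._features(theta, contexts))
        return self._inv(mean + rng.normal(0.0, 1.0, size=mean.shape) * sd)

    def dataset_loglik(self, thetas: np.ndarray, data: Dataset) -> np.ndarray:
        """Joint log-likelihood of ``data`` for a batch of parameter vectors.

        Vectorized hot path for variational fitting: one prediction call over
        the (n_theta * n_experiment) design matrix.  The data-dependent
        Jacobian term is constant in theta and included, so values match
        summed :meth:`logpdf` calls exactly.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        S = thetas.shape[0]
        feats = np.stack([_context_features(c) for c in data.contexts])
        n = feats.shape[0]
        X = _design(
            np.repeat(np.log10(thetas), n, axis=0),
            np.tile(feats, (S, 1)),
        )
        mean, sd = self._moments(X)
        mean = mean.reshape(S, n)
        sd = sd.reshape(S, n)
        u = self._fwd(data.observations)[None, :]
        ll = -0.5 * (_LOG2PI + ((u - mean) / sd) ** 2) - np.log(sd)
        return ll.sum(axis=1) + float(np.sum(self._log_jac(data.observations)))


def _normalize_pairs(pairs):
    """Accept a list of (theta, context, x) triples or a (thetas, feats, xs) tuple."""
    if isinstance(pairs, tuple) and len(pairs) == 3 and not isinstance(pairs[0], (int, float)):
        thetas, feats, xs = pairs
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        feats = np.atleast_2d(np.asarray(feats, dtype=float))
        xs = np.asarray(xs, dtype=float).ravel()
    else:
        thetas, feats, xs = [], [], []
        for theta, ctx, x in pairs:
            thetas.append(np.ravel(np.asarray(theta, dtype=float)))
            feats.append(_context_features(ctx) if isinstance(ctx, CellContext)
                         else np.ravel(np.asarray(ctx, dtype=float)))
            xs.append(float(x))
        thetas, feats, xs = np.stack(thetas), np.stack(feats), np.asarray(xs)
    if not (np.all(np.isfinite(thetas)) and np.all(np.isfinite(feats)) and np.all(np.isfinite(xs))):
        raise ValidationError("training pairs must be finite")
    return thetas, feats, xs


DEFAULT_TRAIN_CONFIG = {
    "hidden_layer_sizes": (48, 48),
    "max_iter": 300,
    "val_fraction": 0.15,
    "sd_floor": 1e-3,
    "seed": 0,
    "tol": 1e-5,
    "solver": "adam",
    "heteroscedastic": True,
    "transform": "asinh",
}


def _fit_mlp(X, y, cfg, seed_shift=0):
    pipeline = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPRegressor(
            hidden_layer_sizes=tuple(cfg["hidden_layer_sizes"]),
            activation="tanh",
            solver=str(cfg["solver"]),
            max_iter=int(cfg["max_iter"]),
            tol=float(cfg["tol"]),
            random_state=(int(cfg["seed"]) + seed_shift) % (2**32),
            early_stopping=False,
        )),
    ])
    offset, scale = float(np.mean(y)), float(np.std(y) + 1e-12)
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipeline.fit(X, (y - offset) / scale)
    loss = pipeline.named_steps["mlp"].loss_
    if not np.isfinite(loss):
        raise TrainingError("non-finite training loss",
                            epoch=pipeline.named_steps["mlp"].n_iter_)
    return _RescaledPipeline(pipeline, offset, scale)


def train_surrogate(pairs, config: dict | None = None) -> SurrogateLikelihood:
    """Fit the conditional Gaussian surrogate on (theta, context, x) pairs.

    The mean network is trained by least squares on the transformed response
    (the Gaussian maximum-likelihood objective); the heteroscedastic log-sd
    network is a regression on log absolute residuals, bias-corrected by the
    half-normal log-mean.  The returned surrogate records its held-out mean
    log-density alongside that of an untrained marginal-Gaussian
    initialization for the same pairs.
    """
    cfg = dict(DEFAULT_TRAIN_CONFIG)
    cfg.update(config or {})
    thetas, feats, xs = _normalize_pairs(pairs)
    if xs.size < 1:
        raise ValidationError("need at least one training pair")
    theta_log10 = np.log10(thetas)
    if not np.all(np.isfinite(theta_log10)):
        raise ValidationError("theta must be positive for log10 conditioning")
    X = _design(theta_log10, feats)
    fwd = np.arcsinh if cfg["transform"] == "asinh" else np.asarray
    u = fwd(xs)

    rng = np.random.default_rng(cfg["seed"])
    n = xs.size
    n_val = max(1, int(round(cfg["val_fraction"] * n))) if n >= 5 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = perm

    mean_model = _fit_mlp(X[tr_idx], u[tr_idx], cfg)
    resid_tr = u[tr_idx] - mean_model.predict(X[tr_idx])
    sigma = max(float(np.std(resid_tr)), float(cfg["sd_floor"]))

    sd_model = None
    sd_cap = np.inf
    if cfg["heteroscedastic"] and tr_idx.size >= 50:
        log_abs = np.log(np.abs(resid_tr) + 1e-12) - _HALF_NORMAL_LOG_MEAN
        sd_model = _fit_mlp(X[tr_idx], log_abs, cfg, seed_shift=1)
        # never predict a dispersion larger than the worst training residual:
        # unbounded extrapolation of the sd net flattens the likelihood
        sd_cap = float(np.max(np.abs(resid_tr))) + 1e-12
        sigma = float(cfg["sd_floor"])

    surrogate = SurrogateLikelihood(
        mean_model=mean_model,
        sd_model=sd_model,
        sigma=sigma,
        sd_cap=sd_cap,
        theta_dim=thetas.shape[1],
        context_dim=feats.shape[1],
        transform=cfg["transform"],
        training_meta={"n_pairs": int(n), "config": cfg},
    )

    # held-out diagnostics: trained surrogate vs. marginal-Gaussian null
    resid_idx = val_idx if val_idx.size else tr_idx
    ll = surrogate.logpdf(xs[resid_idx], thetas[resid_idx], feats[resid_idx])
    surrogate.heldout_loglik = float(np.mean(ll))
    null_mean, null_sd = float(np.mean(u)), max(float(np.std(u)), cfg["sd_floor"])
    null_ll = (
        -0.5 * (_LOG2PI + ((u[resid_idx] - null_mean) / null_sd) ** 2)
        - np.log(null_sd)
        + surrogate._log_jac(xs[resid_idx])
    )
    surrogate.null_loglik = float(np.mean(null_ll))
    return surrogate


def joint_loglik(surrogate: SurrogateLikelihood, data: Dataset, theta) -> float:
    """Sum of per-experiment conditional log-densities at one theta.

    Exactly additive over experiments — the factorized-likelihood identity.
    """
    if len(data) < 1:
        raise ValidationError("dataset is empty")
    theta = np.ravel(np.asarray(theta, dtype=float))
    return float(surrogate.dataset_loglik(theta[None, :], data)[0])
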