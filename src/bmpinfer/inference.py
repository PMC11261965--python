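"""Model / Results surface tying the pipeline together.

:class:`BmpOnestepSBI` is built from an observed response panel (a
:class:`~bmpinfer.synthetic.Dataset`) plus the model shape and prior;
``fit()`` runs the sequential surrogate-likelihood loop and returns an
:class:`SBIResults` carrying the variational posterior, per-round
diagnostics, a ``summary()`` table, posterior-predictive simulation, and
spike-and-slab structural augmentation.

Example
-------
>>> from bmpinfer import BmpOnestepSBI, make_synthetic_study
>>> theta_star, data, prior = make_synthetic_study(seed=3)
>>> model = BmpOnestepSBI(data, noise_sd=0.05)
>>> res = model.fit(n_rounds=3, seed=3)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .metrics import (
    median_distance,
    posterior_predictive_sims,
    ppc_coverage,
    sweep_spike_slab,
)
from .onestep import ModelParameters, ModelShape, simulate_dataset
from .posterior import run_rounds
from .structural import AffinityRecord
from .synthetic import Dataset, PriorSpec

__all__ = ["BmpOnestepSBI", "SBIResults", "make_noisy_simulator"]


def make_noisy_simulator(shape: ModelShape, noise_sd: float, tol: float = 1e-10):
    """Observation-model simulator: onestep readouts plus Gaussian noise.

    Returns ``simulator(theta, contexts, rng) -> vector`` as expected by the
    sequential loop and the predictive metrics.
    """

    def simulator(theta, contexts, rng):
        params = ModelParameters.from_flat(theta, shape)
        signal = simulate_dataset(params, contexts, tol=tol)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        return signal

    return simulator


class BmpOnestepSBI:
    """Simulation-based inference model for the onestep mass-action pathway.

    Parameters
    ----------
    data : Dataset
        Observed scalar responses with their experimental contexts.
    shape : ModelShape, optional
        Receptor/ligand counts; inferred from the first context when omitted.
    prior : PriorSpec, optional
        Log-uniform prior over all 2 * nA * nL * nB parameters
        (default [1e-4, 1e2] per coordinate).
    noise_sd : float
        Observation-noise standard deviation assumed by the simulator used
        for surrogate training and predictive checks.
    """

    def __init__(self, data: Dataset, shape: ModelShape | None = None,
                 prior: PriorSpec | None = None, noise_sd: float = 0.05,
                 solver_tol: float = 1e-10):
        if len(data) < 1:
            raise ValidationError("dataset is empty")
        self.data = data
        self.shape = shape or data.contexts[0].shape
        self.prior = prior or PriorSpec(dimension=self.shape.n_parameters)
        if self.prior.dimension != self.shape.n_parameters:
            raise ValidationError(
                f"prior dimension {self.prior.dimension} != "
                f"{self.shape.n_parameters} model parameters"
            )
        self.noise_sd = float(noise_sd)
        self.simulator = make_noisy_simulator(self.shape, self.noise_sd, tol=solver_tol)

    @classmethod
    def from_tables(cls, contexts_path, observations_path, **kwargs):
        """Build from delimited context/observation tables."""
        from .io import read_contexts, read_observations

        contexts = read_contexts(contexts_path)
        obs = read_observations(observations_path)
        return cls(Dataset(contexts=contexts, observations=obs), **kwargs)

    def fit(self, n_rounds: int = 3, seed: int = 0, **config) -> "SBIResults":
        """Run sequential rounds of surrogate training + variational refit."""
        posterior, history = run_rounds(
            self.simulator, self.prior, self.data, n_rounds,
            config=config or None, seed=seed,
        )
        return SBIResults(self, posterior, history)


class SBIResults:
    """Fitted posterior with diagnostics and downstream analyses."""

    def __init__(self, model: BmpOnestepSBI, posterior, history):
        self.model = model
        self.posterior = posterior
        self.history = history

    # -- posterior access --------------------------------------------------
    def sample_posterior(self, n: int, seed=0) -> np.ndarray:
        """Linear-scale parameter draws, always inside the prior box."""
        return self.posterior.sample(n, seed)

    def posterior_predictive(self, n_draws: int = 500, seed=0) -> np.ndarray:
        return posterior_predictive_sims(
            self.posterior, self.model.simulator, self.model.data.contexts,
            n_draws=n_draws, seed=seed,
        )

    def median_distance(self, n_draws: int = 500, seed=0) -> float:
        sims = self.posterior_predictive(n_draws=n_draws, seed=seed)
        return median_distance(self.model.data.observations, sims)

    def ppc(self, level: float = 0.95, n_draws: int = 500, seed=0) -> float:
        sims = self.posterior_predictive(n_draws=n_draws, seed=seed)
        return ppc_coverage(self.model.data.observations, sims, level=level)

    # -- structural augmentation --------------------------------------------
    def augment_with_structure(
        self,
        affinity: AffinityRecord | float,
        slab_sds=(1.0, 5.0, 10.0, 15.0, 20.0),
        spike_locations=None,
        alpha: float = 0.1,
        n_draws: int = 500,
        seed=0,
        target_index: int = 0,
    ):
        """Spike-and-slab sweep of a structural affinity against the posterior.

        ``affinity`` may be an :class:`AffinityRecord` (its
        multiplicity-adjusted model-scale value becomes a sweep location) or
        a bare spike location.  When ``spike_locations`` is omitted, the grid
        spans 20..100 in steps of 10 — from moderate affinity to the upper
        edge of the prior box.
        """
        if spike_locations is None:
            spike_locations = np.arange(20.0, 101.0, 10.0)
        if isinstance(affinity, AffinityRecord):
            loc = affinity.model_scale_affinity
            spike_locations = np.unique(np.append(np.asarray(spike_locations, float), loc))
        return sweep_spike_slab(
            self.posterior, self.model.simulator, self.model.data.contexts,
            self.model.data.observations,
            spike_locations=spike_locations, slab_sds=slab_sds, alpha=alpha,
            n_draws=n_draws, seed=seed, target_index=target_index,
        )

    # -- reporting -----------------------------------------------------------
    def summary(self, n_samples: int = 4096, seed: int = 0) -> str:
        """Plain-text summary: round diagnostics and posterior marginals."""
        lines = []
        shape = self.model.shape
        lines.append("Onestep mass-action SBI results")
        lines.append("=" * 64)
        lines.append(
            f"shape: {shape.nA} type-A x {shape.nB} type-B x {shape.nL} ligands"
            f"  ({shape.n_parameters} parameters)"
        )
        lines.append(
            f"experiments: {len(self.model.data)}   "
            f"noise sd: {self.model.noise_sd:g}   rounds: {len(self.history)}"
        )
        lines.append("-" * 64)
        lines.append(f"{'round':>5} {'median distance':>16} {'PPC %':>8}")
        for rec in self.history.records:
            lines.append(
                f"{rec['round']:>5} {rec['median_distance']:>16.4f} {rec['ppc']:>8.1f}"
            )
        lines.append("-" * 64)
        lines.append("posterior marginals (log10 scale)")
        mean = self.posterior.mean_log10(n_samples, seed)
        sd = self.posterior.sd_log10(n_samples, seed)
        names = self._parameter_names()
        lines.append(f"{'parameter':>12} {'mean':>10} {'sd':>10}")
        for name, m, s in zip(names, mean, sd):
            lines.append(f"{name:>12} {m:>10.3f} {s:>10.3f}")
        return "\n".join(lines)

    def _parameter_names(self) -> list[str]:
        shape = self.model.shape
        names = []
        for prefix in ("K", "eps"):
            for i in range(shape.nA):
                for j in range(shape.nL):
                    for k in range(shape.nB):
                        names.append(f"{prefix}[{i},{j},{k}]")
        return names

    def save(self, path) -> None:
        from .io import save_posterior

        save_posterior(self.posterior, path)
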