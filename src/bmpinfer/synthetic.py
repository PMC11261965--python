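"""Synthetic ground truth, experimental contexts and noisy observations.

The real pathway dataset this pipeline targets (hundreds of titration
experiments, each conditioned on the receptor expression of the assayed cell
line) is not redistributable, so the generator emulates its statistical
structure: receptor totals drawn log-uniformly per simulated cell line
("conditioning variables", 3 type-A + 2 type-B = 5 at full scale),
single-ligand dose titrations over a dose grid, responses produced by the
onestep simulator under a ground-truth parameter vector plus additive
Gaussian observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .onestep import CellContext, ModelParameters, ModelShape, simulate_dataset

__all__ = [
    "PriorSpec",
    "Dataset",
    "sample_prior",
    "generate_contexts",
    "generate_observations",
    "make_synthetic_study",
]

#: Default single-ligand dose titration (common concentration unit).
DEFAULT_DOSE_GRID = (0.1, 1.0, 10.0)

#: Default log10 range for per-cell-line receptor totals.
RECEPTOR_RANGE_LOG10 = (-1.0, 1.0)


@dataclass(frozen=True)
class PriorSpec:
    """Log-uniform prior, per coordinate, on [low, high].

    ``low == high`` is accepted as a degenerate point prior: sampling then
    returns the constant, while density evaluation (which needs a proper
    box) raises.
    """

    low: float = 1e-4
    high: float = 1e2
    dimension: int = 2

    def __post_init__(self):
        if not (0 < self.low <= self.high):
            raise ValidationError(
                f"prior bounds must satisfy 0 < low <= high, got [{self.low}, {self.high}]"
            )
        if self.dimension < 1:
            raise ValidationError("prior dimension must be >= 1")

    @property
    def log10_bounds(self) -> tuple[float, float]:
        return (np.log10(self.low), np.log10(self.high))

    def log_density_log10(self) -> float:
        """Constant log-density of log10(theta) inside the box (uniform)."""
        lo, hi = self.log10_bounds
        if hi <= lo:
            raise ValidationError("degenerate prior has no density")
        return -self.dimension * np.log(hi - lo)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return np.all((theta >= self.low) & (theta <= self.high), axis=-1)


@dataclass
class Dataset:
    """Paired experimental contexts and scalar observations."""

    contexts: list[CellContext]
    observations: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.observations = np.asarray(self.observations, dtype=float)
        if len(self.contexts) != self.observations.size:
            raise ValidationError(
                f"{len(self.contexts)} contexts but {self.observations.size} observations"
            )
        if not np.all(np.isfinite(self.observations)):
            raise ValidationError("observations must be finite")

    def __len__(self) -> int:
        return len(self.contexts)

    def context_features(self) -> np.ndarray:
        """(n, nA+nB+nL) matrix of concatenated totals."""
        return np.stack([c.features() for c in self.contexts])


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` parameter vectors, each coordinate log-uniform on [low, high]."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spec.log10_bounds
    return 10.0 ** rng.uniform(lo, hi, size=(n, spec.dimension))


def generate_contexts(
    shape: ModelShape,
    n: int,
    dose_grid=DEFAULT_DOSE_GRID,
    seed: int | np.random.Generator = 0,
    receptor_range_log10=RECEPTOR_RANGE_LOG10,
) -> list[CellContext]:
    """Draw ``n`` experimental contexts.

    Each context is a simulated cell line (receptor totals log-uniform over
    ``receptor_range_log10`` decades) exposed to a single ligand at one dose
    from ``dose_grid``; ligand identity and dose cycle deterministically so
    every ligand is titrated.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    dose_grid = np.asarray(dose_grid, dtype=float)
    if dose_grid.size == 0:
        raise ValidationError("dose grid must be non-empty")
    if np.any(dose_grid <= 0):
        raise ValidationError("doses must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = receptor_range_log10
    contexts = []
    for m in range(n):
        A0 = 10.0 ** rng.uniform(lo, hi, size=shape.nA)
        B0 = 10.0 ** rng.uniform(lo, hi, size=shape.nB)
        L0 = np.zeros(shape.nL)
        L0[m % shape.nL] = dose_grid[(m // shape.nL) % dose_grid.size]
        contexts.append(CellContext(A0=A0, B0=B0, L0=L0))
    return contexts


def generate_observations(
    params: ModelParameters,
    contexts: list[CellContext],
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> Dataset:
    """Simulate readouts and add Gaussian observation noise of sd ``noise_sd``."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    signal = simulate_dataset(params, contexts)
    obs = signal + rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else signal
    return Dataset(
        contexts=contexts,
        observations=obs,
        meta={"noise_model": "gaussian", "noise_sd": float(noise_sd)},
    )


def make_synthetic_study(
    shape: ModelShape = ModelShape(1, 1, 1),
    n_experiments: int = 24,
    noise_sd: float = 0.05,
    dose_grid=DEFAULT_DOSE_GRID,
    seed: int = 0,
    prior: PriorSpec | None = None,
):
    """Ground-truth parameters, contexts and noisy observations in one call.

    Returns ``(theta_star, dataset, prior)`` where ``theta_star`` is drawn
    from the prior, so it always lies in the support every downstream stage
    assumes.  Desk-scale defaults (1x1x1 shape, 24 experiments) let the full
    pipeline run in minutes; the full pathway scale is available by passing
    ``shape=PAPER_SHAPE`` and ``n_experiments=940``.
    """
    prior = prior or PriorSpec(dimension=shape.n_parameters)
    if prior.dimension != shape.n_parameters:
        raise ValidationError(
            f"prior dimension {prior.dimension} != {shape.n_parameters} parameters"
        )
    rng = np.random.default_rng(seed)
    theta_star = sample_prior(prior, 1, rng)[0]
    params = ModelParameters.from_flat(theta_star, shape)
    contexts = generate_contexts(shape, n_experiments, dose_grid=dose_grid, seed=rng)
    dataset = generate_observations(params, contexts, noise_sd=noise_sd, seed=rng)
    dataset.meta.update({"seed": int(seed), "shape": (shape.nA, shape.nB, shape.nL)})
    return theta_star, dataset, prior
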