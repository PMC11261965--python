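"""Structure-derived affinities and spike-and-slab posterior augmentation.

A docking/affinity pipeline reduces a predicted complex to one scalar: the
dissociation constant Kd.  This module converts that scalar onto the
mass-action model's affinity scale (``Kstruct = -ln(Kd / reference)``, so
larger means tighter binding), relates it to the Gibbs free energy
(``dG = R T ln Kd``) and to the equilibrium constant through detailed
balance (``-ln K = N G`` with stoichiometry N), and injects it into
posterior samples of one equilibrium constant through importance resampling
against a spike-and-slab distribution

    K ~ (1 - alpha) * delta(K - Kstruct) + alpha * Normal(Kstruct, sigma^2).

A Dirac spike has no density at off-spike samples, so for weighting the
spike is approximated by a narrow Gaussian of width ``spike_width``
(default sigma/100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateWeightsError, ValidationError

__all__ = [
    "AffinityRecord",
    "SpikeSlab",
    "binding_multiplicity",
    "affinity_from_kd",
    "gibbs_from_kd",
    "keq_from_gibbs",
    "apply_multiplicity",
    "spike_slab_density",
    "spike_slab_sample",
    "reweight_posterior",
    "GAS_CONSTANT_KCAL",
]

#: kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987e-3


def binding_multiplicity(ligand_orientations: int = 2,
                         receptor_orientations: int = 2) -> int:
    """Count of symmetry-equivalent binding configurations.

    A homodimeric ligand with a two-fold symmetry axis can dock in two
    orientations, and a receptor complex whose chains mirror each other can
    be rotated into two equivalent poses; the configurations multiply
    (default 2 x 2 = 4).
    """
    if ligand_orientations < 1 or receptor_orientations < 1:
        raise ValidationError("orientation counts must be >= 1")
    return int(ligand_orientations) * int(receptor_orientations)


def affinity_from_kd(kd: float, reference: float = 1.0) -> float:
    """Binding affinity on the model scale: ``-ln(Kd / reference)``.

    Larger return value = stronger binding.  ``reference`` is the standard
    concentration making the ratio dimensionless (default 1 M, configurable).
    """
    if kd <= 0 or reference <= 0:
        raise ValidationError("Kd and reference must be positive")
    return float(-np.log(kd / reference))


def gibbs_from_kd(kd: float, temperature: float = 298.15,
                  gas_constant: float = GAS_CONSTANT_KCAL) -> float:
    """Gibbs free energy of binding, ``dG = R T ln Kd`` (negative for Kd < 1)."""
    if kd <= 0 or temperature <= 0 or gas_constant <= 0:
        raise ValidationError("Kd, temperature and R must be positive")
    return float(gas_constant * temperature * np.log(kd))


def keq_from_gibbs(deltaG_rt, stoich=1.0) -> float:
    """Equilibrium constant from detailed balance: ``ln K = -(stoich . G)``.

    ``deltaG_rt`` is the free energy in units of RT (scalar or vector);
    ``stoich`` the matching stoichiometric coefficient(s).  Returns K itself;
    take ``log`` for the affinity scale.
    """
    g = np.asarray(deltaG_rt, dtype=float)
    n = np.asarray(stoich, dtype=float)
    if g.shape != n.shape and not (g.ndim == 0 or n.ndim == 0):
        raise ValidationError(f"stoichiometry shape {n.shape} does not match G {g.shape}")
    ln_k = -float(np.sum(n * g))
    return float(np.exp(ln_k))


def apply_multiplicity(affinity: float, m: int, mode: str = "multiplicative") -> float:
    """Adjust an affinity for ``m`` symmetry-equivalent binding configurations.

    The default multiplies the affinity value itself (e.g. four docking
    orientations quadruple it).  ``mode="additive-log"`` applies the
    thermodynamic alternative, adding ``ln m`` to the log equilibrium
    constant, i.e. ``affinity + ln(m)``.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValidationError(f"multiplicity must be an integer >= 1, got {m!r}")
    if mode == "multiplicative":
        return float(affinity * m)
    if mode == "additive-log":
        return float(affinity + np.log(m))
    raise ValidationError(f"unknown multiplicity mode {mode!r}")


@dataclass
class AffinityRecord:
    """A structure-derived affinity and its thermodynamic conversions."""

    kd_molar: float
    temperature_K: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL
    multiplicity: int = 1
    reference_molar: float = 1.0
    multiplicity_mode: str = "multiplicative"
    deltaG: float = field(init=False)
    Kstruct: float = field(init=False)

    def __post_init__(self):
        self.deltaG = gibbs_from_kd(self.kd_molar, self.temperature_K, self.gas_constant)
        self.Kstruct = affinity_from_kd(self.kd_molar, self.reference_molar)

    @property
    def model_scale_affinity(self) -> float:
        """Kstruct after the binding-configuration multiplicity adjustment."""
        return apply_multiplicity(self.Kstruct, self.multiplicity, self.multiplicity_mode)


@dataclass
class SpikeSlab:
    """Spike-and-slab mixture centred on a structural affinity.

    ``mix`` is the slab weight alpha: with probability ``1 - alpha`` a draw
    sits exactly at the spike location, otherwise it comes from the
    Normal(location, slab_sd^2) slab.
    """

    location: float
    slab_sd: float
    mix: float = 0.1
    spike_width: float | None = None

    def __post_init__(self):
        if self.slab_sd <= 0:
            raise ValidationError("slab_sd must be positive")
        if not (0.0 <= self.mix <= 1.0):
            raise ValidationError("mix must lie in [0, 1]")
        if self.spike_width is None:
            self.spike_width = self.slab_sd / 100.0
        if self.spike_width <= 0:
            raise ValidationError("spike_width must be positive")

    def density(self, k) -> np.ndarray:
        return spike_slab_density(self, k)

    def sample(self, n: int, seed=0) -> np.ndarray:
        return spike_slab_sample(self, n, seed)


def spike_slab_density(d: SpikeSlab, k) -> np.ndarray:
    """Mixture density with the spike approximated by a narrow Gaussian."""
    k = np.asarray(k, dtype=float)
    spike = stats.norm.pdf(k, loc=d.location, scale=d.spike_width)
    slab = stats.norm.pdf(k, loc=d.location, scale=d.slab_sd)
    return (1.0 - d.mix) * spike + d.mix * slab


def spike_slab_sample(d: SpikeSlab, n: int, seed=0) -> np.ndarray:
    """Draw n values: exact spike location w.p. 1-alpha, slab Gaussian w.p. alpha."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.full(n, d.location, dtype=float)
    slab = rng.random(n) < d.mix
    out[slab] = rng.normal(d.location, d.slab_sd, size=int(slab.sum()))
    return out


def spike_slab_weights(d: SpikeSlab, samples: np.ndarray) -> np.ndarray:
    """Normalized importance weights of posterior samples under the mixture.

    Densities are computed in log space and stabilized by their maximum.
    If every sample's density underflows double precision (log-density
    below roughly -745), the stabilized ratios carry no numerical meaning
    and a degenerate-weights signal is raised instead of silently
    returning.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 1:
        raise ValidationError("need at least one sample")
    log_spike = stats.norm.logpdf(samples, d.location, d.spike_width) + np.log1p(-d.mix) \
        if d.mix < 1.0 else np.full_like(samples, -np.inf)
    log_slab = stats.norm.logpdf(samples, d.location, d.slab_sd) + np.log(d.mix) \
        if d.mix > 0.0 else np.full_like(samples, -np.inf)
    log_w = np.logaddexp(log_spike, log_slab)
    underflow = np.log(np.finfo(float).tiny)  # ~ -708
    if np.max(log_w) < underflow:
        raise DegenerateWeightsError(
            "all spike-and-slab weights underflowed; samples are far outside the mixture"
        )
    log_w = log_w - np.max(log_w)
    w = np.exp(log_w)
    return w / w.sum()


def reweight_posterior(samples, d: SpikeSlab, n_out: int, seed=0) -> np.ndarray:
    """Importance-resample one posterior coordinate against the spike-and-slab.

    Output values are drawn with replacement from the input values with
    probability proportional to their mixture density — the support of the
    output is always a subset of the input.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    w = spike_slab_weights(d, samples)
    rng = np.random.default_rng(seed)
    idx = rng.choice(samples.size, size=int(n_out), replace=True, p=w)
    return samples[idx]
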