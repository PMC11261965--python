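"""Reproducible evaluation protocols for the full pipeline.

These functions package the two headline demonstrations so that tests,
scripts and users run exactly the same procedure:

* :func:`sbi_round_trend` — sequential refinement: over several independent
  synthetic studies, the final round's predictive median distance should
  not exceed round 1's in most replicates.
* :func:`structural_augmentation_trend` — information gain from structure:
  a spike-and-slab prior at the *true* equilibrium constant should lower
  the predictive median distance relative to the unaugmented posterior,
  and a spike displaced by orders of magnitude should not.

The augmentation demonstration first verifies the method's premises on the
fitted study (documented in the methods note): the panel must be
informative (median response above the noise floor), and the posterior
must be consistent with the truth (its 10-90% interval covers the true
coordinate) while retaining meaningful spread — importance resampling can
only re-emphasize posterior mass, never create it.  Study seeds are
scanned in a fixed order until the premises hold; the premises are
properties of the fitted study, not of any sweep outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import BmpOnestepSBI
from .metrics import sweep_spike_slab
from .synthetic import make_synthetic_study

__all__ = ["sbi_round_trend", "structural_augmentation_trend",
           "RoundTrendResult", "AugmentationTrendResult"]


@dataclass
class RoundTrendResult:
    """Median-distance trajectories of independent sequential-SBI replicates."""

    trajectories: list = field(default_factory=list)  # one array per replicate
    ppc: list = field(default_factory=list)

    @property
    def n_improved(self) -> int:
        return int(sum(t[-1] <= t[0] for t in self.trajectories))

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)


def sbi_round_trend(
    n_replicates: int = 5,
    n_rounds: int = 3,
    n_experiments: int = 24,
    sims_per_round: int = 512,
    noise_sd: float = 0.05,
    n_predictive: int = 200,
    seed: int = 0,
) -> RoundTrendResult:
    """Fit independent synthetic studies and record per-round median distance."""
    result = RoundTrendResult()
    for rep in range(n_replicates):
        study_seed = int(seed) + 100 + rep
        _, data, _ = make_synthetic_study(
            seed=study_seed, n_experiments=n_experiments, noise_sd=noise_sd
        )
        model = BmpOnestepSBI(data, noise_sd=noise_sd)
        res = model.fit(
            n_rounds=n_rounds, seed=int(seed) + rep,
            sims_per_round=sims_per_round, n_predictive=n_predictive,
        )
        df = res.history.to_frame()
        result.trajectories.append(df["median_distance"].to_numpy())
        result.ppc.append(df["ppc"].to_numpy())
    return result


@dataclass
class AugmentationTrendResult:
    """Spike-at-truth vs distant-spike comparison across sweep replicates."""

    study_seed: int = -1
    true_K: float = np.nan
    far_location: float = np.nan
    baseline: list = field(default_factory=list)
    true_spike: list = field(default_factory=list)
    far_spike: list = field(default_factory=list)
    premises: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.baseline)

    @property
    def n_true_improved(self) -> int:
        return int(sum(t <= b for t, b in zip(self.true_spike, self.baseline)))

    @property
    def n_far_degraded(self) -> int:
        return int(sum(f >= b for f, b in zip(self.far_spike, self.baseline)))


def _premises_hold(theta_star, data, posterior, noise_sd,
                   min_snr=2.0, spread_band=(0.05, 0.6), seed=0):
    """Premise checks for the augmentation demonstration (see module docstring)."""
    K_true = theta_star[0]
    snr_ok = float(np.median(np.abs(data.observations))) > min_snr * noise_sd
    Ks = posterior.sample(2000, seed)[:, 0]
    lo, hi = np.percentile(Ks, [10, 90])
    coverage_ok = lo <= K_true <= hi
    spread = float(np.std(np.log10(Ks)))
    spread_ok = spread_band[0] <= spread <= spread_band[1]
    return {
        "informative_panel": bool(snr_ok),
        "posterior_covers_truth": bool(coverage_ok),
        "posterior_spread_log10": spread,
        "posterior_spread_in_band": bool(spread_ok),
        "all": bool(snr_ok and coverage_ok and spread_ok),
    }


def structural_augmentation_trend(
    n_replicates: int = 5,
    n_experiments: int = 24,
    n_rounds: int = 3,
    sims_per_round: int = 512,
    noise_sd: float = 0.05,
    alpha: float = 0.1,
    n_draws: int = 500,
    seed: int = 0,
    max_study_scan: int = 12,
) -> AugmentationTrendResult:
    """Run the spike-at-truth vs distant-spike demonstration.

    Scans study seeds in a fixed order, fits each with the sequential loop,
    and runs the sweep replicates on the first study whose fitted posterior
    satisfies the premises.  The distant spike sits three decades from the
    truth (on the side facing away from the posterior mean), clipped to the
    prior box; the informative spike uses a slab sd of 5% of the true value.
    """
    chosen = None
    for k in range(max_study_scan):
        study_seed = int(seed) + 300 + k
        theta_star, data, prior = make_synthetic_study(
            seed=study_seed, n_experiments=n_experiments, noise_sd=noise_sd
        )
        model = BmpOnestepSBI(data, noise_sd=noise_sd)
        res = model.fit(
            n_rounds=n_rounds, seed=int(seed) + k,
            sims_per_round=sims_per_round, n_predictive=100,
        )
        premises = _premises_hold(theta_star, data, res.posterior, noise_sd)
        if premises["all"]:
            chosen = (study_seed, theta_star, data, model, res, premises)
            break
    if chosen is None:
        # no study met the premises within the scan; evaluate the last one
        # anyway and let the recorded premises flag the caveat
        chosen = (study_seed, theta_star, data, model, res, premises)

    study_seed, theta_star, data, model, res, premises = chosen
    K_true = float(theta_star[0])
    Ks = res.posterior.sample(2000, seed=99)[:, 0]
    away = 1e-3 if np.log10(K_true) >= np.mean(np.log10(Ks)) else 1e3
    far = float(np.clip(K_true * away, 1e-4, 1e2))

    result = AugmentationTrendResult(
        study_seed=study_seed, true_K=K_true, far_location=far, premises=premises
    )
    slab_sd = max(0.05 * K_true, 0.01)
    for rep in range(n_replicates):
        sw = sweep_spike_slab(
            res.posterior, model.simulator, data.contexts, data.observations,
            spike_locations=[K_true, far], slab_sds=[slab_sd],
            alpha=alpha, n_draws=n_draws, seed=int(seed) + rep,
        )
        result.baseline.append(float(sw.baseline))
        result.true_spike.append(float(sw.median_distance[0, 0]))
        result.far_spike.append(float(sw.median_distance[1, 0]))
    return result
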