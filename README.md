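# bmpinfer

Simulation-based inference for the BMP "onestep" mass-action signalling
model, with structural-biology affinities injected into the posterior
through a spike-and-slab resampling step.

## The problem

Bone Morphogenetic Protein (BMP) ligands signal promiscuously: several
homodimeric ligands compete for several type I and type II receptors, and
the same ligand mix is read differently by cells expressing different
receptor levels.  The onestep model captures this with one reaction per
trimeric complex,

    A_i + B_k + L_j  ⇌  T_ijk        (equilibrium constant K_ijk),

and a downstream readout `signal = Σ eps_ijk · T_ijk`, giving two
parameters per complex (60 at the full 3 × 2 × 5 pathway scale).  The model
has no tractable likelihood, so fitting it to a panel of dose-response
experiments is a simulation-based-inference (SBI) problem: train a
surrogate of the per-experiment likelihood p(x | θ, c) on simulated pairs,
exploit independence across experiments (the joint likelihood is the
product over the panel), and fit a variational posterior q(θ) over rounds
of sequential refinement.

Separately, a protein-structure pipeline (structure prediction → docking →
affinity regression) yields a dissociation constant Kd for one specific
complex.  `bmpinfer` converts that Kd onto the model's affinity scale
(−ln Kd, with Gibbs-energy and detailed-balance relations and a
binding-configuration multiplicity), encodes it as a spike-and-slab prior
`(1−α)·δ(K − K_struct) + α·N(K_struct, σ²)`, and importance-resamples the
posterior's samples of that equilibrium constant against it.  Whether the
structural information *helped* is measured by the median distance
`med(‖x₀ − x‖₂)` between the observed panel and posterior-predictive
simulations — smaller after augmentation means the structural prior added
information; the package is aimed at systems-biology modellers who want to
test exactly that.

Because the original experimental panel is not redistributable, the
package ships a synthetic-study generator with the same structure
(receptor-expression conditioning variables, single-ligand dose
titrations, additive Gaussian noise) and known ground truth, which is what
the tests and the acceptance script run on.

## Worked example

```python
from bmpinfer import BmpOnestepSBI, make_synthetic_study

# a desk-scale study: 1x1x1 pathway, 24 experiments, known ground truth
theta_star, data, prior = make_synthetic_study(seed=302, n_experiments=24,
                                               noise_sd=0.05)
model = BmpOnestepSBI(data, noise_sd=0.05)
results = model.fit(n_rounds=3, seed=2, sims_per_round=512)
print(results.summary())
```

```
Onestep mass-action SBI results
================================================================
shape: 1 type-A x 1 type-B x 1 ligands  (2 parameters)
experiments: 24   noise sd: 0.05   rounds: 3
----------------------------------------------------------------
round  median distance    PPC %
    1           0.4931     95.8
    2           3.9840     33.3
    3           0.3890     95.8
----------------------------------------------------------------
posterior marginals (log10 scale)
   parameter       mean         sd
    K[0,0,0]      0.489      0.092
  eps[0,0,0]      0.230      0.012
```

The final round's median distance (0.389) improves on round 1 (0.493); the
round-2 excursion is honest SBI behaviour — a freshly retrained surrogate
can transiently mislead the posterior before the next round's simulations
correct it.  The ground truth here was `log10 K* = 0.558,
log10 eps* = 0.236`, consistent with the reported marginals.  Augmenting
with a structural affinity at the true equilibrium constant and comparing
against the unaugmented baseline:

```python
K_true = float(theta_star[0])
sweep = results.augment_with_structure(K_true, spike_locations=[K_true],
                                       slab_sds=[0.05 * K_true], n_draws=500, seed=0)
print(f"baseline {sweep.baseline:.4f}  spike-at-truth {sweep.median_distance[0,0]:.4f}")
# baseline 0.3913  spike-at-truth 0.3612
```

A spike at the true equilibrium constant nudges the predictive cloud
closer to the data; `SweepResult.to_frame()` exports the full grid and
`SweepResult.plot()` draws the median-distance curves with the
unaugmented baseline as a horizontal reference.

The same pipeline runs from the shell over a YAML config:

```sh
bmpinfer simulate config.yaml   # synthetic panel + ground truth + manifest
bmpinfer infer config.yaml      # sequential SBI -> posterior.npz, history.tsv
bmpinfer integrate config.yaml  # Kd conversion + spike-and-slab sweep -> sweep.tsv
bmpinfer report config.yaml
```

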