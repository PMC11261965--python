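"""Affinity unit conversions and spike-and-slab mechanics."""

import numpy as np
import pytest
from scipy import integrate, stats

from bmpinfer import (
    AffinityRecord,
    DegenerateWeightsError,
    SpikeSlab,
    ValidationError,
    affinity_from_kd,
    apply_multiplicity,
    gibbs_from_kd,
    keq_from_gibbs,
    reweight_posterior,
    spike_slab_density,
    spike_slab_sample,
)
from bmpinfer.structural import GAS_CONSTANT_KCAL, binding_multiplicity


class TestAffinityConversions:
    @pytest.mark.parametrize("kd,ref,expected", [
        (1.0, 1.0, 0.0),
        (np.exp(-1.0), 1.0, 1.0),
        (5.8e-12, 1.0, -np.log(5.8e-12)),  # ~25.87
    ])
    def test_affinity_from_kd(self, kd, ref, expected):
        assert affinity_from_kd(kd, ref) == pytest.approx(expected, rel=1e-12)

    def test_strong_binder_magnitude(self):
        assert affinity_from_kd(5.8e-12) == pytest.approx(25.87, abs=0.01)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            affinity_from_kd(0.0)
        with pytest.raises(ValidationError):
            affinity_from_kd(1.0, reference=-2.0)

    def test_gibbs_zero_at_unit_kd(self):
        assert gibbs_from_kd(1.0) == 0.0

    def test_gibbs_strong_binder(self):
        dg = gibbs_from_kd(5.8e-12, 298.15, GAS_CONSTANT_KCAL)
        assert dg == pytest.approx(-15.33, abs=0.01)

    def test_gibbs_sign_flips_across_unit_kd(self):
        assert gibbs_from_kd(0.5) < 0 < gibbs_from_kd(2.0)

    def test_keq_identity_at_zero_energy(self):
        assert keq_from_gibbs(0.0) == 1.0

    def test_keq_linearity_in_stoichiometry(self):
        assert np.log(keq_from_gibbs(1.0, stoich=2.0)) == pytest.approx(-2.0)

    def test_round_trip_with_affinity(self):
        kd = 5.8e-12
        g_rt = gibbs_from_kd(kd, 298.15, GAS_CONSTANT_KCAL) / (GAS_CONSTANT_KCAL * 298.15)
        assert np.log(keq_from_gibbs(g_rt, 1.0)) == pytest.approx(
            affinity_from_kd(kd), rel=1e-12
        )


class TestMultiplicity:
    def test_identity(self):
        assert apply_multiplicity(3.7, 1) == 3.7

    def test_zero_affinity(self):
        assert apply_multiplicity(0.0, 5) == 0.0

    def test_four_configurations(self):
        assert apply_multiplicity(10.24, 4) == pytest.approx(40.96)

    def test_thermodynamic_alternative(self):
        assert apply_multiplicity(10.0, 4, mode="additive-log") == pytest.approx(
            10.0 + np.log(4)
        )

    def test_invalid_multiplicity(self):
        with pytest.raises(ValidationError):
            apply_multiplicity(1.0, 0)

    def test_symmetry_count(self):
        assert binding_multiplicity() == 4

    def test_record_invariant(self):
        rec = AffinityRecord(kd_molar=5.8e-12, multiplicity=4)
        assert rec.deltaG == pytest.approx(
            rec.gas_constant * rec.temperature_K * np.log(rec.kd_molar)
        )
        assert rec.model_scale_affinity == pytest.approx(4 * rec.Kstruct)


class TestSpikeSlabDistribution:
    def test_density_symmetric(self):
        d = SpikeSlab(location=40.0, slab_sd=5.0, mix=0.1)
        for t in (0.3, 1.7, 12.0):
            assert spike_slab_density(d, 40.0 + t) == pytest.approx(
                spike_slab_density(d, 40.0 - t), rel=1e-12
            )

    def test_pure_slab_is_gaussian(self):
        d = SpikeSlab(location=0.0, slab_sd=2.0, mix=1.0)
        x = np.linspace(-5, 5, 11)
        assert np.allclose(spike_slab_density(d, x), stats.norm.pdf(x, 0.0, 2.0))

    def test_density_normalized(self):
        d = SpikeSlab(location=30.0, slab_sd=4.0, mix=0.1)
        total, _ = integrate.quad(lambda k: spike_slab_density(d, k), 30 - 40, 30 + 40,
                                  limit=200)
        assert 0.99 <= total <= 1.01

    def test_all_spike_sampling(self):
        d = SpikeSlab(location=7.0, slab_sd=1.0, mix=0.0)
        assert np.all(spike_slab_sample(d, 100, seed=0) == 7.0)

    def test_all_slab_sampling(self):
        d = SpikeSlab(location=7.0, slab_sd=1.0, mix=1.0)
        assert not np.any(spike_slab_sample(d, 1000, seed=0) == 7.0)

    def test_spike_fraction_binomial(self):
        alpha = 0.1
        n = 100_000
        d = SpikeSlab(location=40.0, slab_sd=5.0, mix=alpha)
        frac = np.mean(spike_slab_sample(d, n, seed=11) == 40.0)
        se = np.sqrt(alpha * (1 - alpha) / n)
        assert abs(frac - (1 - alpha)) <= 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            SpikeSlab(location=0.0, slab_sd=-1.0)
        with pytest.raises(ValidationError):
            SpikeSlab(location=0.0, slab_sd=1.0, mix=1.5)


class TestReweighting:
    def test_constant_input_constant_output(self):
        d = SpikeSlab(location=1.0, slab_sd=1.0, mix=0.1)
        out = reweight_posterior(np.full(50, 3.0), d, 20, seed=0)
        assert np.all(out == 3.0)

    def test_flat_slab_preserves_distribution(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(10.0, 2.0, 3000)
        d = SpikeSlab(location=0.0, slab_sd=1e6, mix=1.0)
        out = reweight_posterior(samples, d, 3000, seed=1)
        assert stats.ks_2samp(samples, out).pvalue > 0.01

    def test_frequencies_match_multinomial_oracle(self):
        values = np.array([38.0, 39.5, 40.0, 41.0, 43.0])
        d = SpikeSlab(location=40.0, slab_sd=2.0, mix=0.5, spike_width=0.5)
        dens = spike_slab_density(d, values)
        w = dens / dens.sum()
        n_out = 100_000
        out = reweight_posterior(values, d, n_out, seed=2)
        for v, p in zip(values, w):
            freq = np.mean(out == v)
            se = np.sqrt(p * (1 - p) / n_out)
            assert abs(freq - p) <= 3 * se + 1e-12

    def test_support_subset(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(5.0, 3.0, 200)
        d = SpikeSlab(location=6.0, slab_sd=1.0, mix=0.1)
        out = reweight_posterior(samples, d, 500, seed=3)
        assert set(out).issubset(set(samples))

    def test_mass_moves_toward_spike(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            samples = rng.normal(rng.uniform(-5, 5), rng.uniform(1, 4), 500)
            loc = rng.uniform(-5, 5)
            d = SpikeSlab(location=loc, slab_sd=1.0, mix=0.1)
            out = reweight_posterior(samples, d, 500, seed=trial)
            assert np.mean(np.abs(out - loc)) <= np.mean(np.abs(samples - loc)) + 1e-9

    def test_degenerate_weights_signal(self):
        d = SpikeSlab(location=0.0, slab_sd=1.0, mix=0.1, spike_width=1e-3)
        far = np.full(10, 1e9)
        with pytest.raises(DegenerateWeightsError):
            reweight_posterior(far, d, 10, seed=0)
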