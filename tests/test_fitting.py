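"""Objective, global fitting, binding free energy, bootstrap diagnostics."""

import numpy as np
import pytest

from ncakin import (
    FitSpec,
    InitialConditions,
    KineticDataset,
    NoiseModel,
    RateParams,
    SamplingSchedule,
    binding_free_energy,
    bootstrap_ci,
    equilibrium_constant_from_free_energy,
    generate_dataset,
    generate_single_stage_dataset,
    global_fit,
    integrate_conversion,
    predict_from_fit,
    sse_objective,
)


@pytest.fixture(scope="module")
def noiseless_dataset(base_params, base_ic):
    return generate_dataset(
        base_params, base_ic, noise=NoiseModel(sigma_add=0.0, seed=0)
    )[0]


class TestKineticDataset:
    def test_validation(self, base_ic):
        with pytest.raises(ValueError):
            KineticDataset(times=[2.0, 1.0, 3.0, 4.0, 5.0],
                           conversion=[0.1] * 5, ic=base_ic)
        with pytest.raises(ValueError):
            KineticDataset(times=[1.0, 2.0], conversion=[0.1, 1.5], ic=base_ic)

    def test_clipping(self, base_ic):
        ds = KineticDataset(times=[1.0, 2.0], conversion=[-0.01, 1.01], ic=base_ic)
        assert ds.conversion_clipped.min() == 0.0
        assert ds.conversion_clipped.max() == 1.0


class TestFitSpec:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(shared={"kr", "k1"}, individual={"k1", "K"})

    def test_unassigned_parameter_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(shared={"kr"}, individual={"k1"}, fixed={"koff": 2.0})

    def test_koff_cannot_be_fit(self):
        with pytest.raises(ValueError):
            FitSpec(shared={"kr", "koff"}, individual={"k1", "K"})


class TestSseObjective:
    def test_self_consistency_on_noiseless_data(self, base_params, noiseless_dataset):
        assert sse_objective(base_params, [noiseless_dataset], rtol=1e-9) <= 1e-8

    def test_wrong_k1_increases_sse(self, base_params, noiseless_dataset):
        wrong = RateParams(
            k1=2 * base_params.k1, kon=base_params.kon,
            koff=base_params.koff, kr=base_params.kr, s=base_params.s,
        )
        sse_true = sse_objective(base_params, [noiseless_dataset])
        assert sse_objective(wrong, [noiseless_dataset]) > sse_true

    def test_noisy_panel_sse_near_noise_floor(self, base_params, base_ic):
        sigma = 0.01
        datasets = generate_dataset(
            base_params, base_ic, noise=NoiseModel(sigma_add=sigma, seed=4), n_reps=3
        )
        n = sum(d.times.size for d in datasets)
        sse = sse_objective(base_params, datasets)
        assert sse == pytest.approx(n * sigma**2, rel=0.35)


class TestGlobalFit:
    def test_single_stage_k1_recovered_exactly(self, base_ic):
        """One noiseless dataset, k1 the only free parameter."""
        truth = 0.02
        ds = generate_single_stage_dataset(
            truth, base_ic, noise=NoiseModel(sigma_add=0.0, seed=0)
        )
        spec = FitSpec(
            shared=frozenset(),
            individual=frozenset({"k1"}),
            fixed={"koff": 2.0, "K": 1e-2, "kr": 1e-4},
            s_grid=(1000,),
        )
        res = global_fit([ds], spec, seed=0)
        assert res.per_dataset[0]["k1"] == pytest.approx(truth, rel=1e-3)

    def test_kon_koff_degeneracy_motivates_fixed_koff(self, base_ic):
        """In the fast-equilibrium regime, scaling kon and koff together
        (K fixed) barely moves conversion: only their ratio is identifiable,
        which is why koff is pinned and K fitted."""
        t = np.geomspace(30, 8000, 80)
        a = RateParams(k1=0.02, kon=100.0, koff=20.0, kr=0.2, s=10)
        b = RateParams(k1=0.02, kon=1000.0, koff=200.0, kr=0.2, s=10)
        xa = integrate_conversion(a, base_ic, t).conversion
        xb = integrate_conversion(b, base_ic, t).conversion
        assert np.max(np.abs(xa - xb)) < 0.005

    def test_two_stage_recovery_small_grid(self, base_params, base_ic):
        """Noisy single-condition data: s and k1 recovered on a narrow grid."""
        datasets = generate_dataset(
            base_params, base_ic, noise=NoiseModel(sigma_add=0.01, seed=7), n_reps=2
        )
        spec = FitSpec(s_grid=tuple(range(8, 13)))
        res = global_fit(datasets, spec, seed=7)
        assert res.s == base_params.s
        assert res.per_dataset[0]["k1"] == pytest.approx(base_params.k1, rel=0.1)

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError):
            global_fit([])


class TestBindingFreeEnergy:
    def test_unit_equilibrium_constant_is_zero(self):
        assert binding_free_energy(1.0, T=298.0) == 0.0

    def test_reference_value(self):
        # K = kon/koff = 10/2 = 5 M^-1 at room temperature
        assert binding_free_energy(5.0, T=298.0) == pytest.approx(-0.95, abs=0.01)

    def test_inversion_of_md_scale_free_energy(self):
        K = equilibrium_constant_from_free_energy(-2.4, T=298.0)
        assert K == pytest.approx(57.6, rel=0.01)
        assert binding_free_energy(K, T=298.0) == pytest.approx(-2.4, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binding_free_energy(0.0)
        with pytest.raises(ValueError):
            binding_free_energy(1.0, T=-5)


class TestPredictFromFit:
    def test_noiseless_self_fit_overlays_data(self, base_params, base_ic,
                                              noiseless_dataset):
        spec = FitSpec(s_grid=(10,))
        res = global_fit([noiseless_dataset], spec, seed=0)
        series, summary, cld = predict_from_fit(res, 0, [noiseless_dataset])
        assert np.max(np.abs(series.conversion - noiseless_dataset.conversion)) < 1e-3
        # terminal state of a ratio-100 run: DPn near 100, controlled breadth
        assert summary.DPn == pytest.approx(100.0, rel=0.05)
        assert 1.0 <= summary.dispersity < 1.5

    def test_predicted_mn_monotone_in_ratio(self, base_params):
        """Stoichiometry: designed and predicted Mn grow with [M]0/[I]0."""
        mns = []
        for ratio in (50.0, 100.0):
            ic = InitialConditions.from_ratio(0.4, ratio)
            ds = generate_dataset(
                base_params, ic, noise=NoiseModel(sigma_add=0.0, seed=0)
            )[0]
            spec = FitSpec(s_grid=(10,))
            res = global_fit([ds], spec, seed=0)
            _, summary, _ = predict_from_fit(res, 0, [ds])
            mns.append(summary.Mn)
        assert mns[1] > mns[0]

    def test_missing_dataset_rejected(self, base_params, noiseless_dataset):
        spec = FitSpec(s_grid=(10,))
        res = global_fit([noiseless_dataset], spec, seed=0)
        with pytest.raises(KeyError):
            predict_from_fit(res, 5, [noiseless_dataset])


class TestBootstrap:
    def test_requires_enough_replicates(self, base_params, noiseless_dataset):
        spec = FitSpec(s_grid=(10,))
        res = global_fit([noiseless_dataset], spec, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci(res, [noiseless_dataset], n_boot=10)

    def test_noiseless_intervals_collapse(self, base_ic):
        ds = generate_single_stage_dataset(
            0.02, base_ic, noise=NoiseModel(sigma_add=0.0, seed=0)
        )
        spec = FitSpec(
            shared=frozenset(), individual=frozenset({"k1"}),
            fixed={"koff": 2.0, "K": 1e-2, "kr": 1e-4}, s_grid=(1000,),
        )
        res = global_fit([ds], spec, seed=0)
        ci = bootstrap_ci(res, [ds], n_boot=100, seed=1)
        width = ci["k1[0]"]["high"] - ci["k1[0]"]["low"]
        assert width < 1e-6
        assert not ci["k1[0]"]["non_identifiable"]

    def test_first_stage_only_data_flags_K(self, base_params, base_ic):
        """Data truncated before the helix stage cannot pin the binding
        constant: its bootstrap interval spans the bounds."""
        full = generate_dataset(
            base_params, base_ic,
            schedule=SamplingSchedule(times=tuple(np.arange(60, 1300, 60.0))),
            noise=NoiseModel(sigma_add=0.005, seed=3),
        )[0]
        keep = full.conversion <= 0.08  # strictly before the coil->helix onset
        ds = KineticDataset(
            full.times[keep], full.conversion[keep], base_ic, label="first stage"
        )
        spec = FitSpec(s_grid=(10,))
        res = global_fit([ds], spec, seed=3)
        ci = bootstrap_ci(res, [ds], n_boot=100, seed=3)
        assert ci["K[0]"]["non_identifiable"]
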