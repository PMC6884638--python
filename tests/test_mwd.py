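"""Chain-length distributions, molar-mass averages, dispersity, GPC traces."""

import numpy as np
import pytest
from scipy import stats

from ncakin import (
    ChainLengthDistribution,
    InitialConditions,
    RateParams,
    build_network,
    chain_length_distribution,
    conversion,
    design_mw,
    gpc_trace,
    integrate,
    moments,
    poisson_reference,
)
from ncakin.mwd import BLG_RESIDUE_MASS, HEXYLAMINE_MASS, central_moment


@pytest.fixture(scope="module")
def terminal_state(base_network):
    return integrate(base_network, 6000.0).final_state


@pytest.fixture(scope="module")
def terminal_cld(terminal_state):
    return chain_length_distribution(terminal_state)


def shifted_poisson(nu: float, I0: float = 1.0) -> ChainLengthDistribution:
    """DP = 1 + Poisson(nu): every chain holds at least one unit."""
    kmax = int(nu + 12 * np.sqrt(nu + 1))
    k = np.arange(0, kmax)
    return ChainLengthDistribution(dp=k + 1, conc=I0 * stats.poisson.pmf(k, nu))


class TestChainLengthDistribution:
    def test_initial_state_is_all_initiator(self, base_network, base_ic):
        st0 = base_network.unpack(0.0, base_network.y0())
        cld = chain_length_distribution(st0)
        assert cld.conc.sum() == 0.0
        assert cld.residual_initiator == base_ic.I0

    def test_chain_total_closes_to_I0(self, terminal_cld, base_ic):
        assert terminal_cld.total_chains == pytest.approx(base_ic.I0, rel=1e-6)

    def test_mass_closure_with_converted_monomer(
        self, base_network, base_ic, terminal_state
    ):
        """sum i*c_i equals converted monomer (free-monomer convention)."""
        cld = chain_length_distribution(terminal_state)
        consumed = base_ic.M0 - terminal_state.M - terminal_state.C.sum()
        assert (cld.dp * cld.conc).sum() == pytest.approx(consumed, rel=1e-6)

    def test_single_stage_limit_is_poisson(self, single_stage_params, base_ic):
        """Pure chain growth: P_i/I0 ~ Poisson(nu), nu = conversion*ratio."""
        net = build_network(single_stage_params, base_ic)
        traj = integrate(net, 3.0 / (0.02 * base_ic.I0))
        x = conversion(traj).conversion[-1]
        cld = chain_length_distribution(traj.final_state)
        ref = poisson_reference(x * base_ic.ratio, I0=base_ic.I0, dp_max=net.Nmax)
        obs = np.concatenate(([cld.residual_initiator], cld.conc)) / base_ic.I0
        exp = np.concatenate(([ref.residual_initiator], ref.conc)) / base_ic.I0
        tvd = 0.5 * np.abs(obs - exp).sum()
        assert tvd <= 1e-3

    def test_two_stage_mwd_depends_on_M0(self, base_params):
        """Terminal distributions at fixed ratio differ between [M]0 values.

        The low-M0 distribution is broader (weaker helix-site saturation
        means a larger relative second-stage acceleration), so its ladder
        must be taller than the 4x-ratio default to hold the tail."""
        fracs = {}
        clds = {}
        for M0, nmax, t_end in ((0.05, 900, 200000.0), (0.4, 400, 20000.0)):
            ic = InitialConditions.from_ratio(M0, 100.0)
            net = build_network(base_params, ic, Nmax=nmax)
            traj = integrate(net, t_end)
            assert conversion(traj).conversion[-1] >= 0.99
            cld = chain_length_distribution(traj.final_state)
            clds[M0] = cld
            fracs[M0] = moments(cld).short_chain_mass_fraction
        n = min(clds[0.05].conc.size, clds[0.4].conc.size)
        a = clds[0.05].conc[:n] / clds[0.05].conc.sum()
        b = clds[0.4].conc[:n] / clds[0.4].conc.sum()
        assert 0.5 * np.abs(a - b).sum() > 0.01  # distributions genuinely differ
        # short chains survive in both, with M0-dependent mass share
        assert fracs[0.05] > 0 and fracs[0.4] > 0
        assert fracs[0.05] != pytest.approx(fracs[0.4], rel=0.05)


class TestMoments:
    def test_monodisperse_dispersity_is_one(self):
        cld = ChainLengthDistribution(dp=[100], conc=[1e-3])
        summ = moments(cld)
        assert summ.dispersity == 1.0
        assert summ.Mn == pytest.approx(100 * BLG_RESIDUE_MASS + HEXYLAMINE_MASS)

    def test_shifted_poisson_dispersity_identity(self):
        """DP = 1 + Poisson(nu) gives DPw/DPn = 1 + nu/(nu+1)^2."""
        nu = 100.0
        summ = moments(shifted_poisson(nu))
        assert summ.DPw / summ.DPn == pytest.approx(1 + nu / (nu + 1) ** 2, abs=1e-4)

    def test_dispersity_at_least_one(self, rng):
        for _ in range(20):
            n = rng.integers(2, 50)
            cld = ChainLengthDistribution(
                dp=np.sort(rng.choice(np.arange(1, 500), size=n, replace=False)),
                conc=rng.random(n),
            )
            summ = moments(cld)
            assert summ.dispersity >= 1.0
            assert summ.DPw >= summ.DPn

    def test_two_stage_broadens_beyond_poisson(self, terminal_cld):
        """Heterogeneous coil->helix crossing broadens the MWD well past the
        ideal living (shifted-Poisson) dispersity at the same DPn."""
        summ = moments(terminal_cld)
        nu = summ.DPn - 1
        poisson_d = 1 + nu / (nu + 1) ** 2
        assert summ.dispersity > poisson_d + 0.01
        assert summ.dispersity < 2.0  # still a controlled polymerization

    def test_empty_distribution_rejected(self):
        cld = ChainLengthDistribution(dp=[1], conc=[0.0])
        with pytest.raises(ValueError):
            moments(cld)


class TestDesignMw:
    @pytest.mark.parametrize(
        "ratio,expected", [(50, 11.1), (100, 22.0), (150, 33.0), (0, 0.1)]
    )
    def test_design_molar_mass_table(self, ratio, expected):
        assert design_mw(ratio) == expected

    def test_monotone_in_ratio(self):
        vals = [design_mw(r) for r in (25, 50, 75, 100, 150, 200)]
        assert vals == sorted(vals)


class TestPoissonReference:
    def test_zero_extent_is_all_initiator(self):
        ref = poisson_reference(0.0, I0=0.004)
        assert ref.conc.sum() == 0.0
        assert ref.residual_initiator == pytest.approx(0.004)

    def test_mode_at_floor_nu(self):
        ref = poisson_reference(100.0)
        assert ref.dp[np.argmax(ref.conc)] in (99, 100)

    def test_two_stage_mwd_is_asymmetric_vs_poisson(self, terminal_cld):
        """Third central moments differ: the adsorption stage skews the MWD."""
        summ = moments(terminal_cld)
        ref = poisson_reference(summ.DPn, dp_max=int(terminal_cld.dp[-1]))
        mu3_model = central_moment(terminal_cld, 3)
        mu3_poisson = central_moment(ref, 3)
        assert abs(mu3_model - mu3_poisson) > 0.2 * abs(mu3_poisson)


class TestGpcTrace:
    def test_monodisperse_unbroadened_single_bin(self):
        cld = ChainLengthDistribution(dp=[100], conc=[1e-3])
        logm, sig = gpc_trace(cld, broadening_sigma=0.0)
        assert (sig > 0).sum() == 1
        assert np.trapezoid(sig, logm) == pytest.approx(1.0, abs=1e-9)

    def test_area_normalized(self, terminal_cld):
        logm, sig = gpc_trace(terminal_cld, broadening_sigma=0.02)
        assert np.trapezoid(sig, logm) == pytest.approx(1.0, abs=1e-9)

    def test_broadened_poisson_peak_position(self):
        ref = poisson_reference(100.0)
        logm, sig = gpc_trace(ref, broadening_sigma=0.02)
        peak = logm[np.argmax(sig)]
        expected = np.log10(100 * BLG_RESIDUE_MASS + HEXYLAMINE_MASS)
        assert peak == pytest.approx(expected, abs=0.02)

    def test_negative_sigma_rejected(self, terminal_cld):
        with pytest.raises(ValueError):
            gpc_trace(terminal_cld, broadening_sigma=-0.1)
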