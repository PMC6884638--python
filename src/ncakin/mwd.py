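"""Chain-length and molar-mass distribution analysis.

Converts chain states of the two-stage model into number distributions over
degree of polymerization (DP), and derives the standard polymer metrics:
DPn, DPw, Mn, Mw, dispersity Đ = Mw/Mn, the short-chain (DP < s) mass
fraction, the stoichiometric "design" molar mass set by [M]0/[I]0, a Poisson
reference distribution (the ideal living chain-growth limit), and a
GPC-like weight-fraction trace on a log10(M) axis.

Default masses are for poly(gamma-benzyl-L-glutamate): repeat unit
219.24 g/mol, n-hexylamine end group 101.19 g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .model_core import ChainState

__all__ = [
    "BLG_RESIDUE_MASS",
    "HEXYLAMINE_MASS",
    "ChainLengthDistribution",
    "MwSummary",
    "chain_length_distribution",
    "moments",
    "design_mw",
    "poisson_reference",
    "gpc_trace",
]

BLG_RESIDUE_MASS = 219.24  # g/mol, gamma-benzyl-L-glutamate repeat unit
HEXYLAMINE_MASS = 101.19  # g/mol, n-hexylamine end group


@dataclass
class ChainLengthDistribution:
    """Number concentrations per DP >= 1; unreacted initiator kept separate.

    Complexed chains count at their chain DP (the bound monomer is not part
    of the chain).  ``s`` is the coil->helix critical length used for the
    short-chain mass fraction; None if not applicable.
    """

    dp: np.ndarray
    conc: np.ndarray
    residual_initiator: float = 0.0
    s: int | None = None

    def __post_init__(self) -> None:
        self.dp = np.asarray(self.dp, dtype=int)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.dp.size != self.conc.size:
            raise ValueError("dp and conc must have equal length")
        if np.any(self.conc < 0):
            raise ValueError("negative concentration in distribution")

    @property
    def total_chains(self) -> float:
        return float(self.conc.sum() + self.residual_initiator)

    def number_fractions(self) -> np.ndarray:
        tot = self.conc.sum()
        return self.conc / tot if tot > 0 else self.conc

    def mass_fractions(self) -> np.ndarray:
        w = self.dp * self.conc
        tot = w.sum()
        return w / tot if tot > 0 else w


@dataclass
class MwSummary:
    DPn: float
    DPw: float
    Mn: float
    Mw: float
    dispersity: float
    short_chain_mass_fraction: float


def chain_length_distribution(state: ChainState) -> ChainLengthDistribution:
    """Pool propagating chains and complexes per DP (i >= 1).

    The unreacted initiator P_0 is excluded from the polymer distribution and
    reported as ``residual_initiator``.
    """
    state = state.clamped()
    nmax = state.P.size - 1
    conc = state.P[1:].copy()
    if state.C.size:
        conc[state.s - 1 : state.s - 1 + state.C.size] += state.C
    return ChainLengthDistribution(
        dp=np.arange(1, nmax + 1),
        conc=conc,
        residual_initiator=float(state.P[0]),
        s=state.s,
    )


def moments(
    cld: ChainLengthDistribution,
    residue_mass: float = BLG_RESIDUE_MASS,
    end_mass: float = HEXYLAMINE_MASS,
) -> MwSummary:
    """Number/weight averages over chains with DP >= 1.

    Chain of DP i has molar mass i*residue_mass + end_mass.  DPn is the
    number-average DP, DPw the weight-average (second/first moment ratio);
    Đ = Mw/Mn >= 1 with equality only for a monodisperse sample.
    """
    c = cld.conc
    n_tot = c.sum()
    if n_tot <= 0:
        raise ValueError("empty chain-length distribution")
    i = cld.dp.astype(float)
    m = i * residue_mass + end_mass
    dpn = float((i * c).sum() / n_tot)
    dpw = float((i**2 * c).sum() / (i * c).sum())
    mn = float((m * c).sum() / n_tot)
    mw = float((m**2 * c).sum() / (m * c).sum())
    if cld.s is not None:
        short = i < cld.s
        scmf = float((i[short] * c[short]).sum() / (i * c).sum())
    else:
        scmf = float("nan")
    return MwSummary(
        DPn=dpn, DPw=dpw, Mn=mn, Mw=mw, dispersity=mw / mn,
        short_chain_mass_fraction=scmf,
    )


def design_mw(
    ratio: float,
    residue_mass: float = BLG_RESIDUE_MASS,
    end_mass: float = HEXYLAMINE_MASS,
) -> float:
    """Design (stoichiometric) Mn in kDa at full conversion, one decimal.

    Every initiator grows ratio = [M]0/[I]0 repeat units on average, so the
    design molar mass is ratio*residue + end group.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return round((ratio * residue_mass + end_mass) / 1000.0, 1)


def poisson_reference(nu: float, I0: float = 1.0, dp_max: int | None = None) -> ChainLengthDistribution:
    """Poisson(nu) number distribution over DP, scaled to chain total I0.

    The exact solution of single-stage living chain growth: after a mean
    extent nu = conversion*ratio per chain, P_i/I0 ~ Poisson(nu).  DP 0
    (the residual initiator) is reported separately.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if dp_max is None:
        dp_max = int(max(10, np.ceil(nu + 12 * np.sqrt(nu + 1))))
    dp = np.arange(1, dp_max + 1)
    pmf = stats.poisson.pmf(dp, nu) if nu > 0 else np.zeros_like(dp, dtype=float)
    p0 = stats.poisson.pmf(0, nu) if nu > 0 else 1.0
    return ChainLengthDistribution(dp=dp, conc=I0 * pmf, residual_initiator=float(I0 * p0))


def gpc_trace(
    cld: ChainLengthDistribution,
    residue_mass: float = BLG_RESIDUE_MASS,
    end_mass: float = HEXYLAMINE_MASS,
    broadening_sigma: float = 0.0,
    n_grid: int = 600,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized weight fraction versus log10(molar mass), GPC-style.

    Projects w_i ~ c_i * M_i onto a uniform log10(M) grid and optionally
    convolves with a Gaussian of width ``broadening_sigma`` (log10-mass
    units) to mimic column band broadening.  The returned curve integrates
    to 1 over log10(M).
    """
    if broadening_sigma < 0:
        raise ValueError("broadening_sigma must be >= 0")
    c = cld.conc
    if c.sum() <= 0:
        raise ValueError("empty chain-length distribution")
    m = cld.dp * residue_mass + end_mass
    logm = np.log10(m)
    w = c * m
    pad = 4 * broadening_sigma + 0.05
    lo, hi = logm.min() - pad, logm.max() + pad
    grid = np.linspace(lo, hi, n_grid)
    signal, edges = np.histogram(logm, bins=n_grid, range=(lo, hi), weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dx = edges[1] - edges[0]
    if broadening_sigma > 0:
        signal = gaussian_filter1d(signal.astype(float), broadening_sigma / dx, mode="constant")
    area = np.trapezoid(signal, centers) if signal.sum() else 1.0
    if area == 0:  # single-bin (monodisperse, unbroadened) trace
        area = signal.sum() * dx
    return centers, signal / area


def central_moment(cld: ChainLengthDistribution, order: int) -> float:
    """Central moment of the DP number distribution (chains with DP >= 1)."""
    f = cld.number_fractions()
    mu = (cld.dp * f).sum()
    return float((((cld.dp - mu) ** order) * f).sum())
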