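"""Reaction network of the two-stage adsorption model of NCA polymerization.

The scheme describes amine-initiated ring-opening polymerization of
N-carboxyanhydrides (NCAs) in which short, coiled chains propagate by a
single bimolecular step while chains that have folded into an alpha-helix
(degree of polymerization >= s) first adsorb the monomer reversibly at the
helical N terminus and then ring-open it — a Michaelis–Menten-like mechanism:

    P_i + M --k1-->  P_{i+1}                    (i < s, coil stage)
    P_i + M <--kon/koff--> C_i --kr--> P_{i+1}  (i >= s, helix stage)

``P_i`` is a propagating chain with ``i`` incorporated monomer units and an
active amine end; ``P_0`` is free initiator; ``C_i`` is the helix–monomer
complex of a DP-``i`` chain with one bound, ring-intact monomer.

The module builds the finite-ladder deterministic rate equations with exact
chain-count and monomer-unit conservation, plus an analytic sparse Jacobian
for stiff integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "RateParams",
    "InitialConditions",
    "ChainState",
    "ReactionNetwork",
    "build_network",
    "rhs",
    "jacobian",
    "conservation_residuals",
    "TruncationError",
]

#: absolute tolerance for integrator undershoot below zero
NEG_TOL = 1e-12


class TruncationError(RuntimeError):
    """Raised when chain mass leaks into the top of the truncated DP ladder."""


@dataclass(frozen=True)
class RateParams:
    """Rate constants of the two-stage scheme.

    Parameters
    ----------
    k1 : float
        Coil-stage propagation rate constant, M^-1 s^-1.  Also used for the
        initiation step (free amine + monomer).
    kon, koff : float
        Monomer adsorption (M^-1 s^-1) and desorption (s^-1) rate constants
        at the helical N terminus.
    kr : float
        Ring-opening rate constant within the helix–monomer complex, s^-1.
    s : int
        Critical chain length (DP) of the coil -> helix transition.
    """

    k1: float
    kon: float
    koff: float
    kr: float
    s: int

    def __post_init__(self) -> None:
        for name in ("k1", "kon", "koff", "kr"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if int(self.s) != self.s or self.s < 2:
            raise ValueError(f"s must be an integer >= 2, got {self.s!r}")
        object.__setattr__(self, "s", int(self.s))

    @property
    def K(self) -> float:
        """Binding equilibrium constant kon/koff, M^-1."""
        if self.koff == 0:
            raise ZeroDivisionError("K undefined for koff = 0")
        return self.kon / self.koff


@dataclass(frozen=True)
class InitialConditions:
    """Initial monomer/initiator concentrations (mol/L) and their ratio."""

    M0: float
    I0: float
    ratio: float

    def __post_init__(self) -> None:
        if not (self.M0 > 0 and self.I0 > 0):
            raise ValueError("M0 and I0 must be positive")
        if abs(self.ratio - self.M0 / self.I0) > 1e-9 * self.ratio:
            raise ValueError("ratio must equal M0/I0")

    @classmethod
    def from_ratio(cls, M0: float, ratio: float) -> "InitialConditions":
        return cls(M0=M0, I0=M0 / ratio, ratio=ratio)


@dataclass
class ChainState:
    """Concentrations at one time point.

    ``P[i]`` (i = 0..Nmax) are propagating chains by incorporated monomer
    count; ``C[j]`` (j = 0..Nmax-s-1) are complexes of chains with DP s+j.
    Complexes exist only for s <= DP <= Nmax-1 so that every ring-opening
    flux stays on the ladder and conservation is exact.
    """

    t: float
    M: float
    P: np.ndarray
    C: np.ndarray
    s: int

    @property
    def total_chains(self) -> float:
        return float(self.P.sum() + self.C.sum())

    @property
    def monomer_units(self) -> float:
        i_P = np.arange(self.P.size)
        i_C = np.arange(self.s, self.s + self.C.size)
        return float(self.M + (i_P * self.P).sum() + ((i_C + 1) * self.C).sum())

    def clamped(self) -> "ChainState":
        """Clamp tiny integrator undershoots (>= -1e-12) to zero."""
        P = np.where((self.P < 0) & (self.P >= -NEG_TOL), 0.0, self.P)
        C = np.where((self.C < 0) & (self.C >= -NEG_TOL), 0.0, self.C)
        M = 0.0 if -NEG_TOL <= self.M < 0 else self.M
        return ChainState(self.t, M, P, C, self.s)


@dataclass(frozen=True)
class ReactionNetwork:
    """Finite-ladder realization of the scheme with truncation DP ``Nmax``."""

    params: RateParams
    ic: InitialConditions
    Nmax: int

    # ---- state-vector layout: y = [M, P_0..P_Nmax, C_s..C_{Nmax-1}] ----

    @property
    def n_P(self) -> int:
        return self.Nmax + 1

    @property
    def n_C(self) -> int:
        return max(0, self.Nmax - self.params.s)

    @property
    def n_state(self) -> int:
        return 1 + self.n_P + self.n_C

    @property
    def single_stage(self) -> bool:
        """True when the helix stage is unreachable on this ladder."""
        return self.n_C == 0

    def y0(self) -> np.ndarray:
        y = np.zeros(self.n_state)
        y[0] = self.ic.M0
        y[1] = self.ic.I0  # P_0 = free initiator
        return y

    def unpack(self, t: float, y: np.ndarray) -> ChainState:
        if y.size != self.n_state:
            raise ValueError(
                f"state vector has size {y.size}, network expects {self.n_state}"
            )
        return ChainState(
            t=t,
            M=float(y[0]),
            P=np.asarray(y[1 : 1 + self.n_P], dtype=float),
            C=np.asarray(y[1 + self.n_P :], dtype=float),
            s=self.params.s,
        )

    def pack(self, state: ChainState) -> np.ndarray:
        return np.concatenate(([state.M], state.P, state.C))

    def check_truncation(self, y: np.ndarray) -> None:
        """Fail if the top 5% of the DP ladder holds non-negligible chains."""
        state = self.unpack(0.0, y)
        top = int(math.floor(0.95 * self.Nmax))
        occ = state.P[top:].sum()
        if self.n_C:
            occ += state.C[max(0, top - self.params.s) :].sum()
        if occ >= 1e-10 * self.ic.I0:
            raise TruncationError(
                f"chain occupancy {occ:.3e} M above DP {top} exceeds "
                f"1e-10*I0 = {1e-10 * self.ic.I0:.3e} M; increase Nmax"
            )


def build_network(
    params: RateParams,
    ic: InitialConditions,
    Nmax: int | str = "auto",
) -> ReactionNetwork:
    """Assemble the finite reaction network.

    ``Nmax="auto"`` uses ceil(4 * [M]0/[I]0): living chain growth concentrates
    mass near DP = ratio, and 4x leaves headroom for the distribution tail.
    A network with s >= Nmax has no reachable helix stage and degenerates to
    pure single-stage chain growth at rate k1.
    """
    if Nmax == "auto":
        Nmax = int(math.ceil(4 * ic.ratio))
    Nmax = int(Nmax)
    if Nmax < 2:
        raise ValueError(f"Nmax must be >= 2, got {Nmax}")
    return ReactionNetwork(params=params, ic=ic, Nmax=Nmax)


def rhs(t: float, y: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Time derivative of the concentration vector.

    Fluxes: coil propagation k1*M*P_i (i < s, including initiation from P_0),
    adsorption kon*M*P_i / desorption koff*C_i and ring-opening kr*C_i for
    s <= i <= Nmax-1.  Chain count and monomer-unit totals are conserved
    identically (all fluxes are internal transfers).
    """
    p = network.params
    Nmax = network.Nmax
    sc = min(p.s, Nmax)  # last coil index is sc-1; ladder cap at Nmax

    M = y[0]
    P = y[1 : 1 + network.n_P]
    C = y[1 + network.n_P :]

    dP = np.zeros_like(P)
    prop = p.k1 * M * P[:sc]
    dP[:sc] -= prop
    dP[1 : sc + 1] += prop
    dM = -prop.sum()

    if network.n_C:
        bind = p.kon * M * P[p.s : Nmax]
        unbind = p.koff * C
        ring = p.kr * C
        dP[p.s : Nmax] += unbind - bind
        dP[p.s + 1 : Nmax + 1] += ring
        dC = bind - unbind - ring
        dM += unbind.sum() - bind.sum()
    else:
        dC = np.zeros(0)

    dy = np.empty_like(y)
    dy[0] = dM
    dy[1 : 1 + network.n_P] = dP
    dy[1 + network.n_P :] = dC
    return dy


def jacobian(t: float, y: np.ndarray, network: ReactionNetwork) -> sparse.csc_matrix:
    """Analytic sparse Jacobian of :func:`rhs` (CSC, for stiff solvers)."""
    p = network.params
    Nmax = network.Nmax
    sc = min(p.s, Nmax)
    nP = network.n_P
    nC = network.n_C
    n = network.n_state

    M = y[0]
    P = y[1 : 1 + nP]

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        r, c, v = np.broadcast_arrays(
            np.asarray(r, dtype=np.int64),
            np.asarray(c, dtype=np.int64),
            np.asarray(v, dtype=float),
        )
        rows.append(np.atleast_1d(r))
        cols.append(np.atleast_1d(c))
        vals.append(np.atleast_1d(v))

    iP = lambda i: 1 + i  # noqa: E731
    iC = lambda i: 1 + nP + (i - p.s)  # noqa: E731

    coil = np.arange(sc)
    # dM/d*
    dM_dM = -p.k1 * P[:sc].sum()
    add(0, iP(coil), np.full(sc, -p.k1 * M))
    # dP_i/dM and dP_i/dP_* from coil propagation
    add(iP(coil), 0, p.k1 * (np.concatenate(([0.0], P[: sc - 1])) - P[:sc]))
    add(iP(sc), 0, p.k1 * P[sc - 1])
    add(iP(coil), iP(coil), np.full(sc, -p.k1 * M))
    add(iP(coil + 1), iP(coil), np.full(sc, p.k1 * M))

    if nC:
        helix = np.arange(p.s, Nmax)
        dM_dM += -p.kon * P[p.s : Nmax].sum()
        add(0, iP(helix), np.full(nC, -p.kon * M))
        add(0, iC(helix), np.full(nC, p.koff))
        # binding: dP_i, dC_i vs M and P_i
        add(iP(helix), 0, -p.kon * P[p.s : Nmax])
        add(iC(helix), 0, p.kon * P[p.s : Nmax])
        add(iP(helix), iP(helix), np.full(nC, -p.kon * M))
        add(iC(helix), iP(helix), np.full(nC, p.kon * M))
        # desorption and ring opening vs C_i
        add(iP(helix), iC(helix), np.full(nC, p.koff))
        add(iP(helix + 1), iC(helix), np.full(nC, p.kr))
        add(iC(helix), iC(helix), np.full(nC, -(p.koff + p.kr)))

    add(0, 0, dM_dM)
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return mat.tocsc()


def conservation_residuals(
    state: ChainState, ic: InitialConditions
) -> tuple[float, float]:
    """Relative errors of chain-count and monomer-unit conservation.

    Returns ``(|sum P + sum C - I0|/I0, |M + sum i*P_i + sum (i+1)*C_i - M0|/M0)``.
    """
    chain = abs(state.total_chains - ic.I0) / ic.I0
    mass = abs(state.monomer_units - ic.M0) / ic.M0
    return chain, mass
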