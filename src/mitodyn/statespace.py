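"""Microstate spaces and mass-action transition sets for respiratory complexes I and III.

The electron state of a respiratory complex is represented as an ordered
array of small integer codes, one per redox carrier or quinone binding site
(0 = oxidized / empty, 1 = reduced / occupied; the flavin has three levels:
0 = FMN, 1 = flavosemiquinone radical, 2 = fully reduced FMNH2).  The full
complex I model enumerates the cartesian product of the flavin, the eight
iron-sulfur clusters and the bound-semiquinone site (1536 states); the
lumped variant replaces the five mid-chain clusters N1b, N4, N5, N6a, N6b
by a single two-state effective carrier (96 states).  Complex III runs the
q-cycle over c1, the Rieske Fe-S cluster, the p-site semiquinone pocket,
the two b-hemes and the n-site semiquinone pocket; the p-site semiquinone
can only exist while the Rieske cluster is reduced, which prunes the
64-state product down to 48 legal states.

All electron transfers and binding events are reversible mass action
transitions between microstates.  Backward rate constants are derived from
class-level midpoint-potential differences (quoted at pH 7), so any cycle
of transitions is thermodynamically consistent by construction and the
machines satisfy detailed balance at zero proton-motive force.

Membrane-potential dependence: a transition moving ``z`` positive charges
out of the matrix carries a symmetric Butler-Volmer factor,
``exp(alpha*z*u)`` on the forward and ``exp(-(1-alpha)*z*u)`` on the
backward rate, with ``u = dpsi / (RT/F)`` and ``dpsi`` negative in an
energized mitochondrion, so that outward pumping is slowed and its reversal
favoured as the membrane hyperpolarizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .constants import C_REF_MM, H_REF_MM, RT_OVER_F_MV

__all__ = [
    "CarrierSpec",
    "StateSpace",
    "TransitionRule",
    "TransitionSet",
    "POOL_NAMES",
    "POOL_REFS",
    "enumerate_states",
    "enumerate_complex_i_states",
    "enumerate_complex_iii_states",
    "complex_i_rules",
    "complex_iii_rules",
    "instantiate_transitions",
    "transition_flux",
    "transition_fluxes",
    "complex_occupancy_summaries",
    "machine_steady_state",
    "equilibrium_pools",
]


#: External reactant pools a respiratory-complex transition may touch.
POOL_NAMES: tuple[str, ...] = (
    "NADH",
    "NAD",
    "Q_n",
    "QH2_n",
    "Q_p",
    "QH2_p",
    "cytc_ox",
    "cytc_red",
    "H_m",
    "H_c",
)

#: Reference concentrations (mM) used to non-dimensionalize pool factors in
#: the mass-action rates; protons are referenced to pH 7 so that rate ratios
#: derived from pH-7 midpoint potentials stay consistent.
POOL_REFS: dict[str, float] = {name: C_REF_MM for name in POOL_NAMES}
POOL_REFS["H_m"] = H_REF_MM
POOL_REFS["H_c"] = H_REF_MM

_POOL_INDEX = {name: i for i, name in enumerate(POOL_NAMES)}


@dataclass(frozen=True)
class CarrierSpec:
    """One redox carrier or quinone binding site of a respiratory complex."""

    name: str
    n_states: int
    kind: str = "fixed-carrier"  # or "binding-site"
    membrane_side: str = "matrix-arm"  # "matrix-arm" | "n-site" | "p-site"

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ValueError(f"carrier {self.name}: n_states must be 2 or 3")
        if self.kind not in ("fixed-carrier", "binding-site"):
            raise ValueError(f"carrier {self.name}: unknown kind {self.kind!r}")


class StateSpace:
    """Enumerated set of legal microstates of one respiratory complex.

    States are stored as an ``(n_states, n_carriers)`` integer array in a
    deterministic order: ascending mixed-radix code with the first-listed
    carrier most significant.  ``index_of`` maps a code array back to its
    row; the round trip is exact by construction.
    """

    def __init__(self, complex_id: str, carriers: Sequence[CarrierSpec],
                 states: np.ndarray):
        names = [c.name for c in carriers]
        if len(set(names)) != len(names):
            raise ValueError("carrier names must be unique within a complex")
        self.complex_id = complex_id
        self.carriers = tuple(carriers)
        self.states = np.ascontiguousarray(states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[1] != len(carriers):
            raise ValueError("states array shape does not match carriers")
        self._carrier_pos = {c.name: i for i, c in enumerate(carriers)}
        radices = np.array([c.n_states for c in carriers], dtype=np.int64)
        weights = np.ones(len(carriers), dtype=np.int64)
        for i in range(len(carriers) - 2, -1, -1):
            weights[i] = weights[i + 1] * radices[i + 1]
        self._weights = weights
        keys = self.states.astype(np.int64) @ weights
        if len(set(keys.tolist())) != len(keys):
            raise ValueError("duplicate microstates")
        self._key_to_row = {int(k): i for i, k in enumerate(keys)}

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def __len__(self) -> int:
        return self.n_states

    def carrier_position(self, name: str) -> int:
        return self._carrier_pos[name]

    def key_of(self, codes: np.ndarray) -> int:
        return int(np.asarray(codes, dtype=np.int64) @ self._weights)

    def index_of(self, codes: np.ndarray) -> int:
        """Row index of a code array; KeyError if the state is not legal."""
        return self._key_to_row[self.key_of(codes)]

    def contains(self, codes: np.ndarray) -> bool:
        return self.key_of(codes) in self._key_to_row

    def column(self, name: str) -> np.ndarray:
        """Codes of one carrier across all states."""
        return self.states[:, self._carrier_pos[name]]

    def to_frame(self):
        """State table (index + one column per carrier) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            self.states, columns=[c.name for c in self.carriers]
        ).rename_axis("state")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def enumerate_states(
    complex_id: str,
    carriers: Sequence[CarrierSpec],
    exclusion: Callable[[np.ndarray], np.ndarray] | None = None,
) -> StateSpace:
    """Enumerate all legal code arrays for ``carriers``.

    ``exclusion``, if given, receives the full ``(n, k)`` candidate array and
    returns a boolean mask of states to *keep*.
    """
    radices = [c.n_states for c in carriers]
    grids = np.meshgrid(*[np.arange(r) for r in radices], indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1).astype(np.int8)
    if exclusion is not None:
        states = states[exclusion(states)]
    return StateSpace(complex_id, carriers, states)


# ---------------------------------------------------------------------------
# Complex I
# ---------------------------------------------------------------------------

#: Chain order of the iron-sulfur clusters in the matrix arm (full model).
CI_FULL_CHAIN = ("N3", "N1b", "N4", "N5", "N6a", "N6b", "N2")
#: Lumped variant: N1b..N6b replaced by one effective carrier "NL".
CI_LUMPED_CHAIN = ("N3", "NL", "N2")


def complex_i_carriers(lumped: bool = True) -> list[CarrierSpec]:
    chain = CI_LUMPED_CHAIN if lumped else CI_FULL_CHAIN
    carriers = [CarrierSpec("FMN", 3)]
    carriers.append(CarrierSpec(chain[0], 2))
    carriers.append(CarrierSpec("N1a", 2))
    for name in chain[1:]:
        carriers.append(CarrierSpec(name, 2))
    carriers.append(CarrierSpec("SQ", 2, kind="binding-site", membrane_side="n-site"))
    return carriers


def enumerate_complex_i_states(lumped: bool = True) -> StateSpace:
    """State space of complex I: 1536 states full, 96 lumped."""
    cid = "CI-lumped" if lumped else "CI-full"
    return enumerate_states(cid, complex_i_carriers(lumped))


# ---------------------------------------------------------------------------
# Complex III
# ---------------------------------------------------------------------------

CIII_CARRIER_NAMES = ("c1", "FeS", "SQp", "bL", "bH", "SQn")


def complex_iii_carriers() -> list[CarrierSpec]:
    side = {"c1": "p-site", "FeS": "p-site", "SQp": "p-site",
            "bL": "p-site", "bH": "n-site", "SQn": "n-site"}
    kind = {"SQp": "binding-site", "SQn": "binding-site"}
    return [
        CarrierSpec(n, 2, kind=kind.get(n, "fixed-carrier"), membrane_side=side[n])
        for n in CIII_CARRIER_NAMES
    ]


def ciii_exclusion(states: np.ndarray) -> np.ndarray:
    """A p-site semiquinone can only be bound while the Rieske Fe-S is reduced."""
    sqp = states[:, CIII_CARRIER_NAMES.index("SQp")]
    fes = states[:, CIII_CARRIER_NAMES.index("FeS")]
    return ~((sqp == 1) & (fes == 0))


def enumerate_complex_iii_states() -> StateSpace:
    """State space of the complex III q-cycle: 48 legal states."""
    return enumerate_states("CIII", complex_iii_carriers(), exclusion=ciii_exclusion)


# ---------------------------------------------------------------------------
# Transition rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionRule:
    """A reversible transition class over carrier code patterns.

    ``changes`` maps carrier names to (source_code, target_code); ``requires``
    adds gating conditions on carriers that do not change.  ``k_forward`` is
    in 1/s (occupancies in mM; bimolecular pool factors are
    non-dimensionalized by the pool reference concentrations).
    ``k_backward`` is tied to ``k_forward`` through the class equilibrium
    constant ``exp(delta_e_mv / (RT/F))`` where ``delta_e_mv`` sums the
    midpoint-potential drops of all transferred electrons.

    ``charge_moved`` (z) counts positive charges crossing the membrane
    outward per forward event; ``protons_pumped`` counts protons delivered
    from the matrix side to the cytosolic side (used by the stoichiometry
    audit and the proton-balance bookkeeping).
    """

    name: str
    changes: tuple[tuple[str, int, int], ...]
    k_forward: float
    delta_e_mv: float
    requires: tuple[tuple[str, int], ...] = ()
    charge_moved: float = 0.0
    protons_pumped: int = 0
    pools_forward: tuple[tuple[str, int], ...] = ()
    pools_reverse: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.k_forward < 0:
            raise ValueError(f"rule {self.name}: negative forward rate")
        for pool, _ in self.pools_forward + self.pools_reverse:
            if pool not in _POOL_INDEX:
                raise KeyError(f"rule {self.name}: unknown pool {pool!r}")

    @property
    def keq(self) -> float:
        return float(np.exp(self.delta_e_mv / RT_OVER_F_MV))

    @property
    def k_backward(self) -> float:
        return self.k_forward / self.keq


def _pool_exponents(pairs: Iterable[tuple[str, int]]) -> np.ndarray:
    v = np.zeros(len(POOL_NAMES))
    for name, nu in pairs:
        v[_POOL_INDEX[name]] += nu
    return v


class TransitionSet:
    """Concrete transitions of one rule set instantiated over a state space.

    Holds flat arrays (source index, target index, rule index) plus
    per-rule kinetic data, and a sparse occupancy incidence matrix so that
    the full set of net fluxes and occupancy derivatives is evaluated with
    a handful of vectorized operations.
    """

    def __init__(self, space: StateSpace, rules: Sequence[TransitionRule],
                 src: np.ndarray, tgt: np.ndarray, rule_idx: np.ndarray):
        self.space = space
        self.rules = tuple(rules)
        self.src = np.asarray(src, dtype=np.int64)
        self.tgt = np.asarray(tgt, dtype=np.int64)
        self.rule_idx = np.asarray(rule_idx, dtype=np.int64)
        n_t = len(self.src)
        self.kf = np.array([rules[r].k_forward for r in self.rule_idx])
        self.kb = np.array([rules[r].k_backward for r in self.rule_idx])
        self.z = np.array([rules[r].charge_moved for r in self.rule_idx])
        self.pumped = np.array([rules[r].protons_pumped for r in self.rule_idx],
                               dtype=float)
        # per-rule pool exponent matrices, gathered per transition
        fwd = np.stack([_pool_exponents(r.pools_forward) for r in rules])
        rev = np.stack([_pool_exponents(r.pools_reverse) for r in rules])
        self.pool_nu_fwd = fwd[self.rule_idx]  # (n_t, n_pools)
        self.pool_nu_rev = rev[self.rule_idx]
        #: net pool production per unit forward flux (reverse minus forward)
        self.pool_stoich = self.pool_nu_rev - self.pool_nu_fwd
        data = np.concatenate([-np.ones(n_t), np.ones(n_t)])
        rows = np.concatenate([self.src, self.tgt])
        cols = np.concatenate([np.arange(n_t), np.arange(n_t)])
        self.incidence = sp.csr_matrix(
            (data, (rows, cols)), shape=(space.n_states, n_t)
        )
        # connected components of the transition graph: the complex I rule
        # set conserves electron-count parity, so its state space splits
        # into two dynamically invariant sectors; each needs its own
        # occupancy constraint in the stationary master equation
        parent = np.arange(space.n_states)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for s_, t_ in zip(self.src, self.tgt):
            rs, rt = find(int(s_)), find(int(t_))
            if rs != rt:
                parent[rs] = rt
        self.component = np.array([find(i) for i in range(space.n_states)])
        self.component_roots = np.unique(self.component)
        # fixed sparsity pattern of the master-equation rate matrix, with
        # one balance row per component pre-replaced by that component's
        # occupancy conservation constraint
        me_rows = np.concatenate([self.tgt, self.src, self.src, self.tgt])
        me_cols = np.concatenate([self.src, self.src, self.tgt, self.tgt])
        rep = {int(r): i for i, r in enumerate(self.component_roots)}
        self._me_keep = ~np.isin(me_rows, self.component_roots)
        cons_rows, cons_cols = [], []
        for root in self.component_roots:
            members = np.nonzero(self.component == root)[0]
            cons_rows.append(np.full(len(members), root, dtype=np.int64))
            cons_cols.append(members.astype(np.int64))
        self._me_rows = np.concatenate([me_rows[self._me_keep]]
                                       + cons_rows)
        self._me_cols = np.concatenate([me_cols[self._me_keep]]
                                       + cons_cols)
        self._me_n_cons = sum(len(c) for c in cons_cols)

    @property
    def n_transitions(self) -> int:
        return len(self.src)

    def fluxes(self, occupancy: np.ndarray, dpsi_mv: float,
               pools: Mapping[str, float] | np.ndarray,
               alpha: float = 0.5) -> np.ndarray:
        """Net forward flux of every transition (mM/s).

        ``occupancy`` is the per-microstate concentration vector (mM);
        ``pools`` the external reactant concentrations (mM), either a mapping
        or a vector ordered like ``POOL_NAMES``.
        """
        pool_vec = _pools_to_vec(pools)
        if np.any(pool_vec < 0):
            raise ValueError("negative pool concentration")
        occ = np.asarray(occupancy, dtype=float)
        if np.any(occ < -1e-6):
            raise ValueError("negative occupancy")
        refs = _POOL_REF_VEC
        with np.errstate(divide="ignore"):
            logc = np.log(np.maximum(pool_vec, 1e-300) / refs)
        ffac = np.exp(self.pool_nu_fwd @ logc)
        rfac = np.exp(self.pool_nu_rev @ logc)
        # zero concentrations: exp(nu * log(~0)) underflows to 0 as it should
        zero = pool_vec <= 0.0
        if zero.any():
            ffac = np.where((self.pool_nu_fwd[:, zero] > 0).any(axis=1), 0.0, ffac)
            rfac = np.where((self.pool_nu_rev[:, zero] > 0).any(axis=1), 0.0, rfac)
        u = dpsi_mv / RT_OVER_F_MV
        bf = np.exp(alpha * self.z * u)
        bb = np.exp(-(1.0 - alpha) * self.z * u)
        return self.kf * bf * occ[self.src] * ffac - self.kb * bb * occ[self.tgt] * rfac

    def occupancy_derivative(self, fluxes: np.ndarray) -> np.ndarray:
        """d(occupancy)/dt from a vector of per-transition net fluxes."""
        return self.incidence @ fluxes

    def pool_production(self, fluxes: np.ndarray) -> np.ndarray:
        """Net production rate of every external pool (mM/s, POOL_NAMES order)."""
        return self.pool_stoich.T @ fluxes


_POOL_REF_VEC = np.array([POOL_REFS[n] for n in POOL_NAMES])


def _pools_to_vec(pools: Mapping[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(pools, np.ndarray):
        return pools
    vec = np.zeros(len(POOL_NAMES))
    for name, c in pools.items():
        vec[_POOL_INDEX[name]] = c
    return vec


def instantiate_transitions(rules: Sequence[TransitionRule],
                            space: StateSpace) -> TransitionSet:
    """Expand pattern rules into concrete (source, target) transitions.

    One transition is created per rule and legal source state whose target is
    also legal; duplicates (same source, target and rule) are removed.
    Referencing a carrier absent from the space is a configuration error.
    """
    for rule in rules:
        for name, *_ in rule.changes:
            if name not in space._carrier_pos:
                raise KeyError(f"rule {rule.name}: unknown carrier {name!r}")
        for name, _ in rule.requires:
            if name not in space._carrier_pos:
                raise KeyError(f"rule {rule.name}: unknown carrier {name!r}")
    src_list, tgt_list, ridx_list = [], [], []
    seen: set[tuple[int, int, int]] = set()
    for ri, rule in enumerate(rules):
        mask = np.ones(space.n_states, dtype=bool)
        for name, code_from, _ in rule.changes:
            mask &= space.column(name) == code_from
        for name, code in rule.requires:
            mask &= space.column(name) == code
        sources = np.nonzero(mask)[0]
        for s in sources:
            codes = space.states[s].copy()
            for name, _, code_to in rule.changes:
                codes[space.carrier_position(name)] = code_to
            if not space.contains(codes):
                continue
            t = space.index_of(codes)
            key = (int(s), int(t), ri)
            if key in seen:
                continue
            seen.add(key)
            src_list.append(s)
            tgt_list.append(t)
            ridx_list.append(ri)
    return TransitionSet(space, rules, np.array(src_list, dtype=np.int64),
                         np.array(tgt_list, dtype=np.int64),
                         np.array(ridx_list, dtype=np.int64))


def transition_flux(tset: TransitionSet, i: int, occupancy: np.ndarray,
                    dpsi_mv: float, pools: Mapping[str, float],
                    alpha: float = 0.5) -> float:
    """Net rate of a single transition (convenience wrapper)."""
    return float(tset.fluxes(occupancy, dpsi_mv, pools, alpha=alpha)[i])


def transition_fluxes(tset: TransitionSet, occupancy: np.ndarray,
                      dpsi_mv: float, pools: Mapping[str, float],
                      alpha: float = 0.5) -> np.ndarray:
    return tset.fluxes(occupancy, dpsi_mv, pools, alpha=alpha)


# ---------------------------------------------------------------------------
# Default rule sets (midpoint potentials in mV, pH 7)
# ---------------------------------------------------------------------------

#: Midpoint potentials of the complex I carriers and couples.  The flavin is
#: split into its two one-electron couples (FMN/FMNH. and FMNH./FMNH2); the
#: bound semiquinone couples sum to twice the free Q/QH2 midpoint so that
#: releasing ubiquinol closes the thermodynamic cycle.
CI_DEFAULT_ENERGIES: dict[str, float] = {
    "NADH": -320.0,   # 2e- couple
    "FMN1": -390.0,   # FMN/FMNH. (ox -> radical)
    "FMN2": -290.0,   # FMNH./FMNH2 (radical -> fully reduced)
    "N3": -250.0,
    "N1a": -370.0,
    "N1b": -250.0,
    "N4": -250.0,
    "N5": -260.0,
    "N6a": -250.0,
    "N6b": -250.0,
    "NL": -250.0,     # lumped N1b..N6b carrier
    "N2": -80.0,
    "SQ1": 60.0,      # Q/SQ(bound), complex I n-site
    "SQ2": 60.0,      # SQ(bound)/QH2
}

CI_DEFAULT_KF: dict[str, float] = {
    "nadh_ox": 2.5e3,
    "fmn_hop": 1.0e4,
    "n1a_exchange": 1.0e3,
    "chain_hop": 1.0e4,
    "pump_hop": 5.0e3,
    "q_bind": 2.0e3,
    "sq_reduce": 2.0e3,
}


def complex_i_rules(lumped: bool = True,
                    energies: Mapping[str, float] | None = None,
                    kf: Mapping[str, float] | None = None,
                    rate_scale: float = 1.0) -> list[TransitionRule]:
    """Reversible mass-action rule set for complex I.

    Electron path: FMN -> N3 -> (N1b -> N4 -> N5 -> N6a -> N6b | NL) -> N2
    -> bound SQ -> QH2, with N1a as an off-path one-electron reservoir
    exchanging with the flavin radical.  Proton export (one per event,
    z = +1) is carried by the N6b->N2 (NL->N2) transfer and by both
    electron deliveries from N2 to the quinone site, four protons per NADH
    in total.
    """
    E = dict(CI_DEFAULT_ENERGIES)
    if energies:
        E.update(energies)
    K = dict(CI_DEFAULT_KF)
    if kf:
        K.update(kf)
    chain = CI_LUMPED_CHAIN if lumped else CI_FULL_CHAIN
    s = rate_scale
    rules: list[TransitionRule] = [
        TransitionRule(
            "nadh_ox",
            changes=(("FMN", 0, 2),),
            k_forward=K["nadh_ox"] * s,
            delta_e_mv=(E["FMN1"] + E["FMN2"]) - 2.0 * E["NADH"],
            pools_forward=(("NADH", 1), ("H_m", 1)),
            pools_reverse=(("NAD", 1),),
        ),
        TransitionRule(
            "fmn2_to_" + chain[0],
            changes=(("FMN", 2, 1), (chain[0], 0, 1)),
            k_forward=K["fmn_hop"] * s,
            delta_e_mv=E[chain[0]] - E["FMN2"],
            pools_reverse=(("H_m", 1),),
        ),
        TransitionRule(
            "fmn1_to_" + chain[0],
            changes=(("FMN", 1, 0), (chain[0], 0, 1)),
            k_forward=K["fmn_hop"] * s,
            delta_e_mv=E[chain[0]] - E["FMN1"],
            pools_reverse=(("H_m", 1),),
        ),
        TransitionRule(
            "fmn1_to_n1a",
            changes=(("FMN", 1, 0), ("N1a", 0, 1)),
            k_forward=K["n1a_exchange"] * s,
            delta_e_mv=E["N1a"] - E["FMN1"],
            pools_reverse=(("H_m", 1),),
        ),
    ]
    for donor, acceptor in zip(chain[:-1], chain[1:]):
        pumping = acceptor == "N2"
        rules.append(TransitionRule(
            f"{donor.lower()}_to_{acceptor.lower()}",
            changes=((donor, 1, 0), (acceptor, 0, 1)),
            k_forward=(K["pump_hop"] if pumping else K["chain_hop"]) * s,
            delta_e_mv=E[acceptor] - E[donor],
            charge_moved=1.0 if pumping else 0.0,
            protons_pumped=1 if pumping else 0,
            pools_forward=(("H_m", 1),) if pumping else (),
            pools_reverse=(("H_c", 1),) if pumping else (),
        ))
    rules.append(TransitionRule(
        "q_bind_reduce",
        changes=(("N2", 1, 0), ("SQ", 0, 1)),
        k_forward=K["q_bind"] * s,
        delta_e_mv=E["SQ1"] - E["N2"],
        charge_moved=1.0,
        protons_pumped=1,
        pools_forward=(("Q_n", 1), ("H_m", 1)),
        pools_reverse=(("H_c", 1),),
    ))
    rules.append(TransitionRule(
        "sq_reduce_release",
        changes=(("N2", 1, 0), ("SQ", 1, 0)),
        k_forward=K["sq_reduce"] * s,
        delta_e_mv=E["SQ2"] - E["N2"],
        charge_moved=1.0,
        protons_pumped=1,
        pools_forward=(("H_m", 3),),           # 2 chemical + 1 pumped
        pools_reverse=(("QH2_n", 1), ("H_c", 1)),
    ))
    return rules


#: Midpoint potentials of the complex III carriers and quinone couples.
CIII_DEFAULT_ENERGIES: dict[str, float] = {
    "FeS": 250.0,
    "c1": 255.0,
    "cytc": 250.0,
    "bL": -135.0,
    "bH": -42.0,
    "SQ1p": -160.0,   # Q/SQ at the p-site pocket
    "SQ2p": 280.0,    # SQ/QH2 at the p-site pocket (2 H+ to the p side)
    "SQ1n": 16.0,     # Q/SQ at the n-site pocket
    "SQ2n": 104.0,    # SQ/QH2 at the n-site pocket (2 H+ from the matrix)
}

CIII_DEFAULT_KF: dict[str, float] = {
    "qh2p_ox": 3.0e3,
    "sqp_to_bl": 2.0e4,
    "fes_to_c1": 2.0e4,
    "c1_to_c": 2.0e4,
    "bl_to_bh": 1.0e4,
    "qn_bind": 4.0e3,
    "sqn_reduce": 1.0e4,
}


def complex_iii_rules(energies: Mapping[str, float] | None = None,
                      kf: Mapping[str, float] | None = None,
                      rate_scale: float = 1.0) -> list[TransitionRule]:
    """Reversible q-cycle rule set for complex III.

    Ubiquinol is oxidized at the p-site in two one-electron steps: the first
    reduces the Rieske Fe-S cluster and leaves a bound semiquinone (both
    protons released to the cytosolic side); the second reduces heme bL and
    releases ubiquinone.  While the p-site semiquinone is bound, neither the
    Fe-S -> c1 transfer nor the inter-heme bL -> bH transfer can proceed
    (the latter gate reconstructs the documented reaction count of 88).
    The q-cycle's charge translocation (two charges per electron pair) is
    distributed over the membrane dielectric: the p-side quinol oxidation,
    the trans-membrane bL -> bH transfer and the n-side quinone reduction
    steps carry dielectric fractions 0.25 / 0.5 / 0.25 of an elementary
    charge each.  At the n-site, heme bH reduces ubiquinone
    to a bound semiquinone and then to ubiquinol, taking up two matrix
    protons.
    """
    E = dict(CIII_DEFAULT_ENERGIES)
    if energies:
        E.update(energies)
    K = dict(CIII_DEFAULT_KF)
    if kf:
        K.update(kf)
    s = rate_scale
    return [
        TransitionRule(
            "qh2p_ox",
            changes=(("FeS", 0, 1), ("SQp", 0, 1)),
            k_forward=K["qh2p_ox"] * s,
            delta_e_mv=E["FeS"] - E["SQ2p"],
            charge_moved=0.25,
            protons_pumped=2,
            pools_forward=(("QH2_p", 1),),
            pools_reverse=(("H_c", 2),),
        ),
        TransitionRule(
            "sqp_to_bl",
            changes=(("SQp", 1, 0), ("bL", 0, 1)),
            k_forward=K["sqp_to_bl"] * s,
            delta_e_mv=E["bL"] - E["SQ1p"],
            pools_reverse=(("Q_p", 1),),
        ),
        TransitionRule(
            "fes_to_c1",
            changes=(("FeS", 1, 0), ("c1", 0, 1)),
            requires=(("SQp", 0),),
            k_forward=K["fes_to_c1"] * s,
            delta_e_mv=E["c1"] - E["FeS"],
        ),
        TransitionRule(
            "c1_to_cytc",
            changes=(("c1", 1, 0),),
            k_forward=K["c1_to_c"] * s,
            delta_e_mv=E["cytc"] - E["c1"],
            pools_forward=(("cytc_ox", 1),),
            pools_reverse=(("cytc_red", 1),),
        ),
        TransitionRule(
            "bl_to_bh",
            changes=(("bL", 1, 0), ("bH", 0, 1)),
            requires=(("SQp", 0),),
            k_forward=K["bl_to_bh"] * s,
            delta_e_mv=E["bH"] - E["bL"],
            charge_moved=0.5,
        ),
        TransitionRule(
            "qn_bind",
            changes=(("bH", 1, 0), ("SQn", 0, 1)),
            k_forward=K["qn_bind"] * s,
            delta_e_mv=E["SQ1n"] - E["bH"],
            charge_moved=0.25,
            pools_forward=(("Q_n", 1),),
        ),
        TransitionRule(
            "sqn_reduce",
            changes=(("bH", 1, 0), ("SQn", 1, 0)),
            k_forward=K["sqn_reduce"] * s,
            delta_e_mv=E["SQ2n"] - E["bH"],
            charge_moved=0.25,
            pools_forward=(("H_m", 2),),
            pools_reverse=(("QH2_n", 1),),
        ),
    ]


# ---------------------------------------------------------------------------
# Observables and analysis helpers
# ---------------------------------------------------------------------------

#: Site conditions whose marginal occupancies are tracked as proxies for
#: superoxide-producing propensity.
ROS_SITES: dict[str, tuple[str, str, int]] = {
    # name -> (complex prefix, carrier, code)
    "flavin_reduced": ("CI", "FMN", 2),
    "flavin_radical": ("CI", "FMN", 1),
    "CI_SQ": ("CI", "SQ", 1),
    "CIII_SQp": ("CIII", "SQp", 1),
    "CIII_SQn": ("CIII", "SQn", 1),
}


def complex_occupancy_summaries(space: StateSpace,
                                occupancy: np.ndarray) -> dict[str, float]:
    """Marginal occupancy of the ROS-relevant sites of one complex.

    Returns the summed occupancy (same units as ``occupancy``) of all
    microstates matching each site condition: fully reduced flavin, flavin
    radical and bound SQ for complex I; bound SQ_p and SQ_n for complex III.
    """
    occ = np.asarray(occupancy, dtype=float)
    out: dict[str, float] = {}
    prefix = "CI" if space.complex_id.startswith("CI-") else "CIII"
    for site, (cplx, carrier, code) in ROS_SITES.items():
        if cplx != prefix:
            continue
        mask = space.column(carrier) == code
        out[site] = float(occ[mask].sum())
    return out


def machine_steady_state(tset: TransitionSet, pools: Mapping[str, float],
                         dpsi_mv: float, total: float,
                         alpha: float = 0.5) -> np.ndarray:
    """Steady-state occupancy of one complex at fixed boundary pools.

    The transition fluxes are linear in the occupancy vector at fixed pools
    and membrane potential, so the steady state solves a sparse linear
    system (master equation) under the conservation constraint that
    occupancies sum to the total complex concentration.
    """
    n = tset.space.n_states
    if total == 0.0:
        return np.zeros(n)
    pool_vec = _pools_to_vec(pools)
    refs = _POOL_REF_VEC
    # tiny floor keeps the master-equation matrix irreducible when a pool
    # is depleted (rates vanish smoothly instead of disconnecting states)
    logc = np.log(np.maximum(pool_vec, 1e-6 * refs) / refs)
    ffac = np.exp(tset.pool_nu_fwd @ logc)
    rfac = np.exp(tset.pool_nu_rev @ logc)
    u = dpsi_mv / RT_OVER_F_MV
    a_f = tset.kf * np.exp(alpha * tset.z * u) * ffac
    a_b = tset.kb * np.exp(-(1.0 - alpha) * tset.z * u) * rfac
    vals = np.concatenate([a_f, -a_f, a_b, -a_b])[tset._me_keep]
    vals = np.concatenate([vals, np.ones(tset._me_n_cons)])
    rhs = np.zeros(n)
    # all occupancy is placed in the sector of the all-oxidized state; any
    # dynamically disconnected sector (odd electron parity in complex I)
    # stays empty
    rhs[tset.component[0]] = total
    if n <= 256:
        Ad = np.zeros((n, n))
        np.add.at(Ad, (tset._me_rows, tset._me_cols), vals)
        try:
            occ = np.linalg.solve(Ad, rhs)
            # one step of iterative refinement sharpens the solution enough
            # for finite-difference Jacobians of downstream residuals
            occ = occ + np.linalg.solve(Ad, rhs - Ad @ occ)
        except np.linalg.LinAlgError:
            occ, *_ = np.linalg.lstsq(Ad, rhs, rcond=None)
        if not np.all(np.isfinite(occ)):
            occ, *_ = np.linalg.lstsq(Ad, rhs, rcond=None)
        return np.asarray(occ)
    Ac = sp.csr_matrix((vals, (tset._me_rows, tset._me_cols)), shape=(n, n))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("error", sp.linalg.MatrixRankWarning)
        try:
            occ = sp.linalg.spsolve(Ac, rhs)
            occ = occ + sp.linalg.spsolve(Ac, rhs - Ac @ occ)
        except (sp.linalg.MatrixRankWarning, RuntimeError):
            occ, *_ = np.linalg.lstsq(Ac.toarray(), rhs, rcond=None)
    if not np.all(np.isfinite(occ)):
        occ, *_ = np.linalg.lstsq(Ac.toarray(), rhs, rcond=None)
    return np.asarray(occ)


def equilibrium_pools(e_star_mv: float = -150.0,
                      ci_energies: Mapping[str, float] | None = None,
                      ciii_energies: Mapping[str, float] | None = None,
                      scale: float = 1.0) -> dict[str, float]:
    """Boundary pool concentrations in redox equilibrium at potential E*.

    With every pool couple poised at the common electron potential
    ``e_star_mv`` (Nernst), zero membrane potential and pH 7 on both sides,
    every transition of both machines is individually at equilibrium, which
    is the condition probed by the detailed-balance property tests.
    """
    Ei = dict(CI_DEFAULT_ENERGIES)
    if ci_energies:
        Ei.update(ci_energies)
    Eiii = dict(CIII_DEFAULT_ENERGIES)
    if ciii_energies:
        Eiii.update(ciii_energies)
    rtf = RT_OVER_F_MV
    e = e_star_mv
    # NAD/NADH = exp(2 (E* - E_NADH) / RT/F); keep NADH at `scale` mM
    nadh = scale
    nad = nadh * np.exp(2.0 * (e - Ei["NADH"]) / rtf)
    e_q = 0.5 * (Eiii["SQ1n"] + Eiii["SQ2n"])  # free Q/QH2 couple, 2 e-
    qh2 = scale
    q = qh2 * np.exp(2.0 * (e - e_q) / rtf)
    cred = scale
    cox = cred * np.exp((e - Eiii["cytc"]) / rtf)
    return {
        "NADH": nadh, "NAD": nad,
        "Q_n": q, "QH2_n": qh2, "Q_p": q, "QH2_p": qh2,
        "cytc_ox": cox, "cytc_red": cred,
        "H_m": H_REF_MM, "H_c": H_REF_MM,
    }
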