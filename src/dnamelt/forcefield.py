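"""Energies and analytic forces of the three interaction sets.

The model follows the three-set decomposition of bead-spring DNA force
fields: (i) intra-strand bonded terms (harmonic+quartic bonds, harmonic
angles, periodic dihedrals) plus Gō-type 12-10 stacking wells on native
intra-strand base-base contacts; (ii) inter-strand terms: Morse wells
between native basepairs (deeper for G-C than A-T) and screened Coulomb
repulsion between the charged phosphates; (iii) excluded volume for chain
self-avoidance.  Salt enters only through the Debye screening length.

Equilibrium values of every bonded term are measured from the ideal B-form
reference structure, so the built helix is an exact minimum of the bonded
energy (Gō convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import _kernels
from .constants import COULOMB_KJ_A, DEFAULT_CONSTANTS, PhysicalConstants
from .params import ForceFieldParams
from .topology import Configuration, DuplexTopology

__all__ = [
    "debye_length",
    "EnergyReport",
    "ForceTables",
    "build_tables",
    "energy_report",
    "bonded_energy",
    "base_pairing_energy",
    "excluded_volume_energy",
    "electrostatic_energy",
    "total_energy",
    "total_force",
]


def debye_length(
    T: float, I: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Debye screening length κ_D in Å for a 1:1 salt.

    κ_D = sqrt(ε₀ ε_k R T / (2 N_A² e² I)), with the ionic strength ``I``
    given in mol/L (converted to mol/m³ internally) and ε_k fixed at its
    room-temperature value.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if I <= 0:
        raise ValueError("ionic strength must be positive")
    c = constants
    i_si = I * 1000.0  # mol/L -> mol/m^3
    kappa_m = np.sqrt(
        c.vacuum_permittivity
        * c.relative_permittivity
        * c.gas_constant
        * T
        / (2.0 * c.avogadro**2 * c.elementary_charge**2 * i_si)
    )
    return float(kappa_m * 1e10)


# ---------------------------------------------------------------------------
# geometry measurements (same conventions as the force kernel)

def _angle(pos, i, j, k) -> float:
    a = pos[i] - pos[j]
    b = pos[k] - pos[j]
    cost = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cost, -1.0, 1.0)))


def _dihedral(pos, i, j, k, l) -> float:
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    sinp = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    cosp = np.dot(n1, n2)
    return float(np.arctan2(sinp, cosp))


@dataclass
class ForceTables:
    """Flat per-instance interaction arrays consumed by the numba kernels."""

    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k2: np.ndarray
    bond_k4: np.ndarray
    ang_idx: np.ndarray
    ang_t0: np.ndarray
    ang_k: np.ndarray
    dih_idx: np.ndarray
    dih_p0: np.ndarray
    dih_k: np.ndarray
    stk_idx: np.ndarray
    stk_sig: np.ndarray
    stk_eps: np.ndarray
    bp_idx: np.ndarray
    bp_sig: np.ndarray
    bp_eps: np.ndarray
    bp_alpha: np.ndarray
    ev_idx: np.ndarray
    ev_eps: float
    ev_sig: float
    ev_cut: float
    pp_idx: np.ndarray
    elec_pref: float  # q_i q_j e²N_A/(4πε₀ε_k), kJ Å/mol, for unit charges

    def as_args(self) -> tuple:
        return (
            self.bond_idx, self.bond_r0, self.bond_k2, self.bond_k4,
            self.ang_idx, self.ang_t0, self.ang_k,
            self.dih_idx, self.dih_p0, self.dih_k,
            self.stk_idx, self.stk_sig, self.stk_eps,
            self.bp_idx, self.bp_sig, self.bp_eps, self.bp_alpha,
            self.ev_idx, self.ev_eps, self.ev_sig, self.ev_cut,
            self.pp_idx, self.elec_pref,
        )


def build_tables(topo: DuplexTopology, params: ForceFieldParams) -> ForceTables:
    """Expand the per-class parameter table into per-instance arrays, taking
    every equilibrium value from the reference structure."""
    ref = topo.reference_positions

    bond_idx = topo.bonds
    bond_r0 = np.linalg.norm(ref[bond_idx[:, 0]] - ref[bond_idx[:, 1]], axis=1)
    bond_k2 = np.array([params.bonds[c]["k2"] for c in topo.bond_classes])
    bond_k4 = np.array([params.bonds[c]["k4"] for c in topo.bond_classes])

    ang_idx = topo.angles
    ang_t0 = np.array([_angle(ref, *ijk) for ijk in ang_idx])
    ang_k = np.array([params.angles[c]["k"] for c in topo.angle_classes])

    dih_idx = topo.dihedrals
    dih_p0 = np.array([_dihedral(ref, *ijkl) for ijkl in dih_idx])
    dih_k = np.array([params.dihedrals[c]["k"] for c in topo.dihedral_classes])

    stk_idx = topo.native_contacts
    stk_sig = np.linalg.norm(ref[stk_idx[:, 0]] - ref[stk_idx[:, 1]], axis=1)
    stk_eps = np.full(len(stk_idx), params.stacking_eps)

    # Watson-Crick wells plus (when cross_factor > 0) cross-stacking wells
    # between each base and the partner base of the neighbouring pair;
    # the latter break on strand separation and provide the duplex
    # cooperativity that makes melting proceed by end unzipping.
    bp_rows = [[i, j] for i, j, _ in topo.basepairs]
    bp_sig_l = [
        params.sigma_AT if c == "AT" else params.sigma_GC for _, _, c in topo.basepairs
    ]
    bp_eps_l = [
        params.eps_AT if c == "AT" else params.eps_GC for _, _, c in topo.basepairs
    ]
    if params.bp_cross_eps > 0.0:
        npairs = len(topo.basepairs)
        for p in range(npairs - 1):
            i_p, j_p, _ = topo.basepairs[p]
            i_q, j_q, _ = topo.basepairs[p + 1]
            depth = params.bp_cross_eps
            for a, b in ((i_p, j_q), (i_q, j_p)):
                bp_rows.append([a, b])
                bp_sig_l.append(float(np.linalg.norm(ref[a] - ref[b])))
                bp_eps_l.append(depth)
    bp_idx = np.array(bp_rows, dtype=np.int64)
    bp_sig = np.array(bp_sig_l)
    bp_eps = np.array(bp_eps_l)
    bp_alpha = np.full(len(bp_idx), params.bp_alpha)

    # excluded volume: every pair not already interacting through a bonded
    # term (1-2, 1-3, 1-4), a native stack or a native basepair
    excluded = set()
    for i, j in topo.bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, j, k in topo.angles:
        excluded.add((min(i, k), max(i, k)))
    for i, j, k, l in topo.dihedrals:
        excluded.add((min(i, l), max(i, l)))
    for i, j in topo.native_contacts:
        excluded.add((min(i, j), max(i, j)))
    for i, j in bp_rows:  # WC pairs and cross-stacking contacts
        excluded.add((min(i, j), max(i, j)))
    n = topo.n_beads
    iu, ju = np.triu_indices(n, k=1)
    keep = np.array([(int(a), int(b)) not in excluded for a, b in zip(iu, ju)])
    ev_idx = np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)

    phos = topo.phosphate_indices
    pi, pj = np.triu_indices(len(phos), k=1)
    pp_idx = np.stack([phos[pi], phos[pj]], axis=1).astype(np.int64)

    return ForceTables(
        bond_idx=bond_idx.astype(np.int64), bond_r0=bond_r0,
        bond_k2=bond_k2, bond_k4=bond_k4,
        ang_idx=ang_idx.astype(np.int64), ang_t0=ang_t0, ang_k=ang_k,
        dih_idx=dih_idx.astype(np.int64), dih_p0=dih_p0, dih_k=dih_k,
        stk_idx=stk_idx.astype(np.int64), stk_sig=stk_sig, stk_eps=stk_eps,
        bp_idx=bp_idx, bp_sig=bp_sig, bp_eps=bp_eps, bp_alpha=bp_alpha,
        ev_idx=ev_idx,
        ev_eps=params.ev_eps, ev_sig=params.ev_sigma,
        ev_cut=params.ev_cutoff_factor * params.ev_sigma,
        pp_idx=pp_idx,
        elec_pref=COULOMB_KJ_A / params.relative_permittivity,
    )


def get_tables(topo: DuplexTopology, params: ForceFieldParams) -> ForceTables:
    """Cached :func:`build_tables` (one entry per topology object)."""
    cache = getattr(topo, "_ff_cache", None)
    if cache is not None and cache[0] is params:
        return cache[1]
    tables = build_tables(topo, params)
    topo._ff_cache = (params, tables)
    return tables


@dataclass
class EnergyReport:
    """Energy decomposition in kJ/mol."""

    bonded: float            # bonds + angles + dihedrals + native stacking
    base_pairing: float
    excluded_volume: float
    electrostatic: float     # screened phosphate-phosphate repulsion (V_qq)

    @property
    def total(self) -> float:
        return self.bonded + self.base_pairing + self.excluded_volume + self.electrostatic

    def as_dict(self) -> dict:
        return {
            "bonded": self.bonded,
            "base_pairing": self.base_pairing,
            "excluded_volume": self.excluded_volume,
            "electrostatic": self.electrostatic,
            "total": self.total,
        }


def _eval(conf, topo, params, T, I) -> Tuple[np.ndarray, tuple]:
    tables = get_tables(topo, params)
    kappa = debye_length(T, I) if (T is not None and I is not None) else -1.0
    pos = np.ascontiguousarray(conf.positions, dtype=np.float64)
    f = np.zeros_like(pos)
    comps = _kernels.eval_forces(pos, f, *tables.as_args(), kappa)
    return f, comps


def energy_report(
    conf: Configuration,
    topo: DuplexTopology,
    params: ForceFieldParams | None = None,
    T: float | None = None,
    I: float | None = None,
) -> EnergyReport:
    """Full energy decomposition; omit ``T``/``I`` to skip electrostatics."""
    params = params or ForceFieldParams.default()
    _, (eb, ea, ed, es, ebp, eev, eel) = _eval(conf, topo, params, T, I)
    return EnergyReport(
        bonded=eb + ea + ed + es,
        base_pairing=ebp,
        excluded_volume=eev,
        electrostatic=eel,
    )


def bonded_energy(conf, topo, params=None) -> float:
    """Intra-strand bond + angle + dihedral + native stacking energy."""
    return energy_report(conf, topo, params).bonded


def base_pairing_energy(conf, topo, params=None) -> float:
    return energy_report(conf, topo, params).base_pairing


def excluded_volume_energy(conf, topo, params=None) -> float:
    return energy_report(conf, topo, params).excluded_volume


def electrostatic_energy(conf, topo, T, I, params=None) -> float:
    """Screened Coulomb repulsion summed over phosphate pairs, kJ/mol.

    Strictly positive (like charges) and monotonically decreasing in the
    ionic strength at fixed configuration.
    """
    params = params or ForceFieldParams.default()
    pos = conf.positions
    tables = get_tables(topo, params)
    d = np.linalg.norm(pos[tables.pp_idx[:, 0]] - pos[tables.pp_idx[:, 1]], axis=1)
    if np.any(d <= 0):
        raise ValueError("coincident phosphate beads")
    return energy_report(conf, topo, params, T, I).electrostatic


def total_energy(conf, topo, params=None, T=None, I=None) -> float:
    return energy_report(conf, topo, params, T, I).total


def total_force(
    conf: Configuration,
    topo: DuplexTopology,
    params: ForceFieldParams | None = None,
    T: float | None = None,
    I: float | None = None,
) -> np.ndarray:
    """Analytic negative gradient of the total energy, kJ/mol/Å, shape (n, 3)."""
    params = params or ForceFieldParams.default()
    f, _ = _eval(conf, topo, params, T, I)
    return f
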