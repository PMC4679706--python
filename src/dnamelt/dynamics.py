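"""Langevin dynamics with inertia, thermostatted by a Nosé-Hoover chain
combined with Langevin friction/noise (NHL), integrated by velocity Verlet.

The equation of motion per bead is

    m d²r/dt² = -∇U - γ m dr/dt + W(t),

with the random force satisfying the fluctuation-dissipation relation at
the target temperature.  The friction/noise pair is applied as an exact
Ornstein-Uhlenbeck substep in the middle of the velocity-Verlet step
(BAOAB splitting); the Nosé-Hoover chain half-steps bracket the whole
step.  Either mechanism can be switched off independently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import _kernels
from .constants import KB, ROOM_TEMPERATURE
from .forcefield import debye_length, get_tables
from .params import ForceFieldParams
from .topology import Configuration, DuplexTopology

THERMOSTATS = {
    "off": _kernels.MODE_OFF,
    "langevin": _kernels.MODE_LANGEVIN,
    "nh": _kernels.MODE_NH,
    "nhl": _kernels.MODE_NHL,
}


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    ``gamma`` is the Langevin friction rate in ps⁻¹ (applied per unit
    mass), ``nh_coupling`` the Nosé-Hoover relaxation time in ps.
    """

    dt: float = 0.01              # ps
    gamma: float = 0.05           # ps^-1
    T_target: float = ROOM_TEMPERATURE
    I: float = 0.05               # mol/L
    n_steps: int = 0
    seed: int = 0
    thermostat: str = "nhl"       # nhl | nh | langevin | off
    nh_chain_length: int = 2
    nh_coupling: float = 0.1      # ps
    langevin_stride: int = 1      # apply friction/noise every k-th step

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.T_target <= 0:
            raise ValueError("T_target must be positive")
        if self.thermostat not in THERMOSTATS:
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.nh_chain_length < 1:
            raise ValueError("nh_chain_length must be >= 1")
        if self.langevin_stride < 1:
            raise ValueError("langevin_stride must be >= 1")


@dataclass
class SimState:
    """Positions, velocities, thermostat variables and RNG bookkeeping."""

    conf: Configuration
    velocities: np.ndarray
    nh_xi: np.ndarray
    nh_vxi: np.ndarray
    time: float = 0.0             # ps
    rng_calls: int = 0            # per-kernel-invocation counter

    def copy(self) -> "SimState":
        return SimState(
            conf=self.conf.copy(),
            velocities=self.velocities.copy(),
            nh_xi=self.nh_xi.copy(),
            nh_vxi=self.nh_vxi.copy(),
            time=self.time,
            rng_calls=self.rng_calls,
        )

    def kinetic_energy(self, topo: DuplexTopology) -> float:
        return float(_kernels.kinetic_energy(self.velocities, topo.masses))

    def kinetic_temperature(self, topo: DuplexTopology, cfg: "SimConfig") -> float:
        nf = n_dof(topo, cfg)
        return 2.0 * self.kinetic_energy(topo) / (nf * KB)


@dataclass
class Trajectory:
    """Frames stored every ``report_every`` steps, plus energy decomposition.

    ``energies`` columns: bond, angle, dihedral, stack, base_pair,
    excluded_volume, electrostatic, kinetic.
    """

    times: np.ndarray             # (F,) ps
    positions: np.ndarray         # (F, n, 3) Å
    velocities: Optional[np.ndarray] = None  # (F, n, 3) Å/ps
    energies: Optional[np.ndarray] = None    # (F, 8) kJ/mol

    ENERGY_COLUMNS = (
        "bond", "angle", "dihedral", "stack",
        "base_pair", "excluded_volume", "electrostatic", "kinetic",
    )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt_frame(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a frame spacing")
        return float(self.times[1] - self.times[0])

    def total_energies(self) -> np.ndarray:
        if self.energies is None:
            raise ValueError("trajectory carries no energies")
        return self.energies.sum(axis=1)

    def write_energy_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("time_ps",) + self.ENERGY_COLUMNS + ("total",))
            for t, row in zip(self.times, self.energies):
                w.writerow([f"{t:.6g}"] + [f"{v:.10g}" for v in row] + [f"{row.sum():.10g}"])

    def write_xyz(self, path: str | Path, topo: DuplexTopology) -> None:
        """XYZ trajectory; element tags encode bead kind (P, S, or base letter)."""
        tags = [
            "P" if b.kind == "phosphate" else ("S" if b.kind == "sugar" else b.base_id)
            for b in topo.beads
        ]
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.positions):
                fh.write(f"{len(tags)}\n")
                fh.write(f"t={t:.6g} ps\n")
                for tag, (x, y, z) in zip(tags, frame):
                    fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")

    @classmethod
    def read_xyz(cls, path: str | Path) -> "Trajectory":
        times, frames = [], []
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines) and lines[i].strip():
            n = int(lines[i])
            times.append(float(lines[i + 1].split("=")[1].split()[0]))
            block = [
                [float(v) for v in lines[i + 2 + k].split()[1:4]] for k in range(n)
            ]
            frames.append(block)
            i += 2 + n
        return cls(times=np.array(times), positions=np.array(frames))


def n_dof(topo: DuplexTopology, cfg: SimConfig) -> int:
    """Thermal degrees of freedom: Langevin noise breaks momentum
    conservation, so only pure-NH / NVE runs subtract the center of mass."""
    n = 3 * topo.n_beads
    if cfg.thermostat in ("off", "nh") or cfg.gamma == 0.0:
        return n - 3
    return n


def init_velocities(
    topo: DuplexTopology, T: float, seed: int, remove_drift: bool = True
) -> np.ndarray:
    """Maxwell-Boltzmann velocities in Å/ps."""
    rng = np.random.default_rng(seed)
    m = topo.masses
    v = rng.standard_normal((topo.n_beads, 3)) * np.sqrt(KB * T * 100.0 / m)[:, None]
    if remove_drift:
        v -= (m[:, None] * v).sum(axis=0) / m.sum()
    return v


def new_state(
    topo: DuplexTopology,
    conf: Configuration,
    cfg: SimConfig,
    velocity_seed: Optional[int] = None,
) -> SimState:
    """Fresh state with MB velocities (or zero when ``velocity_seed`` is None)."""
    if velocity_seed is None:
        vel = np.zeros((topo.n_beads, 3))
    else:
        vel = init_velocities(topo, cfg.T_target, velocity_seed)
    m = cfg.nh_chain_length
    return SimState(
        conf=conf.copy(),
        velocities=vel,
        nh_xi=np.zeros(m),
        nh_vxi=np.zeros(m),
        time=0.0,
    )


def _nh_masses(topo: DuplexTopology, cfg: SimConfig) -> np.ndarray:
    kt = KB * cfg.T_target
    tau2 = cfg.nh_coupling**2
    q = np.full(cfg.nh_chain_length, kt * tau2)
    q[0] *= n_dof(topo, cfg)
    return q


def _kernel_seed(cfg: SimConfig, state: SimState) -> int:
    ss = np.random.SeedSequence([int(cfg.seed) % (2**31), int(state.rng_calls)])
    return int(ss.generate_state(1)[0] % (2**31))


def _run(
    state: SimState,
    cfg: SimConfig,
    topo: DuplexTopology,
    params: ForceFieldParams,
    n_steps: int,
    record_every: int = 0,
    monitor: Optional[dict] = None,
):
    """Shared driver around the integrate kernel. Mutates ``state`` in place;
    returns (trajectory-or-None, detection dict, steps_done)."""
    tables = get_tables(topo, params)
    kappa = debye_length(cfg.T_target, cfg.I)
    mode = THERMOSTATS[cfg.thermostat]
    q = _nh_masses(topo, cfg)
    nf = n_dof(topo, cfg)
    masses = topo.masses

    if monitor is None:
        mon_a = np.zeros(0, dtype=np.int64)
        mon_b = np.zeros(0, dtype=np.int64)
        mon_thr = np.zeros(0)
        consec = np.zeros(0, dtype=np.int64)
        ev_time = np.zeros(0)
        check_every = 0
        persist = 0
        stop = False
    else:
        mon_a = monitor["a"]
        mon_b = monitor["b"]
        mon_thr = monitor["thr"]
        consec = monitor["consec"]
        ev_time = monitor["time"]
        check_every = monitor["check_every"]
        persist = monitor["persist"]
        stop = monitor.get("stop_when_melted", True)

    if record_every > 0:
        n_frames = n_steps // record_every + 1
        rec_t = np.zeros(n_frames)
        rec_pos = np.zeros((n_frames, topo.n_beads, 3))
        rec_vel = np.zeros_like(rec_pos)
        rec_en = np.zeros((n_frames, 8))
    else:
        rec_t = np.zeros(0)
        rec_pos = np.zeros((0, topo.n_beads, 3))
        rec_vel = np.zeros_like(rec_pos)
        rec_en = np.zeros((0, 8))

    seed = _kernel_seed(cfg, state)
    pos = state.conf.positions
    steps_done, status, frames = _kernels.integrate(
        pos, state.velocities, masses,
        *tables.as_args(), kappa,
        n_steps, cfg.dt, cfg.gamma, KB * cfg.T_target, mode, cfg.langevin_stride,
        state.nh_vxi, state.nh_xi, q, nf,
        seed,
        check_every, persist, mon_a, mon_b, mon_thr, consec, ev_time,
        state.time, stop,
        record_every, rec_t, rec_pos, rec_vel, rec_en,
    )
    state.time += steps_done * cfg.dt
    state.rng_calls += 1
    if status == _kernels.STATUS_NONFINITE:
        raise FloatingPointError(
            f"integrator blew up (non-finite coordinates) near step {steps_done}"
        )
    traj = None
    if record_every > 0:
        traj = Trajectory(
            times=rec_t[:frames],
            positions=rec_pos[:frames],
            velocities=rec_vel[:frames],
            energies=rec_en[:frames],
        )
    return traj, monitor, steps_done


def step(
    state: SimState,
    cfg: SimConfig,
    topo: DuplexTopology,
    params: ForceFieldParams | None = None,
) -> SimState:
    """One velocity-Verlet step; returns a new state (input untouched).

    Deterministic given ``(state, cfg)``: the noise stream is derived from
    ``cfg.seed`` and the state's kernel-invocation counter.
    """
    params = params or ForceFieldParams.default()
    out = state.copy()
    _run(out, cfg, topo, params, 1)
    return out


def run_segment(
    state: SimState,
    cfg: SimConfig,
    topo: DuplexTopology,
    params: ForceFieldParams | None = None,
    report_every: int = 1,
) -> tuple[Trajectory, SimState]:
    """Integrate ``cfg.n_steps`` steps, recording every ``report_every``
    steps (frame count = n_steps // report_every + 1, initial frame
    included).  Returns the trajectory and the final state."""
    if report_every < 1:
        raise ValueError("report_every must be >= 1")
    params = params or ForceFieldParams.default()
    out = state.copy()
    if cfg.n_steps == 0:
        # single-frame trajectory of the input state
        from .forcefield import energy_report

        rep = energy_report(out.conf, topo, params, cfg.T_target, cfg.I)
        en = np.array([[0.0, 0.0, 0.0, 0.0, rep.base_pairing, rep.excluded_volume,
                        rep.electrostatic, out.kinetic_energy(topo)]])
        en[0, 0] = rep.bonded  # lumped; per-term split not needed for n=0
        traj = Trajectory(
            times=np.array([out.time]),
            positions=out.conf.positions[None, :, :].copy(),
            velocities=out.velocities[None, :, :].copy(),
            energies=en,
        )
        return traj, out
    traj, _, _ = _run(out, cfg, topo, params, cfg.n_steps, record_every=report_every)
    return traj, out


def thermostat_update(
    state: SimState, cfg: SimConfig, topo: DuplexTopology
) -> SimState:
    """Advance only the Nosé-Hoover chain by half a time step (rescales the
    velocities); exposed for inspection and testing."""
    out = state.copy()
    q = _nh_masses(topo, cfg)
    _kernels.nh_chain_half_step(
        out.velocities, topo.masses, out.nh_vxi, out.nh_xi, q,
        KB * cfg.T_target, n_dof(topo, cfg), 0.5 * cfg.dt,
    )
    return out


def nh_conserved_quantity(
    state: SimState,
    cfg: SimConfig,
    topo: DuplexTopology,
    params: ForceFieldParams | None = None,
) -> float:
    """Augmented conserved quantity of the Nosé-Hoover chain (kJ/mol):
    H + Σ Q_k v_ξk²/2 + N_f kT ξ₁ + kT Σ_{k>1} ξ_k.  Conserved only when the
    Langevin friction/noise channel is off."""
    from .forcefield import total_energy

    params = params or ForceFieldParams.default()
    q = _nh_masses(topo, cfg)
    kt = KB * cfg.T_target
    nf = n_dof(topo, cfg)
    h = total_energy(state.conf, topo, params, cfg.T_target, cfg.I)
    h += state.kinetic_energy(topo)
    h += 0.5 * float(np.sum(q * state.nh_vxi**2))
    h += nf * kt * state.nh_xi[0] + kt * float(np.sum(state.nh_xi[1:]))
    return h


def minimize(
    conf: Configuration,
    topo: DuplexTopology,
    params: ForceFieldParams | None = None,
    n_steps: int = 2000,
    step_size: float = 0.02,
    T: float = ROOM_TEMPERATURE,
    I: float = 0.05,
    force_tol: float = 1e-6,
) -> Configuration:
    """Steepest-descent minimization of the total energy (electrostatics
    evaluated at ``T``, ``I``).  Energy never increases across accepted
    moves; raises if no downhill move can be found while far from a
    stationary point."""
    params = params or ForceFieldParams.default()
    tables = get_tables(topo, params)
    kappa = debye_length(T, I)
    pos = conf.positions.copy()
    e0 = _energy_of(pos, tables, kappa)
    e, it, fmax = _kernels.minimize_sd(
        pos, *tables.as_args(), kappa, n_steps, step_size, force_tol
    )
    if e > e0 + 1e-9:
        raise FloatingPointError(
            f"minimization diverged: energy rose from {e0:.6g} to {e:.6g} "
            f"after {it} iterations (max |F| = {fmax:.3g})"
        )
    return Configuration(pos)


def _energy_of(pos, tables, kappa) -> float:
    f = np.zeros_like(pos)
    comps = _kernels.eval_forces(pos, f, *tables.as_args(), kappa)
    return float(sum(comps))
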