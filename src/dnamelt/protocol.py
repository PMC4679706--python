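"""Temperature-jump melting protocol over replica ensembles.

Each replica runs minimize → thermostatted equilibration at room
temperature → instantaneous retarget of the thermostat to the jump
temperature (velocities kept) → production with on-the-fly dissociation
detection until every monitored basepair has dissociated or the time cap
is reached.  Replicas are statistically independent: each derives its own
noise streams from (master seed, replica id), so results do not depend on
execution order or batching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .analysis import DissociationRecord, DEFAULT_PERSISTENCE
from .constants import ROOM_TEMPERATURE
from .dynamics import SimConfig, SimState, _run, minimize, new_state
from .forcefield import get_tables
from .params import ForceFieldParams
from .topology import build_duplex, initial_coordinates
from . import fixtures

WALL_COMPLETED = "completed"
WALL_TIME_CAP = "hit_time_cap"
WALL_FAILED = "failed"


@dataclass(frozen=True)
class ProtocolSpec:
    """One melting experiment (sequence, jump temperature, salt, ensemble).

    Defaults are the desk-scale preset (20 replicas, 0.1 ns equilibration,
    2,000 minimization steps, 10 ns production cap); :func:`paper_preset`
    switches to the full-scale protocol (100 replicas, 1 ns equilibration,
    40,000 minimization steps).
    """

    sequence_name: str = "11bp"
    T_jump: float = 520.0          # K
    I: float = 0.05                # mol/L
    n_replicas: int = 20
    minimize_steps: int = 2000
    equil_time: float = 100.0      # ps
    max_production_time: float = 10000.0  # ps
    master_seed: int = 1
    dt: float = 0.01               # ps
    gamma: float = 0.05            # ps^-1
    room_T: float = ROOM_TEMPERATURE
    check_every: int = 100         # detection interval, steps
    persistence: int = DEFAULT_PERSISTENCE
    langevin_stride: int = 10      # noise application interval, steps

    def __post_init__(self) -> None:
        if self.T_jump <= 0:
            raise ValueError("T_jump must be positive")
        if self.max_production_time <= 0:
            raise ValueError("max_production_time must be positive")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")


def paper_preset(**overrides) -> ProtocolSpec:
    """Full-scale protocol: 100 replicas, 40,000 minimization steps, 1 ns
    equilibration."""
    base = dict(n_replicas=100, minimize_steps=40000, equil_time=1000.0)
    base.update(overrides)
    return ProtocolSpec(**base)


@dataclass
class ReplicaResult:
    replica_id: int
    dissociation: DissociationRecord
    melted_fully: bool
    wall_status: str
    production_time: float = 0.0   # ps actually integrated after the jump
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wall_status == WALL_COMPLETED and not self.melted_fully:
            raise ValueError("completed replica must be fully melted")


def _replica_seeds(master_seed: int, replica_id: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence([int(master_seed), int(replica_id)])
    s = ss.generate_state(3) % (2**31)
    return int(s[0]), int(s[1]), int(s[2])


def run_replica(
    spec: ProtocolSpec,
    replica_id: int,
    params: Optional[ForceFieldParams] = None,
) -> ReplicaResult:
    """Execute one replica of the melting protocol.

    Integrator blow-ups are captured in the result (``wall_status ==
    'failed'``) rather than raised, so ensembles never silently drop
    replicas.
    """
    params = params or ForceFieldParams.default()
    seq = fixtures.resolve_sequence(spec.sequence_name)
    topo = build_duplex(seq, params)
    vel_seed, equil_seed, prod_seed = _replica_seeds(spec.master_seed, replica_id)

    pairs = topo.monitored_pairs()
    positions = topo.pair_positions()
    classes = [c for _, _, c in pairs]
    nan_record = DissociationRecord(
        times=np.full(len(pairs), np.nan), positions=positions, pair_class=classes
    )

    try:
        conf = minimize(
            initial_coordinates(topo), topo, params,
            n_steps=spec.minimize_steps, T=spec.room_T, I=spec.I,
        )

        equil_cfg = SimConfig(
            dt=spec.dt, gamma=spec.gamma, T_target=spec.room_T, I=spec.I,
            seed=equil_seed, thermostat="nhl",
            langevin_stride=spec.langevin_stride,
        )
        state = new_state(topo, conf, equil_cfg, velocity_seed=vel_seed)
        n_equil = int(round(spec.equil_time / spec.dt))
        if n_equil > 0:
            _run(state, equil_cfg, topo, params, n_equil)

        # temperature jump: retarget thermostat and noise, keep velocities
        prod_cfg = replace(equil_cfg, T_target=spec.T_jump, seed=prod_seed)
        state.time = 0.0  # production clock starts at the jump
        monitor = {
            "a": np.array([p[0] for p in pairs], dtype=np.int64),
            "b": np.array([p[1] for p in pairs], dtype=np.int64),
            "thr": np.array([params.dissociation_threshold(c) for c in classes]),
            "consec": np.zeros(len(pairs), dtype=np.int64),
            "time": np.full(len(pairs), np.nan),
            "check_every": spec.check_every,
            "persist": spec.persistence,
            "stop_when_melted": True,
        }
        n_prod = int(round(spec.max_production_time / spec.dt))
        _run(state, prod_cfg, topo, params, n_prod, monitor=monitor)

        record = DissociationRecord(
            times=monitor["time"], positions=positions, pair_class=classes
        )
        melted = record.complete
        return ReplicaResult(
            replica_id=replica_id,
            dissociation=record,
            melted_fully=melted,
            wall_status=WALL_COMPLETED if melted else WALL_TIME_CAP,
            production_time=state.time,
        )
    except FloatingPointError as exc:
        return ReplicaResult(
            replica_id=replica_id,
            dissociation=nan_record,
            melted_fully=False,
            wall_status=WALL_FAILED,
            error=str(exc),
        )


def run_ensemble(
    spec: ProtocolSpec,
    params: Optional[ForceFieldParams] = None,
    progress: bool = False,
) -> List[ReplicaResult]:
    """Run ``spec.n_replicas`` independent replicas (serially).

    Partial failures are collected in the returned list, never raised.
    """
    params = params or ForceFieldParams.default()
    results = []
    for rid in range(spec.n_replicas):
        results.append(run_replica(spec, rid, params))
        if progress:
            r = results[-1]
            print(
                f"replica {rid}: {r.wall_status}, "
                f"t_prod = {r.production_time:.0f} ps", flush=True,
            )
    return results
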