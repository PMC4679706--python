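"""Study sequences, random duplex generation and scripted trajectories.

The scripted trajectories are event-structure test doubles for the
analysis stage: per-pair base-bead separations follow a below-threshold
baseline and then ramp monotonically outward through the class threshold
at a prescribed time, with velocities consistent with the finite
difference of the positions, so both detection pathways (velocity-based
and displacement-based) see the same events.  They do not emulate
force-field dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .dynamics import Trajectory
from .params import ForceFieldParams
from .sequence import Sequence, parse_sequence
from .topology import DuplexTopology

_STUDY = {
    "11bp": "ATC CGT ATG CG",
    "16bp": "ATC CGT ATG CGA TCC G",
    "21bp": "ATC CGT ATG CGA TCC GTA TGC",
    "26bp": "ATC CGT ATG CGA TCC GTA TGC GAT CC",
}


def study_sequences() -> Dict[str, Sequence]:
    """The four study duplexes (11/16/21/26 bp): the 11-bp asymmetric
    sequence and its whole- or half-repeat extensions."""
    return {k: parse_sequence(v, name=k) for k, v in _STUDY.items()}


def resolve_sequence(name_or_bases: str) -> Sequence:
    """Look up a study sequence by key, else parse the string as bases."""
    table = study_sequences()
    if name_or_bases in table:
        return table[name_or_bases]
    return parse_sequence(name_or_bases)


def random_duplex(n: int, at_fraction: float, seed: int) -> Sequence:
    """Random sequence of length ``n`` with expected A+T share
    ``at_fraction`` (each position drawn independently)."""
    if n < 2:
        raise ValueError("need at least 2 basepairs")
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    weak = rng.random(n) < at_fraction
    half = rng.random(n) < 0.5
    bases = np.where(weak, np.where(half, "A", "T"), np.where(half, "G", "C"))
    return Sequence("".join(bases), name=f"random_{n}bp_at{at_fraction:g}")


@dataclass(frozen=True)
class ScriptedEvent:
    """One scripted dissociation: monitored-pair position (1-based duplex
    coordinate) and the frame time at which the separation crosses the
    threshold."""

    position: int
    time: float          # ps
    ramp_time: float = 2.0   # ps over which the separation climbs
    speed: float = 0.5       # Å/ps outward speed after crossing

    def __post_init__(self) -> None:
        if self.time < 0 or not np.isfinite(self.time):
            raise ValueError("scripted time must be nonnegative and finite")


def scripted_trajectory(
    topo: DuplexTopology,
    events: List[ScriptedEvent],
    dt_frame: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: Optional[float] = None,
    params: Optional[ForceFieldParams] = None,
    tail: float = 5.0,
) -> Trajectory:
    """Trajectory whose monitored-pair separations encode known events.

    Scripted pairs sit at the native separation, then move apart linearly
    so that the first frame at or after ``event.time`` lies just above the
    class threshold; non-scripted pairs stay at baseline throughout.
    Gaussian jitter of ``noise_sd`` Å is added to the scripted separations.
    """
    params = params or ForceFieldParams.default()
    pairs = topo.monitored_pairs()
    positions = topo.pair_positions()
    pos_to_row = {int(p): k for k, p in enumerate(positions)}
    for ev in events:
        if ev.position not in pos_to_row:
            raise ValueError(f"no monitored pair at position {ev.position}")

    t_end = duration
    if t_end is None:
        t_end = (max((ev.time for ev in events), default=0.0) + tail)
    for ev in events:
        if ev.time > t_end:
            raise ValueError(
                f"scripted time {ev.time} ps beyond trajectory span {t_end} ps"
            )

    n_frames = int(np.floor(t_end / dt_frame)) + 1
    times = np.arange(n_frames) * dt_frame
    rng = np.random.default_rng(seed)

    ref = topo.reference_positions
    pos = np.repeat(ref[None, :, :], n_frames, axis=0)
    vel = np.zeros_like(pos)

    for ev in events:
        row = pos_to_row[ev.position]
        a, b, cls = pairs[row]
        thr = params.dissociation_threshold(cls)
        d0 = float(np.linalg.norm(ref[a] - ref[b]))
        u = (ref[a] - ref[b]) / d0
        # separation profile: baseline, linear ramp that sits just above the
        # threshold at the first frame >= ev.time, then steady outward drift
        margin = 0.5 * ev.speed * dt_frame
        sep = np.empty(n_frames)
        for f, t in enumerate(times):
            if t < ev.time - ev.ramp_time:
                sep[f] = d0
            elif t < ev.time:
                frac = (t - (ev.time - ev.ramp_time)) / ev.ramp_time
                sep[f] = d0 + frac * (thr + margin - d0)
            else:
                sep[f] = thr + margin + ev.speed * (t - ev.time)
        if noise_sd > 0:
            sep = sep + rng.normal(0.0, noise_sd, n_frames)
        # velocities from the forward difference of the separation
        dsep = np.empty(n_frames)
        dsep[:-1] = np.diff(sep) / dt_frame
        dsep[-1] = dsep[-2]
        half = 0.5 * (sep - d0)
        pos[:, a, :] = ref[a] + np.outer(half, u)
        pos[:, b, :] = ref[b] - np.outer(half, u)
        vel[:, a, :] = np.outer(0.5 * dsep, u)
        vel[:, b, :] = np.outer(-0.5 * dsep, u)

    return Trajectory(times=times, positions=pos, velocities=vel)
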