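"""Melting-event detection and ensemble observables.

A monitored basepair counts as dissociated at the first stored frame where
its base-base separation exceeds the class threshold (G-C 2.8694 Å,
A-T 2.9002 Å by default) *and* the two base beads move apart (positive
radial relative velocity), with both conditions holding for a persistence
window of consecutive frames (debouncing against thermal recrossing).
Events are first-passage: once recorded they are final.

Observables follow the plotting convention that the first dissociation in
each replica defines time zero: the melting duration is the time between
the first and last dissociation, the interval series Δt lists gaps between
rank-adjacent dissociations, the order curve gives mean zeroed time versus
number of dissociated pairs, and the position curve gives the mean zeroed
dissociation time of each basepair along the duplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .params import ForceFieldParams
from .topology import DuplexTopology
from .dynamics import Trajectory

OPEN_AT_END = "AT_end"
OPEN_GC_END = "GC_end"
OPEN_BOTH = "both"

DEFAULT_PERSISTENCE = 3


@dataclass
class DissociationRecord:
    """First-passage dissociation times of the monitored pairs of one replica.

    ``times`` are in ps on the trajectory clock (NaN = never dissociated);
    ``positions`` is the duplex coordinate of each monitored pair
    (1 = nearest the 5' end of strand 1); ``pair_class`` is "AT" or "GC".
    """

    times: np.ndarray
    positions: np.ndarray
    pair_class: List[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if len(self.times) != len(self.positions) or len(self.times) != len(self.pair_class):
            raise ValueError("inconsistent record lengths")
        if np.any(self.times[np.isfinite(self.times)] < 0):
            raise ValueError("dissociation times must be nonnegative")

    @property
    def n_pairs(self) -> int:
        return len(self.times)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.times)))

    def dissociated_positions(self) -> np.ndarray:
        return self.positions[np.isfinite(self.times)]


class IncompleteMeltingError(ValueError):
    """Raised when an observable requires a fully melted record."""


def detect_events(
    traj: Trajectory,
    topo: DuplexTopology,
    params: Optional[ForceFieldParams] = None,
    persistence: int = DEFAULT_PERSISTENCE,
    thresholds: Optional[np.ndarray] = None,
) -> DissociationRecord:
    """Scan a stored trajectory for basepair dissociation events.

    Velocities are used for the opposite-motion clause when the trajectory
    carries them; otherwise the forward difference of the separation serves
    as the radial-velocity sign (requires ≥ 2 frames).
    """
    params = params or ForceFieldParams.default()
    pairs = topo.monitored_pairs()
    a_idx = np.array([p[0] for p in pairs])
    b_idx = np.array([p[1] for p in pairs])
    if thresholds is None:
        thresholds = np.array(
            [params.dissociation_threshold(c) for _, _, c in pairs]
        )
    has_vel = traj.velocities is not None
    if not has_vel and traj.n_frames < 2:
        raise ValueError(
            "trajectory carries no velocities and has < 2 frames; "
            "cannot evaluate the opposite-motion clause"
        )

    rel = traj.positions[:, a_idx, :] - traj.positions[:, b_idx, :]  # (F, M, 3)
    dist = np.linalg.norm(rel, axis=2)
    if has_vel:
        dvel = traj.velocities[:, a_idx, :] - traj.velocities[:, b_idx, :]
        radial = np.einsum("fmd,fmd->fm", dvel, rel)  # sign of d(dist)/dt
    else:
        radial = np.empty_like(dist)
        radial[:-1] = np.diff(dist, axis=0)
        radial[-1] = radial[-2]

    open_now = (dist > thresholds[None, :]) & (radial > 0.0)
    n_pairs = len(pairs)
    times = np.full(n_pairs, np.nan)
    for m in range(n_pairs):
        run = 0
        for fidx in range(traj.n_frames):
            if open_now[fidx, m]:
                run += 1
                if run >= persistence:
                    times[m] = traj.times[fidx - persistence + 1]
                    break
            else:
                run = 0
    return DissociationRecord(
        times=times,
        positions=topo.pair_positions(),
        pair_class=[c for _, _, c in pairs],
    )


def melting_duration(rec: DissociationRecord) -> float:
    """Time between the first and the last dissociation (ps).

    With the first event defining time zero this is simply the last zeroed
    event time; the value is invariant under a common time offset.
    """
    if not rec.complete:
        missing = rec.positions[~np.isfinite(rec.times)]
        raise IncompleteMeltingError(
            f"melting incomplete: pairs at positions {missing.tolist()} never dissociated"
        )
    return float(rec.times.max() - rec.times.min())


def interval_series(rec: DissociationRecord) -> np.ndarray:
    """Gaps Δt between rank-adjacent dissociations; sums to the duration."""
    if not rec.complete:
        raise IncompleteMeltingError("interval series requires a fully melted record")
    return np.diff(np.sort(rec.times))


def order_curve(records: Iterable[DissociationRecord]) -> pd.DataFrame:
    """Mean (and sd) zeroed dissociation time versus number of dissociated
    pairs N_p, over fully melted replicas."""
    recs = [r for r in records if r.complete]
    if not recs:
        raise ValueError("no fully melted replicas")
    zeroed = np.stack([np.sort(r.times) - r.times.min() for r in recs])
    return pd.DataFrame(
        {
            "n_dissociated": np.arange(1, zeroed.shape[1] + 1),
            "mean_time": zeroed.mean(axis=0),
            "sd_time": zeroed.std(axis=0, ddof=0),
        }
    )


def position_curve(
    records: Iterable[DissociationRecord], topo: DuplexTopology
) -> pd.DataFrame:
    """Mean zeroed dissociation time of the basepair at each duplex position
    n_p; reveals which end of the chain opens early."""
    recs = [r for r in records if r.complete]
    if not recs:
        raise ValueError("no fully melted replicas")
    zeroed = np.stack([r.times - r.times.min() for r in recs])
    positions = recs[0].positions
    return pd.DataFrame(
        {
            "position": positions,
            "pair_class": recs[0].pair_class,
            "mean_time": zeroed.mean(axis=0),
            "sd_time": zeroed.std(axis=0, ddof=0),
        }
    )


def at_rich_end(topo: DuplexTopology, k_window: int) -> str:
    """Which duplex end is A-T-rich: "5p" (position 1 side) or "3p".

    Compares the A/T content of the terminal ``k_window`` monitored pairs
    at each end; ties are broken by the distance of the nearest A-T pair to
    each end (fraying starts at the terminus, so proximity wins).
    """
    classes = [c for _, _, c in topo.monitored_pairs()]
    n = len(classes)
    if k_window > n // 2:
        raise ValueError("k_window larger than half the monitored pair count")
    left = classes[:k_window]
    right = classes[-k_window:]
    n_left = sum(c == "AT" for c in left)
    n_right = sum(c == "AT" for c in right)
    if n_left != n_right:
        return "5p" if n_left > n_right else "3p"
    # tie-break: distance of the nearest AT pair to the terminus
    d_left = next((i for i, c in enumerate(classes) if c == "AT"), n)
    d_right = next((i for i, c in enumerate(reversed(classes)) if c == "AT"), n)
    return "5p" if d_left <= d_right else "3p"


def classify_opening(
    rec: DissociationRecord, topo: DuplexTopology, k_window: int = 3
) -> str:
    """Opening-end class of one replica from its first ``k_window`` events.

    ``AT_end``: all of the first ``k_window`` dissociations fall in the
    terminal window at the A-T-rich end; ``GC_end``: all in the window at
    the opposite end; ``both`` otherwise.
    """
    if not rec.complete:
        raise IncompleteMeltingError("classification requires a fully melted record")
    n = rec.n_pairs
    if k_window > n // 2:
        raise ValueError("k_window larger than half the monitored pair count")
    order = rec.positions[np.argsort(rec.times)]
    first = set(order[:k_window].tolist())
    low = set(range(1, k_window + 1))
    high = set(range(n - k_window + 1, n + 1))
    at_side = at_rich_end(topo, k_window)
    at_window, gc_window = (low, high) if at_side == "5p" else (high, low)
    if first <= at_window:
        return OPEN_AT_END
    if first <= gc_window:
        return OPEN_GC_END
    return OPEN_BOTH


def opening_fractions(
    records: Iterable[DissociationRecord], topo: DuplexTopology, k_window: int = 3
) -> dict:
    recs = [r for r in records if r.complete]
    if not recs:
        raise ValueError("no fully melted replicas")
    labels = [classify_opening(r, topo, k_window) for r in recs]
    n = len(labels)
    return {
        OPEN_AT_END: labels.count(OPEN_AT_END) / n,
        OPEN_GC_END: labels.count(OPEN_GC_END) / n,
        OPEN_BOTH: labels.count(OPEN_BOTH) / n,
    }


@dataclass
class EnsembleSummary:
    """Replica-averaged melting observables."""

    n_replicas: int
    n_complete: int
    duration_mean: float
    duration_sd: float
    order: pd.DataFrame
    intervals: pd.DataFrame       # mean Δt per dissociation rank
    position: pd.DataFrame
    opening: dict                 # fractions, sum to 1

    def as_dict(self) -> dict:
        return {
            "n_replicas": self.n_replicas,
            "n_complete": self.n_complete,
            "duration_mean_ps": self.duration_mean,
            "duration_sd_ps": self.duration_sd,
            "opening_fractions": self.opening,
        }


def summarize_ensemble(
    records: TypingSequence[DissociationRecord],
    topo: DuplexTopology,
    k_window: int = 3,
) -> EnsembleSummary:
    """Aggregate an ensemble of replicas (means over fully melted replicas;
    incomplete replicas are counted but excluded from the averages)."""
    records = list(records)
    complete = [r for r in records if r.complete]
    if not complete:
        raise ValueError("no fully melted replicas to summarize")
    durations = np.array([melting_duration(r) for r in complete])
    ivals = np.stack([interval_series(r) for r in complete])
    intervals = pd.DataFrame(
        {
            "rank": np.arange(1, ivals.shape[1] + 1),
            "mean_dt": ivals.mean(axis=0),
            "sd_dt": ivals.std(axis=0, ddof=0),
        }
    )
    return EnsembleSummary(
        n_replicas=len(records),
        n_complete=len(complete),
        duration_mean=float(durations.mean()),
        duration_sd=float(durations.std(ddof=0)),
        order=order_curve(complete),
        intervals=intervals,
        position=position_curve(complete, topo),
        opening=opening_fractions(complete, topo, k_window),
    )


def records_to_frame(records: TypingSequence[DissociationRecord]) -> pd.DataFrame:
    """Tidy table: one row per (replica, monitored pair) event."""
    rows = []
    for rid, rec in enumerate(records):
        for pos, cls, t in zip(rec.positions, rec.pair_class, rec.times):
            rows.append(
                {
                    "replica": rid,
                    "position": int(pos),
                    "pair_class": cls,
                    "time_ps": float(t),
                }
            )
    return pd.DataFrame(rows)
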