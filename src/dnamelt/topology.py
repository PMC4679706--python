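"""Duplex topology and ideal B-form coordinates.

Each nucleotide is represented by three beads -- phosphate (P), sugar (S)
and base (B) -- with the 5'-terminal residue of each strand lacking its
phosphate, giving ``3N - 1`` beads per strand for ``N`` bases.  Strand 1 is
built as a right-handed helix (36° twist, 3.38 Å rise per residue by
default); strand 2 is obtained by the rotate-and-shift rule: a 180°
rotation about an axis perpendicular to the helix axis (which reverses the
chain direction, making the strands antiparallel, while preserving
chirality) followed by a rotation about the helix axis and an upward shift
chosen so that every base faces its Watson-Crick partner across the axis.

Bead labeling convention: beads of strand 1 carry odd labels, beads of
strand 2 even labels; within each strand labels increase from the 5' end,
and within a residue the order is phosphate (when present, it is the
5'-most site), then base, then sugar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .params import ForceFieldParams, HelixGeometry
from .sequence import Sequence, complement

KIND_PHOSPHATE = "phosphate"
KIND_SUGAR = "sugar"
KIND_BASE = "base"


@dataclass(frozen=True)
class Bead:
    kind: str                 # phosphate | sugar | base
    base_id: Optional[str]    # A/C/G/T for base beads, None otherwise
    strand: int               # 1 or 2
    label: int                # odd on strand 1, even on strand 2
    mass: float               # amu
    charge: float             # elementary charges

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")
        if self.kind == KIND_PHOSPHATE and self.charge != -1.0:
            raise ValueError("phosphate bead must carry charge -1 e")
        if self.label % 2 != (1 if self.strand == 1 else 0):
            raise ValueError("label parity must match strand")


@dataclass
class Configuration:
    """Per-bead positions in Å (isolated chain, no box)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy())


@dataclass
class DuplexTopology:
    """Connectivity, native contacts and basepair bookkeeping of one duplex."""

    sequence: Sequence
    beads: List[Bead]
    bonds: np.ndarray            # (nb, 2) bead indices
    bond_classes: List[str]
    angles: np.ndarray           # (na, 3)
    angle_classes: List[str]
    dihedrals: np.ndarray        # (nd, 4)
    dihedral_classes: List[str]
    native_contacts: np.ndarray  # (ns, 2) intra-strand stacking pairs
    basepairs: List[Tuple[int, int, str]]  # (base bead s1, base bead s2, AT|GC)
    monitored: List[int]         # indices into basepairs
    reference_positions: np.ndarray
    geometry: HelixGeometry
    base_index_s1: np.ndarray = field(repr=False, default=None)  # residue -> bead
    base_index_s2: np.ndarray = field(repr=False, default=None)

    # -- array views used by the force kernels -------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    @property
    def phosphate_indices(self) -> np.ndarray:
        return np.array(
            [i for i, b in enumerate(self.beads) if b.kind == KIND_PHOSPHATE],
            dtype=np.int64,
        )

    def monitored_pairs(self) -> List[Tuple[int, int, str]]:
        return [self.basepairs[k] for k in self.monitored]

    def pair_positions(self) -> np.ndarray:
        """Duplex coordinate of each monitored pair, 1 = nearest the 5' end
        of strand 1 among monitored pairs."""
        return np.arange(1, len(self.monitored) + 1)


def _strand_sites(n: int, geo: HelixGeometry) -> dict:
    """Ideal helical coordinates of one strand laid along +z, 5' at z=0."""
    i = np.arange(n)
    theta = i * geo.twist
    z = i * geo.rise

    def ring(radius, dtheta, dz):
        return np.stack(
            [radius * np.cos(theta + dtheta), radius * np.sin(theta + dtheta), z + dz],
            axis=1,
        )

    return {
        "base": ring(geo.r_base, 0.0, 0.0),
        "sugar": ring(geo.r_sugar, geo.sugar_angle, 0.0),
        "phosphate": ring(geo.r_phosphate, geo.phosphate_angle, geo.phosphate_dz),
    }


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_duplex(
    seq: Sequence,
    params: Optional[ForceFieldParams] = None,
    geometry: Optional[HelixGeometry] = None,
) -> DuplexTopology:
    """Construct the two-strand three-site topology for ``seq``.

    Deterministic: identical inputs give identical topologies.  The
    complementary strand is generated internally; basepair ``k`` joins
    residue ``k`` of strand 1 (0-based, 5'→3') with its partner on strand 2.
    The first nucleotide of each strand (one residue at each duplex end) is
    excluded from the monitored basepair list, leaving ``N - 2`` monitored
    pairs.
    """
    params = params or ForceFieldParams.default()
    geo = geometry or params.geometry
    n = len(seq)
    if n < 2:
        raise ValueError("duplex needs at least 2 basepairs")
    strand2_seq = complement(seq)

    beads: List[Bead] = []
    base_idx = np.zeros((2, n), dtype=np.int64)
    sugar_idx = np.zeros((2, n), dtype=np.int64)
    phos_idx = -np.ones((2, n), dtype=np.int64)

    for s, bases in enumerate((seq.bases, strand2_seq.bases)):
        in_strand = 0  # per-strand running index; labels 2k+1 / 2k+2

        def label() -> int:
            nonlocal in_strand
            k = in_strand
            in_strand += 1
            return 2 * k + 1 if s == 0 else 2 * k + 2

        for i, b in enumerate(bases):
            if i > 0:
                phos_idx[s, i] = len(beads)
                beads.append(
                    Bead(KIND_PHOSPHATE, None, s + 1, label(), params.masses["phosphate"], -1.0)
                )
            base_idx[s, i] = len(beads)
            beads.append(Bead(KIND_BASE, b, s + 1, label(), params.masses[b], 0.0))
            sugar_idx[s, i] = len(beads)
            beads.append(Bead(KIND_SUGAR, None, s + 1, label(), params.masses["sugar"], 0.0))

    bonds, bond_classes = [], []
    angles, angle_classes = [], []
    dihedrals, dihedral_classes = [], []
    for s in range(2):
        B, S, P = base_idx[s], sugar_idx[s], phos_idx[s]
        for i in range(n):
            bonds.append((S[i], B[i])); bond_classes.append("SB")
            if i > 0:
                bonds.append((S[i - 1], P[i])); bond_classes.append("S3P")
                bonds.append((P[i], S[i])); bond_classes.append("PS5")
                angles.append((S[i - 1], P[i], S[i])); angle_classes.append("SPS")
                angles.append((B[i], S[i], P[i])); angle_classes.append("BSP5")
                angles.append((B[i - 1], S[i - 1], P[i])); angle_classes.append("BSP3")
            if 0 < i < n - 1:
                angles.append((P[i], S[i], P[i + 1])); angle_classes.append("PSP")
            if 0 < i < n - 1:
                dihedrals.append((S[i - 1], P[i], S[i], P[i + 1])); dihedral_classes.append("SPSP")
            if 0 < i and i + 1 < n:
                dihedrals.append((P[i], S[i], P[i + 1], S[i + 1])); dihedral_classes.append("PSPS")

    native_contacts = []
    for s in range(2):
        for i in range(n - 1):
            native_contacts.append((base_idx[s, i], base_idx[s, i + 1]))

    basepairs = []
    for i in range(n):
        j = n - 1 - i  # antiparallel partner residue on strand 2
        cls = "AT" if seq.bases[i] in "AT" else "GC"
        basepairs.append((int(base_idx[0, i]), int(base_idx[1, j]), cls))
    monitored = list(range(1, n - 1))

    # --- coordinates --------------------------------------------------------
    sites = _strand_sites(n, geo)
    ref = np.zeros((len(beads), 3))
    for i in range(n):
        ref[base_idx[0, i]] = sites["base"][i]
        ref[sugar_idx[0, i]] = sites["sugar"][i]
        if i > 0:
            ref[phos_idx[0, i]] = sites["phosphate"][i]
    # strand 2: rotate 180° about x (reverses direction, keeps chirality),
    # then align about z so bases face their partners, then shift up.
    flip = np.diag([1.0, -1.0, -1.0])
    chi = np.pi + (n - 1) * geo.twist
    rot = _rot_z(chi) @ flip
    shift = np.array([0.0, 0.0, (n - 1) * geo.rise])
    for i in range(n):
        ref[base_idx[1, i]] = rot @ sites["base"][i] + shift
        ref[sugar_idx[1, i]] = rot @ sites["sugar"][i] + shift
        if i > 0:
            ref[phos_idx[1, i]] = rot @ sites["phosphate"][i] + shift

    topo = DuplexTopology(
        sequence=seq,
        beads=beads,
        bonds=np.array(bonds, dtype=np.int64),
        bond_classes=bond_classes,
        angles=np.array(angles, dtype=np.int64),
        angle_classes=angle_classes,
        dihedrals=np.array(dihedrals, dtype=np.int64),
        dihedral_classes=dihedral_classes,
        native_contacts=np.array(native_contacts, dtype=np.int64),
        basepairs=basepairs,
        monitored=monitored,
        reference_positions=ref,
        geometry=geo,
        base_index_s1=base_idx[0].copy(),
        base_index_s2=base_idx[1].copy(),
    )
    _check_geometry(topo)
    return topo


def _check_geometry(topo: DuplexTopology) -> None:
    pos = topo.reference_positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 1.0:
        raise ValueError(
            f"reference geometry places beads {np.unravel_index(d.argmin(), d.shape)} "
            f"only {d.min():.2f} Å apart"
        )


def initial_coordinates(topo: DuplexTopology) -> Configuration:
    """Ideal B-form starting configuration (all basepairs hybridized)."""
    return Configuration(topo.reference_positions.copy())


def axis_extent(topo: DuplexTopology) -> float:
    """Helix-axis length of the duplex: (N-1) rise steps between residues."""
    return (topo.n_bp - 1) * topo.geometry.rise


def topology_to_json(topo: DuplexTopology, path: str | Path | None = None) -> str:
    """Dump beads, indices and labels as JSON for inspection."""
    doc = {
        "sequence": topo.sequence.bases,
        "n_beads": topo.n_beads,
        "beads": [
            {
                "kind": b.kind,
                "base": b.base_id,
                "strand": b.strand,
                "label": b.label,
                "mass": b.mass,
                "charge": b.charge,
            }
            for b in topo.beads
        ],
        "bonds": topo.bonds.tolist(),
        "bond_classes": topo.bond_classes,
        "angles": topo.angles.tolist(),
        "dihedrals": topo.dihedrals.tolist(),
        "native_contacts": topo.native_contacts.tolist(),
        "basepairs": [[i, j, c] for i, j, c in topo.basepairs],
        "monitored": topo.monitored,
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text
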