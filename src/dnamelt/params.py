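"""Force-field parameter table.

All numbers live in a versioned YAML file so an alternative
parameterization can be swapped in without touching any logic; the code
only fixes the functional forms.  Equilibrium values of the bonded terms
are not stored here: they are measured from the ideal B-form reference
structure when the interaction tables are built (Gō convention), which
makes the built helix an exact minimum of the bonded energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict

import yaml

_REQUIRED_SECTIONS = (
    "masses",
    "charges",
    "bonds",
    "angles",
    "dihedrals",
    "stacking",
    "base_pair",
    "excluded_volume",
    "electrostatics",
    "dissociation",
    "geometry",
)

BOND_CLASSES = ("SB", "S3P", "PS5")
ANGLE_CLASSES = ("SPS", "PSP", "BSP5", "BSP3")
DIHEDRAL_CLASSES = ("SPSP", "PSPS")


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal B-form construction constants (twist/rise and site placement)."""

    twist_deg: float = 36.0
    rise: float = 3.38
    r_base: float = 1.0
    r_sugar: float = 6.9
    r_phosphate: float = 8.9
    sugar_angle: float = -0.30
    phosphate_angle: float = -0.60
    phosphate_dz: float = -1.69

    @property
    def twist(self) -> float:
        import math

        return math.radians(self.twist_deg)


@dataclass(frozen=True)
class ForceFieldParams:
    """Validated view of one parameter table."""

    version: int
    masses: Dict[str, float]
    charges: Dict[str, float]
    bonds: Dict[str, Dict[str, float]]
    angles: Dict[str, Dict[str, float]]
    dihedrals: Dict[str, Dict[str, float]]
    stacking_eps: float
    eps_AT: float
    eps_GC: float
    sigma_AT: float
    sigma_GC: float
    bp_alpha: float
    bp_cross_eps: float
    ev_eps: float
    ev_sigma: float
    ev_cutoff_factor: float
    relative_permittivity: float
    diss_threshold_AT: float
    diss_threshold_GC: float
    diss_mode: str
    geometry: HelixGeometry = field(default_factory=HelixGeometry)

    def __post_init__(self) -> None:
        if self.eps_GC <= self.eps_AT:
            raise ValueError(
                "eps_GC must exceed eps_AT (three vs two hydrogen bonds)"
            )
        for name in ("eps_AT", "eps_GC", "sigma_AT", "sigma_GC", "bp_alpha",
                     "ev_eps", "ev_sigma", "stacking_eps",
                     "relative_permittivity", "diss_threshold_AT",
                     "diss_threshold_GC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diss_mode not in ("absolute", "offset"):
            raise ValueError("dissociation mode must be 'absolute' or 'offset'")
        for kind in ("phosphate", "sugar", "A", "C", "G", "T"):
            if self.masses.get(kind, 0.0) <= 0:
                raise ValueError(f"mass for {kind} must be positive")
        if self.charges.get("phosphate") != -1.0:
            raise ValueError("phosphate charge must be exactly -1 e")
        for cls in BOND_CLASSES:
            if cls not in self.bonds:
                raise ValueError(f"missing bond class {cls}")
        for cls in ANGLE_CLASSES:
            if cls not in self.angles:
                raise ValueError(f"missing angle class {cls}")
        for cls in DIHEDRAL_CLASSES:
            if cls not in self.dihedrals:
                raise ValueError(f"missing dihedral class {cls}")

    def dissociation_threshold(self, pair_class: str) -> float:
        """Per-class separation beyond which a basepair counts as dissociated.

        In ``absolute`` mode the tabulated value is the threshold itself; in
        ``offset`` mode it is added to the native contact distance.
        """
        raw = self.diss_threshold_AT if pair_class == "AT" else self.diss_threshold_GC
        if self.diss_mode == "absolute":
            return raw
        sigma = self.sigma_AT if pair_class == "AT" else self.sigma_GC
        return sigma + raw

    @classmethod
    def from_dict(cls, data: dict) -> "ForceFieldParams":
        missing = [s for s in _REQUIRED_SECTIONS if s not in data]
        if missing:
            raise ValueError(f"parameter table missing sections: {missing}")
        bp = data["base_pair"]
        ev = data["excluded_volume"]
        diss = data["dissociation"]
        return cls(
            version=int(data.get("version", 0)),
            masses={k: float(v) for k, v in data["masses"].items()},
            charges={k: float(v) for k, v in data["charges"].items()},
            bonds={k: dict(v) for k, v in data["bonds"].items()},
            angles={k: dict(v) for k, v in data["angles"].items()},
            dihedrals={k: dict(v) for k, v in data["dihedrals"].items()},
            stacking_eps=float(data["stacking"]["eps"]),
            eps_AT=float(bp["eps_AT"]),
            eps_GC=float(bp["eps_GC"]),
            sigma_AT=float(bp["sigma_AT"]),
            sigma_GC=float(bp["sigma_GC"]),
            bp_alpha=float(bp["alpha"]),
            bp_cross_eps=float(bp.get("cross_eps", 0.0)),
            ev_eps=float(ev["eps"]),
            ev_sigma=float(ev["sigma"]),
            ev_cutoff_factor=float(ev.get("cutoff_factor", 3.0)),
            relative_permittivity=float(
                data["electrostatics"]["relative_permittivity"]
            ),
            diss_threshold_AT=float(diss["threshold_AT"]),
            diss_threshold_GC=float(diss["threshold_GC"]),
            diss_mode=str(diss.get("mode", "absolute")),
            geometry=HelixGeometry(**{k: float(v) for k, v in data["geometry"].items()}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ForceFieldParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ForceFieldParams":
        global _DEFAULT
        if _DEFAULT is None:
            text = (
                resources.files("dnamelt") / "parameters" / "default.yaml"
            ).read_text()
            _DEFAULT = cls.from_dict(yaml.safe_load(text))
        return _DEFAULT


_DEFAULT: ForceFieldParams | None = None
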