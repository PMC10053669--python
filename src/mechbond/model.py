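"""Core domain types: atoms, structures, trajectories and selections.

Conventions
-----------
* Residue numbering is author (PDB) numbering, 1-based; all residue ranges
  are inclusive on both ends, matching how structural papers quote them
  (e.g. "residues 19th–241st").
* Units: coordinates in Å, time in ns, force in pN, energies in kcal/mol.
* Atom iteration order is file order and is preserved everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MechbondError",
    "FormatError",
    "TopologyError",
    "SelectionError",
    "ParameterError",
    "MissingHydrogenError",
    "ConfigError",
    "FitError",
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "select",
]


class MechbondError(Exception):
    """Base class for all package errors."""


class FormatError(MechbondError):
    """A file did not parse; the message names the offending line or frame."""


class TopologyError(MechbondError):
    """Trajectory frames are inconsistent with the supplied topology."""


class SelectionError(MechbondError):
    """An atom selection is empty or refers outside its structure."""


class ParameterError(MechbondError):
    """Required per-atom parameters (radius, charge, LJ) are missing."""


class MissingHydrogenError(MechbondError):
    """Hydrogen-bond detection was asked to run on a hydrogen-free structure."""


class ConfigError(MechbondError):
    """A run configuration is internally inconsistent."""


class FitError(MechbondError):
    """A model fit failed to converge; carries a moment-based fallback."""

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


@dataclass
class Atom:
    """One atom with optional nonbonded parameters.

    ``charge`` is in elementary charges, ``lj_epsilon`` in kcal/mol and
    ``lj_rmin_half`` in Å (the Lorentz–Berthelot half-minimum convention).
    """

    serial: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    charge: Optional[float] = None
    lj_epsilon: Optional[float] = None
    lj_rmin_half: Optional[float] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be length-3")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if self.residue_seq <= 0:
            raise ValueError(f"atom {self.serial}: residue_seq must be positive")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


class Structure:
    """An ordered collection of atoms grouped into chains.

    Invariants: ``(chain_id, residue_seq, name)`` triples are unique and
    iteration order is file order.
    """

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise FormatError("structure contains no atoms")
        self.atoms: list[Atom] = list(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.name)
            if key in seen:
                raise FormatError(
                    f"duplicate atom {a.name} in residue {a.chain_id}:{a.residue_seq}"
                )
            seen.add(key)
        self._coords = np.array([a.position for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order (Å)."""
        return self._coords

    @property
    def chains(self) -> dict[str, tuple[int, int]]:
        """Map chain id → inclusive (min, max) residue range."""
        out: dict[str, tuple[int, int]] = {}
        for a in self.atoms:
            lo, hi = out.get(a.chain_id, (a.residue_seq, a.residue_seq))
            out[a.chain_id] = (min(lo, a.residue_seq), max(hi, a.residue_seq))
        return out

    def atom_index(self, chain_id: str, residue_seq: int, name: str) -> int:
        """Index of a uniquely named atom; raises ``SelectionError`` if absent."""
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_seq == residue_seq
                and a.name == name
            ):
                return i
        raise SelectionError(f"no atom {name} in residue {chain_id}:{residue_seq}")

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self)} topology atoms"
            )
        atoms = []
        for a, p in zip(self.atoms, coords):
            atoms.append(
                Atom(
                    a.serial,
                    a.name,
                    a.element,
                    a.residue_seq,
                    a.residue_name,
                    a.chain_id,
                    p.copy(),
                    a.charge,
                    a.lj_epsilon,
                    a.lj_rmin_half,
                )
            )
        return Structure(atoms)


class Trajectory:
    """Frame-ordered coordinates bound to one :class:`Structure` topology.

    ``frames`` is an (n_frames, n_atoms, 3) array in Å. ``times`` (ns) must be
    strictly increasing when present; ``applied_force`` (pN) is one value per
    frame when present.
    """

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray,
        times: Optional[np.ndarray] = None,
        applied_force: Optional[np.ndarray] = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise TopologyError(
                f"frame array of shape {frames.shape} does not match a "
                f"{len(topology)}-atom topology"
            )
        if frames.shape[0] == 0:
            raise TopologyError("trajectory must contain at least one frame")
        self.topology = topology
        self.frames = frames
        if times is not None:
            times = np.asarray(times, dtype=float)
            if times.shape != (len(frames),):
                raise TopologyError("times must have one entry per frame")
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise TopologyError("frame times must be strictly increasing")
        self.times = times
        if applied_force is not None:
            applied_force = np.asarray(applied_force, dtype=float)
            if applied_force.shape != (len(frames),):
                raise TopologyError("applied_force must have one entry per frame")
        self.applied_force = applied_force

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class Selection:
    """A non-empty set of atom indices on one structure, with a label."""

    structure: Structure
    indices: tuple[int, ...]
    label: str

    def __post_init__(self):
        if len(self.indices) == 0:
            raise SelectionError(f"empty selection: {self.label!r}")
        n = len(self.structure)
        if min(self.indices) < 0 or max(self.indices) >= n:
            raise SelectionError(
                f"selection {self.label!r} has indices outside the structure"
            )
        object.__setattr__(self, "indices", tuple(sorted(set(self.indices))))

    def __len__(self) -> int:
        return len(self.indices)

    def atoms(self) -> Iterable[Atom]:
        for i in self.indices:
            yield self.structure.atoms[i]

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def isdisjoint(self, other: "Selection") -> bool:
        return set(self.indices).isdisjoint(other.indices)


def select(
    structure: Structure,
    chain: str,
    residue_range: tuple[int, int],
    names: Optional[set[str]] = None,
) -> Selection:
    """Select atoms of one chain within an inclusive author-numbered range.

    Parameters
    ----------
    names:
        optional atom-name filter (e.g. ``{"CA"}`` for a Cα-only selection).

    Raises
    ------
    SelectionError
        if the result is empty — deliberate, to prevent silent off-by-one
        mistakes on author numbering (a residue absent from a truncated
        construct must fail loudly, not vanish).
    """
    lo, hi = residue_range
    if hi < lo:
        raise SelectionError(f"empty residue range [{lo}, {hi}]")
    idx = [
        i
        for i, a in enumerate(structure.atoms)
        if a.chain_id == chain
        and lo <= a.residue_seq <= hi
        and (names is None or a.name in names)
    ]
    label = f"chain {chain} residues {lo}-{hi}" + (
        f" names {sorted(names)}" if names else ""
    )
    if not idx:
        raise SelectionError(f"empty selection: {label}")
    return Selection(structure, tuple(idx), label)
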