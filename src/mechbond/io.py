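"""Structure, trajectory and report I/O.

PDB
---
Fixed-column ``ATOM``/``HETATM`` records are read with author residue
numbering preserved. Alternate locations other than blank/'A' are dropped
(keep-first policy); insertion codes are rejected with a clear error because
every downstream selection is keyed on plain integer residue numbers.

Trajectory dialect
------------------
Trajectories are stored as plain multi-frame XYZ text::

    <n_atoms>
    t=<time_ns> f=<force_pN>      (comment line; both fields optional)
    <element> <x> <y> <z>         (one line per atom, topology order, Å)
    ... repeated per frame ...

This keeps trajectories human-readable and diffable; the reader validates
the per-frame atom count against the topology and names the frame index of
any truncation.
"""

from __future__ import annotations

import json
import os
import re
from typing import Optional, Sequence

import numpy as np

from .model import (
    Atom,
    FormatError,
    MechbondError,
    Structure,
    TopologyError,
    Trajectory,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "write_report",
    "read_report",
]

_ELEMENT_FROM_NAME = re.compile(r"([A-Za-z])")


def _guess_element(name: str) -> str:
    """Fall back to the first alphabetic character of the atom name."""
    m = _ELEMENT_FROM_NAME.search(name)
    if not m:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    return m.group(1).upper()


def read_structure(path: str) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    One :class:`Atom` per ``ATOM``/``HETATM`` record; author numbering is
    preserved. Raises :class:`FormatError` naming the line number on any
    unparseable record, and on files with zero atom records.
    """
    atoms: list[Atom] = []
    seen_altloc: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21].strip() or " "
                resseq = int(line[22:26])
                icode = line[26]
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}: unparseable {rec} record at line {lineno}: {exc}"
                ) from exc
            if icode not in (" ", ""):
                raise FormatError(
                    f"{path}: insertion code {icode!r} at line {lineno} is not "
                    "supported (renumber the structure)"
                )
            key = (chain, resseq, name)
            if altloc not in (" ", "A", ""):
                continue  # keep-first altloc policy
            if key in seen_altloc:
                continue
            seen_altloc.add(key)
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _guess_element(name)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element.upper(),
                    residue_seq=resseq,
                    residue_name=resname,
                    chain_id=chain,
                    position=np.array([x, y, z]),
                )
            )
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms)


def write_structure(structure: Structure, path: str) -> None:
    """Write a minimal PDB file (3-decimal coordinates, PDB precision)."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                f"{a.chain_id:1.1s}{a.residue_seq:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}\n"
            )
        fh.write("END\n")


_COMMENT_FIELD = re.compile(r"(\w+)=([-+0-9.eE]+)")


def read_trajectory(topology: Structure, path: str) -> Trajectory:
    """Read the multi-frame XYZ dialect against a topology.

    Raises :class:`TopologyError` on an atom-count mismatch and
    :class:`FormatError` naming the frame index of a truncated final frame.
    """
    n = len(topology)
    frames: list[np.ndarray] = []
    times: list[float] = []
    forces: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: expected atom count at line {i + 1}, got "
                f"{lines[i]!r}"
            ) from exc
        if count != n:
            raise TopologyError(
                f"{path}: frame {frame_idx} declares {count} atoms but the "
                f"topology has {n}"
            )
        if i + 1 + count >= len(lines) + 1 and len(lines) - i - 2 < count:
            raise FormatError(
                f"{path}: truncated frame {frame_idx} (expected {count} atom "
                f"lines)"
            )
        comment = lines[i + 1]
        fields = dict(_COMMENT_FIELD.findall(comment))
        if "t" in fields:
            times.append(float(fields["t"]))
        if "f" in fields:
            forces.append(float(fields["f"]))
        coords = np.empty((n, 3))
        for j in range(count):
            lineidx = i + 2 + j
            if lineidx >= len(lines) or not lines[lineidx].strip():
                raise FormatError(
                    f"{path}: truncated frame {frame_idx} (expected {count} "
                    f"atom lines)"
                )
            parts = lines[lineidx].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: malformed atom line {lineidx + 1} in frame "
                    f"{frame_idx}"
                )
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + count
        frame_idx += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    t = np.array(times) if len(times) == len(frames) else None
    f = np.array(forces) if len(forces) == len(frames) else None
    return Trajectory(topology, np.stack(frames), times=t, applied_force=f)


def write_trajectory(trajectory: Trajectory, path: str) -> None:
    """Write the multi-frame XYZ dialect (6-decimal coordinates)."""
    top = trajectory.topology
    with open(path, "w") as fh:
        for k in range(len(trajectory)):
            fh.write(f"{len(top)}\n")
            parts = []
            if trajectory.times is not None:
                parts.append(f"t={float(trajectory.times[k])!r}")
            if trajectory.applied_force is not None:
                parts.append(f"f={float(trajectory.applied_force[k])!r}")
            fh.write(" ".join(parts) if parts else f"frame {k}")
            fh.write("\n")
            for a, p in zip(top.atoms, trajectory.frames[k]):
                fh.write(f"{a.element} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_report(tables: Sequence, path_prefix: str) -> list[str]:
    """Write a list of tables/profiles as sibling TSV files plus one JSON.

    Each table must provide ``name``, ``to_tsv(path)`` and ``to_dict()``.
    Floats are written with round-trip ``repr`` so a written report reads
    back bit-exactly. Returns the list of written paths.
    """
    if not tables:
        raise MechbondError("write_report: empty table list")
    os.makedirs(os.path.dirname(path_prefix) or ".", exist_ok=True)
    written = []
    payload = {}
    for t in tables:
        tsv_path = f"{path_prefix}_{t.name}.tsv"
        t.to_tsv(tsv_path)
        written.append(tsv_path)
        payload[t.name] = t.to_dict()
    json_path = f"{path_prefix}.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(json_path)
    return written


def read_report(json_path: str) -> dict:
    """Read back the JSON half of a written report (bit-exact floats)."""
    with open(json_path) as fh:
        return json.load(fh)
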