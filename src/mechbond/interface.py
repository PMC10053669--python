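"""Per-frame and per-trajectory interface metrics.

The observables implemented here are the standard geometric readouts of a
protein–protein interface in an MD trajectory:

* geometric hydrogen bonds (donor–acceptor distance and donor-H-acceptor
  angle criteria) and their per-residue-pair occupancies,
* salt bridges between acidic carboxylate oxygens and basic side-chain
  nitrogens,
* interfacial hydrogen-bond counts per frame (N_HB),
* Shrake–Rupley solvent-accessible surface area and the buried SASA of a
  complex,
* pairwise nonbonded interaction energy (Coulomb + Lennard-Jones) with a
  switched cutoff.

The hydrogen-bond angle criterion is read as *deviation from linearity*:
an event requires ∠D–H–A ≥ 180° − ``max_dha_deviation`` (the convention of
the common trajectory-analysis tools). Both the distance and angle cutoffs
are configurable through :class:`HBondCriteria`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    MissingHydrogenError,
    ParameterError,
    Selection,
    SelectionError,
    Structure,
    Trajectory,
)
from .params import COULOMB_K, VDW_RADII

__all__ = [
    "HBondCriteria",
    "BondEvent",
    "OccupancyRow",
    "OccupancyTable",
    "EnergyTerms",
    "detect_hbonds",
    "detect_salt_bridges",
    "occupancy",
    "aggregate_occupancy",
    "hbond_count_series",
    "sasa",
    "buried_sasa",
    "interaction_energy",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``max_da_distance`` (Å) bounds the donor–acceptor heavy-atom distance;
    ``max_dha_deviation`` (degrees) bounds the deviation of the D–H–A angle
    from linearity. ``max_dh_bond`` (Å) is the covalent D–H attachment
    cutoff used to pair hydrogens with their donor heavy atoms.
    """

    max_da_distance: float = 3.5
    max_dha_deviation: float = 30.0
    max_dh_bond: float = 1.25
    donor_elements: tuple[str, ...] = ("N", "O")
    acceptor_elements: tuple[str, ...] = ("N", "O")

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_dha_deviation <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


@dataclass(frozen=True)
class BondEvent:
    """One qualifying (donor, hydrogen, acceptor) triple in one frame."""

    frame: int
    donor: tuple[str, int, str]  # (chain, residue_seq, atom name)
    hydrogen: str
    acceptor: tuple[str, int, str]
    da_distance: float
    dha_deviation: float


@dataclass
class OccupancyRow:
    """Occupancy of one residue pair under one condition."""

    chain_a: str
    seq_a: int
    chain_b: str
    seq_b: int
    occupancy: float
    spread: float = 0.0
    condition: str = ""
    label: str = ""

    @property
    def pair(self) -> tuple[str, int, str, int]:
        return (self.chain_a, self.seq_a, self.chain_b, self.seq_b)


@dataclass
class OccupancyTable:
    """Residue-pair bond occupancies, the home of survival-rate tables."""

    rows: list[OccupancyRow]
    name: str = "occupancy"

    def __post_init__(self):
        for r in self.rows:
            if not (0.0 <= r.occupancy <= 1.0):
                raise ValueError(f"occupancy {r.occupancy} outside [0, 1]")
            if r.spread < 0:
                raise ValueError("spread must be non-negative")

    def get(self, pair: tuple[str, int, str, int]) -> Optional[OccupancyRow]:
        for r in self.rows:
            if r.pair == pair:
                return r
        return None

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                [
                    "chain_a",
                    "seq_a",
                    "chain_b",
                    "seq_b",
                    "occupancy",
                    "spread",
                    "condition",
                    "label",
                ]
            )
            for r in self.rows:
                w.writerow(
                    [
                        r.chain_a,
                        r.seq_a,
                        r.chain_b,
                        r.seq_b,
                        repr(r.occupancy),
                        repr(r.spread),
                        r.condition,
                        r.label,
                    ]
                )

    @classmethod
    def from_tsv(cls, path: str, name: str = "occupancy") -> "OccupancyTable":
        rows = []
        with open(path, newline="") as fh:
            rd = csv.reader(fh, delimiter="\t")
            header = next(rd)
            for rec in rd:
                d = dict(zip(header, rec))
                rows.append(
                    OccupancyRow(
                        chain_a=d["chain_a"],
                        seq_a=int(d["seq_a"]),
                        chain_b=d["chain_b"],
                        seq_b=int(d["seq_b"]),
                        occupancy=float(d["occupancy"]),
                        spread=float(d["spread"]),
                        condition=d.get("condition", ""),
                        label=d.get("label", ""),
                    )
                )
        return cls(rows, name=name)

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "chain_a": r.chain_a,
                    "seq_a": r.seq_a,
                    "chain_b": r.chain_b,
                    "seq_b": r.seq_b,
                    "occupancy": r.occupancy,
                    "spread": r.spread,
                    "condition": r.condition,
                    "label": r.label,
                }
                for r in self.rows
            ]
        }


@dataclass(frozen=True)
class EnergyTerms:
    """Pairwise nonbonded energy split (kcal/mol)."""

    electrostatic: float
    van_der_waals: float

    @property
    def total(self) -> float:
        return self.electrostatic + self.van_der_waals


# ---------------------------------------------------------------------------
# hydrogen-bond machinery
# ---------------------------------------------------------------------------


def _check_disjoint(sel_a: Selection, sel_b: Selection) -> None:
    if sel_a.structure is not sel_b.structure:
        raise SelectionError("selections must reference the same structure")
    if not sel_a.isdisjoint(sel_b):
        raise SelectionError("selections overlap")


def _donor_h_pairs(
    structure: Structure,
    coords: np.ndarray,
    sel: Selection,
    criteria: HBondCriteria,
) -> list[tuple[int, int]]:
    """Covalently attached (donor heavy atom, hydrogen) index pairs."""
    if not any(a.element == "H" for a in structure.atoms):
        raise MissingHydrogenError(
            "structure carries no hydrogen atoms; hydrogen-bond detection "
            "requires explicit hydrogens (no implicit placement is done)"
        )
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.element == "H":
            by_residue.setdefault(a.residue_key, []).append(i)
    pairs = []
    for i in sel.indices:
        a = structure.atoms[i]
        if a.element not in criteria.donor_elements:
            continue
        for j in by_residue.get(a.residue_key, []):
            if np.linalg.norm(coords[i] - coords[j]) <= criteria.max_dh_bond:
                pairs.append((i, j))
    return pairs


def _acceptors(structure: Structure, sel: Selection, criteria: HBondCriteria):
    return [
        i
        for i in sel.indices
        if structure.atoms[i].element in criteria.acceptor_elements
    ]


def _eval_triples(
    frames: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria,
):
    """Evaluate the geometric criteria for every (donor, H) × acceptor combo.

    Returns boolean presence (F, m, k) plus distance and deviation arrays.
    """
    D = frames[:, donors]  # (F, m, 3)
    H = frames[:, hydrogens]
    A = frames[:, acceptors]  # (F, k, 3)
    diff = D[:, :, None, :] - A[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (F, m, k)
    u = D - H  # H -> D
    v = A[:, None, :, :] - H[:, :, None, :]  # H -> A
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("fmd,fmkd->fmk", u, v) / (nu[:, :, None] * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    dev = 180.0 - ang
    ok = (dist <= criteria.max_da_distance) & (dev <= criteria.max_dha_deviation)
    return ok, dist, dev


def _interface_triples(
    structure: Structure,
    topo_coords: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria,
):
    """Candidate triples for both donor→acceptor directions across an interface.

    Hydrogen attachment is resolved on the supplied coordinates (the
    topology frame for trajectory-level statistics): attachment is a
    topological property and does not change along a trajectory.
    """
    out = []
    for donor_sel, acc_sel in ((sel_a, sel_b), (sel_b, sel_a)):
        dh = _donor_h_pairs(structure, topo_coords, donor_sel, criteria)
        acc = _acceptors(structure, acc_sel, criteria)
        if dh and acc:
            d = np.array([p[0] for p in dh], dtype=int)
            h = np.array([p[1] for p in dh], dtype=int)
            a = np.array(acc, dtype=int)
            out.append((d, h, a))
    return out


def detect_hbonds(
    frame: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[BondEvent]:
    """Detect geometric hydrogen bonds across an interface in one frame.

    ``frame`` is the full-structure (n_atoms, 3) coordinate array. Both
    donor→acceptor directions are examined; each qualifying
    (donor, H, acceptor) triple is reported once.
    """
    _check_disjoint(sel_a, sel_b)
    structure = sel_a.structure
    frame = np.asarray(frame, dtype=float)
    events: list[BondEvent] = []
    for d, h, a in _interface_triples(structure, frame, sel_a, sel_b, criteria):
        ok, dist, dev = _eval_triples(frame[None], d, h, a, criteria)
        for mi, ki in zip(*np.nonzero(ok[0])):
            da = structure.atoms[d[mi]]
            ha = structure.atoms[h[mi]]
            aa = structure.atoms[a[ki]]
            events.append(
                BondEvent(
                    frame=0,
                    donor=(da.chain_id, da.residue_seq, da.name),
                    hydrogen=ha.name,
                    acceptor=(aa.chain_id, aa.residue_seq, aa.name),
                    da_distance=float(dist[0, mi, ki]),
                    dha_deviation=float(dev[0, mi, ki]),
                )
            )
    events.sort(key=lambda e: (e.donor, e.hydrogen, e.acceptor))
    return events


def _pair_presence(
    trajectory: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria,
    chunk: int = 250,
):
    """Per-frame presence of every interface residue pair and triple count.

    Returns (pairs, presence (F, n_pairs) bool, n_hb (F,) int) where the
    pair key is ((chain, seq) on the A side, (chain, seq) on the B side).
    """
    _check_disjoint(sel_a, sel_b)
    structure = sel_a.structure
    topo = structure.coords
    groups = _interface_triples(structure, topo, sel_a, sel_b, criteria)
    F = len(trajectory)
    n_hb = np.zeros(F, dtype=int)
    a_set = set(sel_a.indices)
    pair_keys: list[tuple] = []
    pair_cols: list[np.ndarray] = []
    per_group = []
    for d, h, a in groups:
        # map each (m, k) combination to its residue pair, oriented A-side first
        keys = np.empty((len(d), len(a)), dtype=object)
        for mi, di in enumerate(d):
            rd = structure.atoms[di].residue_key
            d_in_a = di in a_set
            for ki, ai in enumerate(a):
                ra = structure.atoms[ai].residue_key
                keys[mi, ki] = (rd, ra) if d_in_a else (ra, rd)
        per_group.append(keys)
    presence_by_pair: dict[tuple, np.ndarray] = {}
    for start in range(0, F, chunk):
        stop = min(start + chunk, F)
        sub = trajectory.frames[start:stop]
        for (d, h, a), keys in zip(groups, per_group):
            ok, _, _ = _eval_triples(sub, d, h, a, criteria)
            n_hb[start:stop] += ok.sum(axis=(1, 2))
            hit = np.nonzero(ok.any(axis=0))
            for mi, ki in zip(*hit):
                key = keys[mi, ki]
                col = presence_by_pair.get(key)
                if col is None:
                    col = np.zeros(F, dtype=bool)
                    presence_by_pair[key] = col
                col[start:stop] |= ok[:, mi, ki]
    pairs = sorted(presence_by_pair)
    presence = (
        np.stack([presence_by_pair[p] for p in pairs], axis=1)
        if pairs
        else np.zeros((F, 0), dtype=bool)
    )
    return pairs, presence, n_hb


def occupancy(
    trajectory: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    condition: str = "",
) -> OccupancyTable:
    """Per-residue-pair hydrogen-bond occupancy over a trajectory.

    The occupancy (survival ratio) of a pair is the fraction of frames in
    which at least one qualifying hydrogen bond connects its two residues.
    Multiple atom-level bonds between the same residues collapse to one
    event per frame; pairs never bonded are omitted.
    """
    pairs, presence, _ = _pair_presence(trajectory, sel_a, sel_b, criteria)
    structure = sel_a.structure
    resnames = {a.residue_key: a.residue_name for a in structure.atoms}
    rows = []
    occ = presence.mean(axis=0) if len(pairs) else np.empty(0)
    for p, o in zip(pairs, occ):
        (ca, sa), (cb, sb) = p
        label = f"{resnames[p[0]]}{sa}({ca})-{resnames[p[1]]}{sb}({cb})"
        rows.append(
            OccupancyRow(
                chain_a=ca,
                seq_a=sa,
                chain_b=cb,
                seq_b=sb,
                occupancy=float(o),
                condition=condition,
                label=label,
            )
        )
    rows.sort(key=lambda r: (-r.occupancy, r.pair))
    return OccupancyTable(rows, name="occupancy")


def aggregate_occupancy(
    tables: Sequence[OccupancyTable], condition: str = ""
) -> OccupancyTable:
    """Aggregate replicate occupancy tables to mean ± SD per pair.

    A pair missing from one replicate counts as occupancy 0 there (it never
    formed in that run).
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    pairs: dict[tuple, str] = {}
    for t in tables:
        for r in t.rows:
            pairs.setdefault(r.pair, r.label)
    rows = []
    for pair in sorted(pairs):
        vals = []
        for t in tables:
            r = t.get(pair)
            vals.append(r.occupancy if r is not None else 0.0)
        vals = np.array(vals)
        rows.append(
            OccupancyRow(
                chain_a=pair[0],
                seq_a=pair[1],
                chain_b=pair[2],
                seq_b=pair[3],
                occupancy=float(vals.mean()),
                spread=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                condition=condition,
                label=pairs[pair],
            )
        )
    rows.sort(key=lambda r: (-r.occupancy, r.pair))
    return OccupancyTable(rows, name="occupancy")


def hbond_count_series(
    trajectory: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> np.ndarray:
    """Per-frame interfacial hydrogen-bond count N_HB.

    Counts distinct qualifying (donor, H, acceptor) triples across the
    interface in each frame (both directions).
    """
    _, _, n_hb = _pair_presence(trajectory, sel_a, sel_b, criteria)
    return n_hb


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

ACIDIC_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_NITROGENS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}


def detect_salt_bridges(
    frame: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
    cutoff: float = 4.0,
    acidic: dict[str, tuple[str, ...]] = ACIDIC_OXYGENS,
    basic: dict[str, tuple[str, ...]] = BASIC_NITROGENS,
) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
    """Salt-bridge contacts between acidic and basic residues in one frame.

    A contact exists when any carboxylate oxygen of Asp/Glu lies within
    ``cutoff`` Å of any side-chain nitrogen of Lys/Arg across the interface.
    Each residue pair is reported once per frame with its minimum O–N
    distance, regardless of how many atom contacts it has.
    """
    _check_disjoint(sel_a, sel_b)
    structure = sel_a.structure
    frame = np.asarray(frame, dtype=float)

    def classify(sel: Selection, table: dict[str, tuple[str, ...]]):
        out = []
        for i in sel.indices:
            a = structure.atoms[i]
            if a.name in table.get(a.residue_name, ()):
                out.append(i)
        return out

    best: dict[tuple, float] = {}
    for acid_sel, base_sel in ((sel_a, sel_b), (sel_b, sel_a)):
        oxy = classify(acid_sel, acidic)
        nit = classify(base_sel, basic)
        if not oxy or not nit:
            continue
        d = np.linalg.norm(
            frame[np.array(oxy)][:, None, :] - frame[np.array(nit)][None, :, :],
            axis=-1,
        )
        for oi, ni in zip(*np.nonzero(d <= cutoff)):
            acid_res = structure.atoms[oxy[oi]].residue_key
            base_res = structure.atoms[nit[ni]].residue_key
            key = (acid_res, base_res)
            dist = float(d[oi, ni])
            if key not in best or dist < best[key]:
                best[key] = dist
    return [(k[0], k[1], best[k]) for k in sorted(best)]


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [
            np.cos(theta) * np.sin(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(phi),
        ],
        axis=1,
    )


def _radii_for(structure: Structure, indices: np.ndarray) -> np.ndarray:
    radii = np.empty(len(indices))
    for k, i in enumerate(indices):
        a = structure.atoms[i]
        try:
            radii[k] = VDW_RADII[a.element.upper()]
        except KeyError:
            raise ParameterError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.name} in {a.chain_id}:{a.residue_seq})"
            ) from None
    return radii


def sasa(
    frame: np.ndarray,
    selection: Selection,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Shrake–Rupley solvent-accessible surface area of a selection (Å²).

    Only atoms in the selection occlude each other — the selection is
    treated as an isolated molecule, which is what the buried-SASA
    difference formula requires. The quadrature uses a fixed golden-spiral
    point set, so results are bit-reproducible for a given point count.
    """
    frame = np.asarray(frame, dtype=float)
    idx = selection.index_array
    coords = frame[idx]
    radii = _radii_for(selection.structure, idx) + probe
    pts = _sphere_points(n_sphere_points)
    area = 0.0
    for k in range(len(idx)):
        rk = radii[k]
        d = np.linalg.norm(coords - coords[k], axis=1)
        near = np.nonzero((d < rk + radii) & (np.arange(len(idx)) != k))[0]
        surface = coords[k] + rk * pts
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in near:
            accessible &= (
                np.linalg.norm(surface - coords[j], axis=1) >= radii[j]
            )
            if not accessible.any():
                break
        area += 4.0 * np.pi * rk * rk * accessible.mean()
    return float(area)


def buried_sasa(
    frame: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Buried surface area of a complex: SASA(A) + SASA(B) − SASA(A∪B).

    Two-sided (summed over both partners); symmetric in A and B, and zero
    up to quadrature error for non-contacting partners.
    """
    _check_disjoint(sel_a, sel_b)
    union = Selection(
        sel_a.structure,
        tuple(sorted(set(sel_a.indices) | set(sel_b.indices))),
        f"{sel_a.label} + {sel_b.label}",
    )
    return (
        sasa(frame, sel_a, probe, n_sphere_points)
        + sasa(frame, sel_b, probe, n_sphere_points)
        - sasa(frame, union, probe, n_sphere_points)
    )


# ---------------------------------------------------------------------------
# nonbonded interaction energy
# ---------------------------------------------------------------------------


def _nonbonded_arrays(structure: Structure, indices: np.ndarray):
    q = np.empty(len(indices))
    eps = np.empty(len(indices))
    rmin2 = np.empty(len(indices))
    missing = []
    for k, i in enumerate(indices):
        a = structure.atoms[i]
        if a.charge is None or a.lj_epsilon is None or a.lj_rmin_half is None:
            missing.append(f"{a.chain_id}:{a.residue_seq}:{a.name}")
            continue
        q[k], eps[k], rmin2[k] = a.charge, a.lj_epsilon, a.lj_rmin_half
    if missing:
        raise ParameterError(
            "atoms missing nonbonded parameters: " + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    return q, eps, rmin2


def _switching(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM-style switching function, 1 below r_on, 0 beyond r_off."""
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    s = np.ones_like(r)
    mid = (r > r_on) & (r <= r_off)
    denom = (off2 - on2) ** 3
    s[mid] = ((off2 - r2[mid]) ** 2 * (off2 + 2.0 * r2[mid] - 3.0 * on2)) / denom
    s[r > r_off] = 0.0
    return s


def interaction_energy(
    frame: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
    cutoff: float = 12.0,
    switch_on: float = 10.0,
) -> EnergyTerms:
    """Cross-selection nonbonded interaction energy in one frame (kcal/mol).

    Sums Coulomb (k = 332.0636 kcal·Å·mol⁻¹·e⁻²) and 12-6 Lennard-Jones
    terms (Lorentz–Berthelot combination) over all inter-selection atom
    pairs within ``cutoff`` Å, each scaled by a switching function active
    over [switch_on, cutoff]. No intra-selection terms are included; plain
    switched cutoff, no Ewald/reaction field.
    """
    _check_disjoint(sel_a, sel_b)
    structure = sel_a.structure
    frame = np.asarray(frame, dtype=float)
    ia, ib = sel_a.index_array, sel_b.index_array
    qa, ea, ra = _nonbonded_arrays(structure, ia)
    qb, eb, rb = _nonbonded_arrays(structure, ib)
    d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :], axis=-1)
    mask = d <= cutoff
    if not mask.any():
        return EnergyTerms(0.0, 0.0)
    r = d[mask]
    s = _switching(r, switch_on, cutoff)
    qq = np.outer(qa, qb)[mask]
    elec = float(np.sum(COULOMB_K * qq / r * s))
    eps = np.sqrt(np.outer(ea, eb))[mask]
    rmin = (ra[:, None] + rb[None, :])[mask]
    ratio6 = (rmin / r) ** 6
    vdw = float(np.sum(eps * (ratio6 * ratio6 - 2.0 * ratio6) * s))
    return EnergyTerms(elec, vdw)
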