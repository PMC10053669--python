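"""Shared builders and independent brute-force oracles for the test suite.

The oracles here deliberately re-derive every quantity from first
principles (exhaustive enumeration, closed forms, dense quadrature) and
never call the vectorised implementation paths they are used to check.
"""

from __future__ import annotations

import numpy as np

import mechbond as mb
from mechbond.interface import HBondCriteria


def random_interface_structure(rng: np.random.Generator, n_residues: int = 25):
    """A random two-chain structure of small N/H/O/C residues in a box.

    Each residue has a heavy N or O with a covalently attached hydrogen
    (0.95–1.05 Å), one carbon and one extra oxygen at random positions, so
    the frame is rich in donors, acceptors and decoys. Residues alternate
    between chains A and B.
    """
    atoms = []
    serial = 1
    for res in range(1, n_residues + 1):
        chain = "A" if res % 2 else "B"
        base = rng.uniform(0, 18, size=3)
        heavy_el = rng.choice(["N", "O"])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        h_pos = base + direction * rng.uniform(0.95, 1.05)
        extras = [
            ("C", "C", base + rng.uniform(-3, 3, size=3)),
            ("OX", "O", base + rng.uniform(-3, 3, size=3)),
        ]
        for name, el, pos in [(heavy_el, heavy_el, base),
                              ("H", "H", h_pos)] + extras:
            atoms.append(
                mb.Atom(serial, name, el, res, "RND", chain, pos)
            )
            serial += 1
    return mb.Structure(atoms)


def brute_force_hbonds(
    frame: np.ndarray,
    sel_a: mb.Selection,
    sel_b: mb.Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[tuple]:
    """Exhaustive (donor, H, acceptor) triple enumeration, O(n³) by intent.

    Returns the set of qualifying triples as
    ((chain, seq, donor name), hydrogen name, (chain, seq, acceptor name)).
    """
    structure = sel_a.structure
    found = set()
    for donor_sel, acc_sel in ((sel_a, sel_b), (sel_b, sel_a)):
        for di in donor_sel.indices:
            d = structure.atoms[di]
            if d.element not in criteria.donor_elements:
                continue
            for hi, h in enumerate(structure.atoms):
                if h.element != "H" or h.residue_key != d.residue_key:
                    continue
                if np.linalg.norm(frame[di] - frame[hi]) > criteria.max_dh_bond:
                    continue
                for ai in acc_sel.indices:
                    a = structure.atoms[ai]
                    if a.element not in criteria.acceptor_elements:
                        continue
                    dist = np.linalg.norm(frame[di] - frame[ai])
                    if dist > criteria.max_da_distance:
                        continue
                    u = frame[di] - frame[hi]
                    v = frame[ai] - frame[hi]
                    cosang = np.dot(u, v) / (
                        np.linalg.norm(u) * np.linalg.norm(v)
                    )
                    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if 180.0 - angle <= criteria.max_dha_deviation:
                        found.add(
                            (
                                (d.chain_id, d.residue_seq, d.name),
                                h.name,
                                (a.chain_id, a.residue_seq, a.name),
                            )
                        )
    return found


def five_mode_specs() -> list[mb.BondSpec]:
    """One bond per force-response mode, with well-separated shapes.

    Shapes are chosen so that on the default 0–100 pN grid each curve's
    successive differences exceed the 0.05 classification tolerance where
    a trend is planted and stay well inside it where a plateau is planted.
    """
    return [
        mb.BondSpec(("A", 1, "N", "H"), ("B", 1, "O"), "steady", 0.5,
                    label="steady"),
        mb.BondSpec(("A", 2, "N", "H"), ("B", 2, "O"), "catch_slip", 0.2,
                    (0.5,), (50.0,), (20.0,), "catch_slip"),
        mb.BondSpec(("A", 3, "N", "H"), ("B", 3, "O"), "slip_catch", 0.7,
                    (-0.5,), (50.0,), (20.0,), "slip_catch"),
        mb.BondSpec(("A", 4, "N", "H"), ("B", 4, "O"), "catch_slip_catch",
                    0.2, (0.4, 0.4), (25.0, 100.0), (15.0, 15.0), "csc"),
        mb.BondSpec(("A", 5, "N", "H"), ("B", 5, "O"), "slip_catch_slip",
                    0.8, (-0.4, -0.4), (25.0, 100.0), (15.0, 15.0), "scs"),
    ]


def simple_pair_structure(
    da_distance: float = 2.9,
    deviation: float = 10.0,
    donor_element: str = "N",
    acceptor_element: str = "O",
):
    """Donor + hydrogen on chain A, acceptor on chain B, at exact geometry.

    The hydrogen is placed on the donor→acceptor axis and then tilted in
    the plane so the D–H–A deviation equals ``deviation`` exactly.
    """
    from mechbond.synthetic import _solve_tilt

    tilt = _solve_tilt(deviation, da_distance)
    h = np.array([np.sin(tilt), np.cos(tilt), 0.0])
    atoms = [
        mb.Atom(1, donor_element, donor_element, 1, "RES", "A",
                np.zeros(3)),
        mb.Atom(2, "H", "H", 1, "RES", "A", h),
        mb.Atom(3, acceptor_element, acceptor_element, 1, "RES", "B",
                np.array([0.0, da_distance, 0.0])),
    ]
    s = mb.Structure(atoms)
    return s, mb.Selection(s, (0, 1), "A"), mb.Selection(s, (2,), "B")
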