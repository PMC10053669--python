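"""Synthetic two-chain complexes with planted force-dependent hydrogen bonds.

The generator builds a toy complex of two chains (A and B) of glycine-like
residues (backbone N, H, CA, C, O only). Each planted bond pairs a donor
N–H on chain A with an acceptor O on chain B; in every trajectory frame the
bond is present with probability o(F) — its occupancy curve at the applied
force — drawn as an independent Bernoulli event (an optional Markov
persistence adds dwell-time correlation, off by default). A present bond
uses the bound geometry template (donor–acceptor distance 2.9 Å, D–H–A
deviation 10°, comfortably inside the 3.5 Å / 30° detection criteria); an
absent bond uses the unbound template (5.0 Å, which violates the distance
criterion). Every atom receives sub-0.05 Å positional jitter.

Occupancy curves are Gaussian-bump parametrisations

    o(F) = baseline + Σᵢ aᵢ · exp(−(F − cᵢ)² / 2wᵢ²)

whose bump signs and count encode the five force-response modes: no bumps
(steady), one positive bump (catch–slip: unimodal interior maximum), one
negative bump (slip–catch), two positive bumps (catch–slip–catch) and two
negative (slip–catch–slip).

Geometry is laid out so that planted bonds are the *only* hydrogen bonds
the detection criteria can ever see: each bond occupies its own 24 Å slot
along x, the two chains are separated in y, and inert atoms sit at least
5.3 Å from any cross-chain donor or acceptor even after jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .model import Atom, ConfigError, Structure, Trajectory
from .params import BACKBONE_NONBONDED

__all__ = [
    "BondSpec",
    "GeneratorConfig",
    "occupancy_curve",
    "generate_complex",
    "generate_trajectory",
    "generate_ramp",
]

MODES = (
    "steady",
    "catch_slip",
    "slip_catch",
    "catch_slip_catch",
    "slip_catch_slip",
)

_SLOT_SPACING = 24.0  # Å between planted-bond slots along x
_JITTER = 0.045  # Å, uniform per coordinate; keeps all margins intact
_DH_LENGTH = 1.0  # Å covalent N–H


@dataclass(frozen=True)
class BondSpec:
    """One planted donor–acceptor pair with its occupancy curve.

    ``donor`` is (chain, residue_seq, heavy-atom name, hydrogen name) and
    ``acceptor`` is (chain, residue_seq, atom name). The curve parameters
    must keep o(F) inside [0, 1] for all F ≥ 0 and must match the declared
    mode's bump signature; both are validated at construction.
    """

    donor: tuple[str, int, str, str]
    acceptor: tuple[str, int, str]
    mode: str
    baseline: float
    amplitudes: tuple[float, ...] = ()
    centers: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not (len(self.amplitudes) == len(self.centers) == len(self.widths)):
            raise ConfigError("amplitudes/centers/widths must align")
        if any(w <= 0 for w in self.widths):
            raise ConfigError("bump widths must be positive")
        n_bumps = {"steady": 0, "catch_slip": 1, "slip_catch": 1,
                   "catch_slip_catch": 2, "slip_catch_slip": 2}[self.mode]
        if len(self.amplitudes) != n_bumps:
            raise ConfigError(
                f"mode {self.mode!r} needs {n_bumps} bump(s), "
                f"got {len(self.amplitudes)}"
            )
        want_positive = self.mode in ("catch_slip", "catch_slip_catch")
        for a in self.amplitudes:
            if want_positive and a <= 0:
                raise ConfigError(f"{self.mode} bumps must be positive")
            if not want_positive and n_bumps and a >= 0:
                raise ConfigError(f"{self.mode} bumps must be negative")
        # range validation on a dense grid covering every bump
        fmax = max([200.0] + [c + 4 * w for c, w in zip(self.centers, self.widths)])
        grid = np.linspace(0.0, fmax, 2001)
        o = occupancy_curve(self, grid)
        if o.min() < 0.0 or o.max() > 1.0:
            raise ConfigError(
                f"occupancy curve leaves [0, 1] (range "
                f"[{o.min():.3f}, {o.max():.3f}])"
            )


def occupancy_curve(
    spec: BondSpec, force: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Target occupancy o(F) of a planted bond at force F (pN). F must be ≥ 0."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    o = np.full_like(f, float(spec.baseline))
    for a, c, w in zip(spec.amplitudes, spec.centers, spec.widths):
        o = o + a * np.exp(-((f - c) ** 2) / (2.0 * w * w))
    return float(o) if np.isscalar(force) else o


@dataclass
class GeneratorConfig:
    """Everything needed to build one synthetic complex and its trajectories.

    ``chain_a_numbering``/``chain_b_numbering`` give explicit author residue
    numbers (default 1..n). One ``seed`` governs each (force, replicate)
    run; the replicate index perturbs the seed deterministically through a
    :class:`numpy.random.SeedSequence`.
    """

    n_residues_per_chain: int
    bond_specs: list[BondSpec] = field(default_factory=list)
    n_frames: int = 2000
    force_grid: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0)
    seed: int = 0
    bound_distance: float = 2.9
    bound_deviation: float = 10.0
    unbound_distance: float = 5.0
    chain_a_numbering: Optional[list[int]] = None
    chain_b_numbering: Optional[list[int]] = None
    frame_dt_ns: float = 0.05
    markov_persistence: float = 0.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not (0.0 < self.bound_distance < 3.5):
            raise ConfigError("bound distance must satisfy the 3.5 Å criterion")
        if not (0.0 <= self.bound_deviation < 30.0):
            raise ConfigError("bound deviation must satisfy the 30° criterion")
        if self.unbound_distance <= 3.5:
            raise ConfigError("unbound distance must violate the 3.5 Å criterion")
        if not (0.0 <= self.markov_persistence < 1.0):
            raise ConfigError("markov_persistence must be in [0, 1)")
        if self.chain_a_numbering is None:
            self.chain_a_numbering = list(range(1, self.n_residues_per_chain + 1))
        if self.chain_b_numbering is None:
            self.chain_b_numbering = list(range(1, self.n_residues_per_chain + 1))
        for numbering, chain in (
            (self.chain_a_numbering, "A"),
            (self.chain_b_numbering, "B"),
        ):
            if len(numbering) != self.n_residues_per_chain:
                raise ConfigError(
                    f"chain {chain} numbering length != n_residues_per_chain"
                )
            if len(set(numbering)) != len(numbering):
                raise ConfigError(f"chain {chain} numbering has duplicates")
        if len(self.bond_specs) > self.n_residues_per_chain:
            raise ConfigError("more bonds than residues per chain")
        used_a: set[int] = set()
        used_b: set[int] = set()
        for spec in self.bond_specs:
            dc, dseq, dname, hname = spec.donor
            ac, aseq, aname = spec.acceptor
            if dc != "A" or ac != "B":
                raise ConfigError("donors must be on chain A, acceptors on B")
            if dseq not in self.chain_a_numbering:
                raise ConfigError(f"donor residue A:{dseq} does not exist")
            if aseq not in self.chain_b_numbering:
                raise ConfigError(f"acceptor residue B:{aseq} does not exist")
            if dseq in used_a or aseq in used_b:
                raise ConfigError(
                    "each residue may participate in at most one planted bond"
                )
            used_a.add(dseq)
            used_b.add(aseq)


def _solve_tilt(target_deviation: float, da_distance: float) -> float:
    """H tilt (radians off the donor→acceptor axis) giving the target D–H–A
    deviation when the bond is bound."""
    if target_deviation == 0.0:
        return 0.0

    def deviation(t: float) -> float:
        h = np.array([_DH_LENGTH * np.sin(t), _DH_LENGTH * np.cos(t)])
        d = -h  # H -> D
        a = np.array([0.0, da_distance]) - h  # H -> A
        cosang = np.dot(d, a) / (np.linalg.norm(d) * np.linalg.norm(a))
        return 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))

    return brentq(
        lambda t: deviation(t) - target_deviation, 1e-9, np.radians(60.0)
    )


def _layout(config: GeneratorConfig):
    """Slot index for every residue and the bond donor/acceptor residue maps."""
    donor_slot = {
        spec.donor[1]: k for k, spec in enumerate(config.bond_specs)
    }
    acceptor_slot = {
        spec.acceptor[1]: k for k, spec in enumerate(config.bond_specs)
    }
    nb = len(config.bond_specs)
    slots_a, slots_b = {}, {}
    nxt = nb
    for seq in config.chain_a_numbering:
        slots_a[seq] = donor_slot.get(seq, None)
        if slots_a[seq] is None:
            slots_a[seq] = nxt
            nxt += 1
    nxt = nb
    for seq in config.chain_b_numbering:
        slots_b[seq] = acceptor_slot.get(seq, None)
        if slots_b[seq] is None:
            slots_b[seq] = nxt
            nxt += 1
    return slots_a, slots_b, donor_slot, acceptor_slot


def generate_complex(config: GeneratorConfig) -> Structure:
    """Build the two-chain complex (deterministic; no jitter on the topology).

    All atoms carry default backbone nonbonded parameters so the energy
    stage runs out of the box. Acceptor atoms sit at the *unbound* template
    in the topology; trajectories toggle them per frame.
    """
    slots_a, slots_b, donor_slot, acceptor_slot = _layout(config)
    tilt = _solve_tilt(config.bound_deviation, config.bound_distance)
    hx, hy = _DH_LENGTH * np.sin(tilt), _DH_LENGTH * np.cos(tilt)
    atoms: list[Atom] = []
    serial = 1

    def add(name, element, seq, chain, pos):
        nonlocal serial
        q, eps, rmin = BACKBONE_NONBONDED[name]
        atoms.append(
            Atom(serial, name, element, seq, "GLY", chain,
                 np.array(pos, dtype=float),
                 charge=q, lj_epsilon=eps, lj_rmin_half=rmin)
        )
        serial += 1

    for seq in sorted(config.chain_a_numbering):
        x = _SLOT_SPACING * slots_a[seq]
        is_donor = seq in donor_slot
        add("N", "N", seq, "A", (x, 0.0, 0.0))
        if is_donor:
            add("H", "H", seq, "A", (x + hx, hy, 0.0))
        else:
            add("H", "H", seq, "A", (x, -1.0, 0.0))
        add("CA", "C", seq, "A", (x + 1.5, -1.1, 0.0))
        add("C", "C", seq, "A", (x + 2.3, -2.2, 0.0))
        add("O", "O", seq, "A", (x + 2.3, -3.4, 0.0))
    for seq in sorted(config.chain_b_numbering):
        x = _SLOT_SPACING * slots_b[seq]
        is_acceptor = seq in acceptor_slot
        add("N", "N", seq, "B", (x, 8.0, 0.0))
        add("H", "H", seq, "B", (x, 9.0, 0.0))
        add("CA", "C", seq, "B", (x + 1.5, 8.8, 0.0))
        add("C", "C", seq, "B", (x + 0.6, 6.7, 0.0))
        if is_acceptor:
            add("O", "O", seq, "B", (x, config.unbound_distance, 0.0))
        else:
            add("O", "O", seq, "B", (x + 0.5, 5.5, 0.0))
    return Structure(atoms)


def _presence(
    rng: np.random.Generator, p: float, n: int, persistence: float
) -> np.ndarray:
    if persistence == 0.0:
        return rng.random(n) < p
    # stationary two-state Markov chain with occupancy p and lag-1
    # correlation `persistence`
    out = np.empty(n, dtype=bool)
    out[0] = rng.random() < p
    p11 = p + persistence * (1.0 - p)
    p01 = p * (1.0 - persistence)
    draws = rng.random(n)
    for i in range(1, n):
        out[i] = draws[i] < (p11 if out[i - 1] else p01)
    return out


def run_seed(config: GeneratorConfig, force: float, replicate: int = 0):
    """Deterministic per-(force, replicate) random generator."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed), int(round(force * 1000)) + 1, replicate + 1]
        )
    )


def generate_trajectory(
    structure: Structure,
    config: GeneratorConfig,
    force: float,
    replicate: int = 0,
    n_frames: Optional[int] = None,
) -> Trajectory:
    """Sample one trajectory at a constant applied force.

    Per frame and per planted bond, presence is a Bernoulli(o(F)) event
    from the run's seeded generator; present bonds take the bound geometry,
    absent bonds the unbound one, and every atom gets sub-0.05 Å jitter.
    """
    F = config.n_frames if n_frames is None else n_frames
    if F < 1:
        raise ConfigError("n_frames must be >= 1")
    rng = run_seed(config, force, replicate)
    frames = np.broadcast_to(
        structure.coords, (F, len(structure), 3)
    ).copy()
    for spec in config.bond_specs:
        p = float(occupancy_curve(spec, force))
        present = _presence(rng, p, F, config.markov_persistence)
        di = structure.atom_index("A", spec.donor[1], spec.donor[2])
        ai = structure.atom_index("B", spec.acceptor[1], spec.acceptor[2])
        r = np.where(present, config.bound_distance, config.unbound_distance)
        frames[:, ai, :] = structure.coords[di]
        frames[:, ai, 1] += r
    frames += rng.uniform(-_JITTER, _JITTER, size=frames.shape)
    times = config.frame_dt_ns * np.arange(F)
    return Trajectory(
        structure,
        frames,
        times=times,
        applied_force=np.full(F, float(force)),
    )


def generate_ramp(
    structure: Structure,
    config: GeneratorConfig,
    peak_force: float,
    rupture_frame: int,
    n_frames: Optional[int] = None,
    force_noise: float = 0.0,
    replicate: int = 0,
    plateau: int = 11,
):
    """A force-ramp run with a planted rupture.

    The force trace rises linearly, holds a ``plateau``-frame shoulder at
    ``peak_force`` ending at ``rupture_frame``, then collapses linearly;
    every planted bond is present before the rupture frame and absent from
    it on. The plateau makes the smoothed peak equal the planted peak
    exactly in the noiseless case (a pure triangle would be averaged
    down by any moving window). Returns ``(trajectory, trace)`` where the
    trace carries the planted per-frame bond count.
    """
    F = config.n_frames if n_frames is None else n_frames
    if not (plateau < rupture_frame < F):
        raise ConfigError(
            "rupture_frame must lie strictly inside the run, after the plateau"
        )
    rng = run_seed(config, peak_force, 1000 + replicate)
    frames = np.broadcast_to(structure.coords, (F, len(structure), 3)).copy()
    present = np.arange(F) < rupture_frame
    for spec in config.bond_specs:
        di = structure.atom_index("A", spec.donor[1], spec.donor[2])
        ai = structure.atom_index("B", spec.acceptor[1], spec.acceptor[2])
        r = np.where(present, config.bound_distance, config.unbound_distance)
        frames[:, ai, :] = structure.coords[di]
        frames[:, ai, 1] += r
    frames += rng.uniform(-_JITTER, _JITTER, size=frames.shape)
    times = config.frame_dt_ns * np.arange(F)
    rise = rupture_frame - plateau
    up = np.linspace(0.0, peak_force, rise, endpoint=False)
    shoulder = np.full(plateau, peak_force)
    down = np.linspace(peak_force, 0.2 * peak_force, F - rupture_frame + 1)[1:]
    force = np.concatenate([up, shoulder, down])
    if force_noise > 0:
        force = force + rng.normal(0.0, force_noise, size=F)
    n_hb = np.where(present, len(config.bond_specs), 0)
    trajectory = Trajectory(structure, frames, times=times, applied_force=force)
    from .allostery import ForceTrace  # local import to avoid a cycle

    return trajectory, ForceTrace(times, force, n_hb)
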