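"""Config-driven orchestration of the three analysis campaigns.

* :func:`run_equilibrium_analysis` — compare systems (e.g. a full receptor
  against a domain truncation) over replicate equilibrium trajectories:
  Cα-RMSD, residue-pair occupancies, N_HB, buried SASA, interaction energy,
  dissociation probability fD, and cross-system p-values.
* :func:`run_force_clamp_analysis` — force-response profiles (E, N_HB, fD,
  DMC, κ) over an ordered force grid with replicate spread, biphasic
  thresholds, per-pair catch/slip mode classification (thermograph) and
  Gaussian fits of the N_HB frequency per force.
* :func:`run_ramp_analysis` — force-ramp time series (force, buried SASA,
  RMSD, steered–fixed distance) and rupture-force extraction.

Equilibrium replicates are aggregated as mean ± SD, force profiles as
mean ± SE, matching the two reporting conventions of replicate MD studies.
The pipeline never runs MD; it consumes trajectories.

It also ships the reference residue-pair occupancy table of the
DNAM-1/CD155 complex (12 interface hydrogen bonds, wild-type and D2-deleted
occupancies; see :func:`load_reference_occupancies`) and can translate it
into a synthetic generator configuration whose planted occupancies mirror
the reference values (:func:`reference_config`), so the whole pipeline can
be exercised end-to-end against a known ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .allostery import (
    ForceTrace,
    RuptureResult,
    cross_angle_series,
    dmc_series,
    pull_distance_series,
    rmsd_series,
    rupture_force,
)
from .force_response import (
    BiphasicResult,
    ForceResponseProfile,
    GaussianFit,
    biphasic_threshold,
    classify_mode,
    compare_replicates,
    dissociation_probability,
    fit_gaussian,
)
from .interface import (
    HBondCriteria,
    OccupancyTable,
    aggregate_occupancy,
    buried_sasa,
    hbond_count_series,
    interaction_energy,
    occupancy,
)
from .model import (
    Atom,
    ConfigError,
    Selection,
    Structure,
    Trajectory,
    select,
)
from .synthetic import BondSpec, GeneratorConfig

logger = logging.getLogger("mechbond")

__all__ = [
    "RunConfig",
    "SystemSummary",
    "EquilibriumReport",
    "ClampReport",
    "RampReport",
    "load_reference_occupancies",
    "reference_bond_specs",
    "reference_config",
    "truncate_chain",
    "run_equilibrium_analysis",
    "run_force_clamp_analysis",
    "run_ramp_analysis",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Selections, criteria and cutoffs for one analysis run.

    Residue ranges are inclusive author numbering; ``None`` ranges mean the
    whole chain. Loop/strand ranges are (chain, lo, hi); steered/fixed
    atoms are (chain, residue_seq, atom name).
    """

    label: str = "run"
    chain_a: str = "A"
    chain_b: str = "B"
    range_a: Optional[tuple[int, int]] = None
    range_b: Optional[tuple[int, int]] = None
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    energy_cutoff: float = 12.0
    energy_switch_on: float = 10.0
    sasa_probe: float = 1.4
    sasa_points: int = 960
    sasa_stride: int = 50
    loop1: Optional[tuple[str, int, int]] = None
    loop2: Optional[tuple[str, int, int]] = None
    strand_a: Optional[tuple[str, int, int]] = None
    strand_b: Optional[tuple[str, int, int]] = None
    steered_atom: Optional[tuple[str, int, str]] = None
    fixed_atom: Optional[tuple[str, int, str]] = None
    classify_epsilon: float = 0.05
    rupture_window: int = 11

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = raw.pop("criteria", None)
        cfg = cls(**{k: _tuplify(v) for k, v in raw.items()})
        if crit:
            cfg.criteria = HBondCriteria(**crit)
        return cfg

    def to_yaml(self, path: str) -> None:
        d = self.__dict__.copy()
        d["criteria"] = {
            "max_da_distance": self.criteria.max_da_distance,
            "max_dha_deviation": self.criteria.max_dha_deviation,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _interface_selections(structure: Structure, config: RunConfig):
    ra = config.range_a or structure.chains[config.chain_a]
    rb = config.range_b or structure.chains[config.chain_b]
    return (
        select(structure, config.chain_a, tuple(ra)),
        select(structure, config.chain_b, tuple(rb)),
    )


def _ca_selection(structure: Structure) -> Selection:
    idx = [i for i, a in enumerate(structure.atoms) if a.name == "CA"]
    return Selection(structure, tuple(idx), "calpha")


def _range_selection(structure: Structure, spec: tuple[str, int, int],
                     names: Optional[set[str]] = None) -> Selection:
    chain, lo, hi = spec
    return select(structure, chain, (lo, hi), names=names)


def _traj_hash(trajectory: Trajectory) -> str:
    return hashlib.sha1(
        np.ascontiguousarray(trajectory.frames).tobytes()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reference occupancy table
# ---------------------------------------------------------------------------


def load_reference_occupancies() -> pd.DataFrame:
    """The packaged reference interface-occupancy table.

    Twelve hydrogen-bonded residue pairs across the DNAM-1/CD155 interface
    with their equilibrium survival ratios (mean ± SD over three runs) for
    the wild-type complex and for the D2-deleted construct. Columns:
    ``no, receptor_residue, ligand_residue, wt_occupancy, wt_sd,
    dd2_occupancy, dd2_sd``.
    """
    path = resources.files("mechbond").joinpath("data/reference_occupancy.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def _residue_number(label: str) -> int:
    m = re.search(r"\d+", label)
    if not m:
        raise ValueError(f"cannot parse residue number from {label!r}")
    return int(m.group())


def _unique_numbers(labels: Sequence[str]) -> list[int]:
    """Map residue labels to unique integers, bumping duplicates upward."""
    used: set[int] = set()
    out = []
    for lab in labels:
        n = _residue_number(lab)
        while n in used:
            n += 1
        used.add(n)
        out.append(n)
    return out


def reference_bond_specs(system: str = "WT") -> list[BondSpec]:
    """Steady planted bonds whose occupancies mirror the reference table.

    ``system="WT"`` yields all 12 bonds at the wild-type occupancies;
    ``system="dD2"`` yields 11 bonds at the D2-deleted occupancies — the
    K190–E71 pair is dropped because residue 190 does not exist in the
    truncated receptor. Residue labels that appear twice in the table are
    mapped to the next free residue number so every planted bond has its
    own donor and acceptor residue; the original pair name is kept in the
    bond label.
    """
    df = load_reference_occupancies()
    if system == "dD2":
        df = df[df.receptor_residue != "K190"]
        col = "dd2_occupancy"
    elif system == "WT":
        col = "wt_occupancy"
    else:
        raise ConfigError(f"unknown system {system!r} (use 'WT' or 'dD2')")
    donors = _unique_numbers(list(df.receptor_residue))
    acceptors = _unique_numbers(list(df.ligand_residue))
    specs = []
    for (_, row), dseq, aseq in zip(df.iterrows(), donors, acceptors):
        specs.append(
            BondSpec(
                donor=("A", dseq, "N", "H"),
                acceptor=("B", aseq, "O"),
                mode="steady",
                baseline=float(row[col]),
                label=f"{row.receptor_residue}-{row.ligand_residue}",
            )
        )
    return specs


def reference_config(
    system: str = "WT", n_frames: int = 2000, seed: int = 0
) -> GeneratorConfig:
    """Generator configuration planted with the reference occupancies."""
    specs = reference_bond_specs(system)
    return GeneratorConfig(
        n_residues_per_chain=len(specs),
        bond_specs=specs,
        n_frames=n_frames,
        seed=seed,
        chain_a_numbering=sorted(s.donor[1] for s in specs),
        chain_b_numbering=sorted(s.acceptor[1] for s in specs),
    )


def truncate_chain(
    structure: Structure, chain: str, residue_range: tuple[int, int]
) -> Structure:
    """Keep only the given residue range of one chain (other chains intact).

    Models a domain-deletion construct: selections for residues outside the
    range will subsequently fail with an empty-selection error.
    """
    lo, hi = residue_range
    atoms = [
        a
        for a in structure.atoms
        if a.chain_id != chain or lo <= a.residue_seq <= hi
    ]
    return Structure(
        [
            Atom(
                a.serial, a.name, a.element, a.residue_seq, a.residue_name,
                a.chain_id, a.position.copy(), a.charge, a.lj_epsilon,
                a.lj_rmin_half,
            )
            for a in atoms
        ]
    )


# ---------------------------------------------------------------------------
# per-replicate metric extraction
# ---------------------------------------------------------------------------


def _replicate_metrics(
    trajectory: Trajectory, config: RunConfig
) -> tuple[dict[str, float], OccupancyTable, np.ndarray]:
    """Scalar metrics, the occupancy table and the N_HB series of one run."""
    structure = trajectory.topology
    sel_a, sel_b = _interface_selections(structure, config)
    occ = occupancy(trajectory, sel_a, sel_b, config.criteria)
    n_hb = hbond_count_series(trajectory, sel_a, sel_b, config.criteria)
    ca = _ca_selection(structure)
    rmsd = rmsd_series(trajectory, 0, ca)
    stride = max(1, config.sasa_stride)
    sasa_vals = [
        buried_sasa(
            trajectory.frames[k], sel_a, sel_b,
            config.sasa_probe, config.sasa_points,
        )
        for k in range(0, len(trajectory), stride)
    ]
    energies = [
        interaction_energy(
            frame, sel_a, sel_b, config.energy_cutoff, config.energy_switch_on
        ).total
        for frame in trajectory.frames
    ]
    fd = dissociation_probability([r.occupancy for r in occ.rows]) \
        if occ.rows else 1.0
    metrics = {
        "rmsd": float(np.mean(rmsd.values)),
        "n_hb": float(np.mean(n_hb)),
        "buried_sasa": float(np.mean(sasa_vals)),
        "energy": float(np.mean(energies)),
        "fd": float(fd),
    }
    return metrics, occ, n_hb


EQUILIBRIUM_METRICS = ("rmsd", "n_hb", "buried_sasa", "energy", "fd")


@dataclass
class SystemSummary:
    """Replicate-aggregated metrics for one system."""

    label: str
    n_replicates: int
    replicate_metrics: dict[str, list[float]]
    occupancy: OccupancyTable

    def mean(self, metric: str) -> float:
        return float(np.mean(self.replicate_metrics[metric]))

    def sd(self, metric: str) -> float:
        v = self.replicate_metrics[metric]
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_replicates": self.n_replicates,
            "metrics": {
                m: {"mean": self.mean(m), "sd": self.sd(m),
                    "replicates": list(self.replicate_metrics[m])}
                for m in sorted(self.replicate_metrics)
            },
            "occupancy": self.occupancy.to_dict(),
        }


@dataclass
class EquilibriumReport:
    systems: dict[str, SystemSummary]
    pvalues: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "systems": {k: v.to_dict() for k, v in sorted(self.systems.items())},
            "pvalues": dict(sorted(self.pvalues.items())),
        }

    def write(self, prefix: str) -> list[str]:
        os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
        written = []
        for label, summary in sorted(self.systems.items()):
            path = f"{prefix}_occupancy_{label}.tsv"
            summary.occupancy.to_tsv(path)
            written.append(path)
        path = f"{prefix}_equilibrium.json"
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)
        return written


def run_equilibrium_analysis(
    trajectories: dict[str, Sequence[Trajectory]], config: RunConfig
) -> EquilibriumReport:
    """Compare systems over replicate equilibrium trajectories.

    For each system: mean Cα-RMSD, aggregated occupancy table (mean ± SD
    per pair, a missing pair counting as 0), mean N_HB, mean buried SASA,
    mean interaction energy and fD, each mean ± SD over replicates. With
    exactly two systems, unpaired two-tailed t-test p-values are attached
    per metric.
    """
    if not trajectories:
        raise ConfigError("no systems supplied")
    systems: dict[str, SystemSummary] = {}
    for label in sorted(trajectories):
        runs = list(trajectories[label])
        if not runs:
            raise ConfigError(f"system {label!r} has no trajectories")
        per_metric: dict[str, list[float]] = {m: [] for m in EQUILIBRIUM_METRICS}
        tables = []
        for rep, traj in enumerate(runs):
            logger.info(
                "stage=equilibrium system=%s force=0 replicate=%d hash=%s",
                label, rep, _traj_hash(traj),
            )
            metrics, occ, _ = _replicate_metrics(traj, config)
            for m, v in metrics.items():
                per_metric[m].append(v)
            tables.append(occ)
        systems[label] = SystemSummary(
            label=label,
            n_replicates=len(runs),
            replicate_metrics=per_metric,
            occupancy=aggregate_occupancy(tables, condition=label),
        )
    pvalues: dict[str, float] = {}
    labels = sorted(systems)
    if len(labels) == 2:
        a, b = labels
        for m in EQUILIBRIUM_METRICS:
            va = systems[a].replicate_metrics[m]
            vb = systems[b].replicate_metrics[m]
            if len(va) >= 2 and len(vb) >= 2:
                pvalues[m] = compare_replicates(va, vb, method="t")
    return EquilibriumReport(systems, pvalues)


# ---------------------------------------------------------------------------
# force-clamp campaign
# ---------------------------------------------------------------------------


@dataclass
class ClampReport:
    profiles: dict[str, ForceResponseProfile]
    thresholds: dict[str, BiphasicResult]
    thermograph: pd.DataFrame  # pair label × force occupancies + mode column
    gaussian_fits: dict[float, Optional[GaussianFit]]
    occupancy_by_force: dict[float, OccupancyTable]

    def to_dict(self) -> dict:
        return {
            "profiles": {k: v.to_dict() for k, v in sorted(self.profiles.items())},
            "thresholds": {
                k: {
                    "thresholds": [list(t) for t in v.thresholds],
                    "monotone": v.monotone,
                    "biphasic": v.biphasic,
                }
                for k, v in sorted(self.thresholds.items())
            },
            "thermograph": self.thermograph.to_dict(orient="index"),
            "gaussian_fits": {
                repr(float(f)): (
                    None
                    if g is None
                    else {"mean": g.mean, "sigma": g.sigma,
                          "amplitude": g.amplitude, "rss": g.rss}
                )
                for f, g in sorted(self.gaussian_fits.items())
            },
        }

    def write(self, prefix: str) -> list[str]:
        os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
        written = []
        for name, profile in sorted(self.profiles.items()):
            path = f"{prefix}_profile_{name}.tsv"
            profile.to_tsv(path)
            written.append(path)
        path = f"{prefix}_thermograph.tsv"
        self.thermograph.to_csv(path, sep="\t")
        written.append(path)
        path = f"{prefix}_clamp.json"
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)
        return written


def run_force_clamp_analysis(
    trajectories: dict[float, Sequence[Trajectory]], config: RunConfig
) -> ClampReport:
    """Force-response profiles, thresholds, thermograph and Gaussian fits.

    ``trajectories`` maps each clamp force (pN) to its replicate runs. The
    force grid must have at least 3 levels. DMC and κ profiles are included
    when the config defines loop and strand selections.
    """
    forces = sorted(trajectories)
    if len(forces) < 3:
        raise ConfigError("need at least 3 force levels")
    metric_reps: dict[str, list[list[float]]] = {
        m: [] for m in ("energy", "n_hb", "fd", "dmc", "kappa")
    }
    occupancy_by_force: dict[float, OccupancyTable] = {}
    gaussian_fits: dict[float, Optional[GaussianFit]] = {}
    for force in forces:
        runs = list(trajectories[force])
        if not runs:
            raise ConfigError(f"force {force} has no trajectories")
        per_force = {m: [] for m in metric_reps}
        tables = []
        pooled_nhb: list[np.ndarray] = []
        for rep, traj in enumerate(runs):
            logger.info(
                "stage=clamp system=%s force=%s replicate=%d hash=%s",
                config.label, force, rep, _traj_hash(traj),
            )
            structure = traj.topology
            sel_a, sel_b = _interface_selections(structure, config)
            occ = occupancy(traj, sel_a, sel_b, config.criteria)
            tables.append(occ)
            n_hb = hbond_count_series(traj, sel_a, sel_b, config.criteria)
            pooled_nhb.append(n_hb)
            per_force["n_hb"].append(float(np.mean(n_hb)))
            per_force["fd"].append(
                dissociation_probability([r.occupancy for r in occ.rows])
                if occ.rows
                else 1.0
            )
            energies = [
                interaction_energy(
                    frame, sel_a, sel_b,
                    config.energy_cutoff, config.energy_switch_on,
                ).total
                for frame in traj.frames
            ]
            per_force["energy"].append(float(np.mean(energies)))
            if config.loop1 and config.loop2:
                s = dmc_series(
                    traj,
                    _range_selection(structure, config.loop1),
                    _range_selection(structure, config.loop2),
                )
                per_force["dmc"].append(float(np.mean(s.values)))
            if config.strand_a and config.strand_b:
                s = cross_angle_series(
                    traj,
                    _range_selection(structure, config.strand_a, {"CA"}),
                    _range_selection(structure, config.strand_b, {"CA"}),
                )
                per_force["kappa"].append(float(np.mean(s.values)))
        occupancy_by_force[force] = aggregate_occupancy(
            tables, condition=f"{force}pN"
        )
        counts = np.concatenate(pooled_nhb)
        bins = np.arange(counts.min(), counts.max() + 1)
        freqs = np.array([(counts == b).sum() for b in bins], dtype=float)
        try:
            gaussian_fits[force] = fit_gaussian(bins, freqs)
        except (ValueError,) as exc:
            logger.info("gaussian fit skipped at %s pN: %s", force, exc)
            gaussian_fits[force] = None
        for m in metric_reps:
            if per_force[m]:
                metric_reps[m].append(per_force[m])
    profiles: dict[str, ForceResponseProfile] = {}
    thresholds: dict[str, BiphasicResult] = {}
    for m, reps in metric_reps.items():
        if len(reps) == len(forces):
            profile = ForceResponseProfile(m, np.array(forces), reps)
            profiles[m] = profile
            thresholds[m] = biphasic_threshold(profile)
    # thermograph: pair label × force mean occupancy, with a mode column
    pair_labels: dict[tuple, str] = {}
    for table in occupancy_by_force.values():
        for r in table.rows:
            pair_labels.setdefault(r.pair, r.label)
    rows = {}
    for pair in sorted(pair_labels):
        occ_by_f = []
        for force in forces:
            r = occupancy_by_force[force].get(pair)
            occ_by_f.append(r.occupancy if r is not None else 0.0)
        mode = classify_mode(occ_by_f, config.classify_epsilon)
        rows[pair_labels[pair]] = {
            **{f"{force}pN": o for force, o in zip(forces, occ_by_f)},
            "mode": mode.label,
            "pattern": mode.pattern,
        }
    thermograph = pd.DataFrame.from_dict(rows, orient="index")
    thermograph.index.name = "pair"
    return ClampReport(
        profiles, thresholds, thermograph, gaussian_fits, occupancy_by_force
    )


# ---------------------------------------------------------------------------
# force-ramp campaign
# ---------------------------------------------------------------------------


@dataclass
class RampReport:
    series: dict[str, np.ndarray]
    time: np.ndarray
    rupture: RuptureResult

    def to_dict(self) -> dict:
        """Summary only; the full per-frame series live in the TSV export."""
        return {
            "n_frames": int(len(self.time)),
            "time_span_ns": [float(self.time[0]), float(self.time[-1])],
            "series_summary": {
                k: {
                    "mean": float(np.mean(v)),
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                }
                for k, v in sorted(self.series.items())
            },
            "rupture": {
                "force_pN": self.rupture.force,
                "frame": self.rupture.frame,
                "dissociated": self.rupture.dissociated,
            },
        }

    def write(self, prefix: str) -> list[str]:
        os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
        df = pd.DataFrame({"time_ns": self.time, **self.series})
        path = f"{prefix}_ramp_series.tsv"
        df.to_csv(path, sep="\t", index=False)
        jpath = f"{prefix}_ramp.json"
        with open(jpath, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return [path, jpath]


def run_ramp_analysis(
    trajectory: Trajectory, trace: ForceTrace, config: RunConfig
) -> RampReport:
    """Force-ramp time series and rupture force.

    The trace must align 1:1 with the trajectory frames. If the trace does
    not carry an interface bond count, it is computed from the trajectory
    so the rupture search can stop at dissociation.
    """
    if len(trace) != len(trajectory):
        raise ConfigError(
            f"trace length {len(trace)} != trajectory length {len(trajectory)}"
        )
    logger.info(
        "stage=ramp system=%s force=ramp replicate=0 hash=%s",
        config.label, _traj_hash(trajectory),
    )
    structure = trajectory.topology
    sel_a, sel_b = _interface_selections(structure, config)
    n_hb = (
        np.asarray(trace.n_hb)
        if trace.n_hb is not None
        else hbond_count_series(trajectory, sel_a, sel_b, config.criteria)
    )
    full_trace = ForceTrace(trace.time, trace.force, n_hb)
    stride = max(1, config.sasa_stride)
    sasa_idx = np.arange(0, len(trajectory), stride)
    sasa_vals = np.array(
        [
            buried_sasa(
                trajectory.frames[k], sel_a, sel_b,
                config.sasa_probe, config.sasa_points,
            )
            for k in sasa_idx
        ]
    )
    # hold the strided SASA constant between evaluation points
    sasa_series = np.repeat(sasa_vals, stride)[: len(trajectory)]
    ca = _ca_selection(structure)
    rmsd = rmsd_series(trajectory, 0, ca).values
    series = {
        "force_pN": np.asarray(trace.force, dtype=float),
        "n_hb": n_hb.astype(float),
        "buried_sasa": sasa_series,
        "rmsd": rmsd,
    }
    if config.steered_atom and config.fixed_atom:
        series["pull_distance"] = pull_distance_series(
            trajectory, config.steered_atom, config.fixed_atom
        ).values
    rupture = rupture_force(full_trace, config.rupture_window)
    return RampReport(series, np.asarray(trace.time, dtype=float), rupture)
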