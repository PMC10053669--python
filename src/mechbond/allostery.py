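"""Conformational and mechanical observables along a trajectory.

RMSD after optimal superposition, steered–fixed atom distance, the
distance between loop mass centres (DMC), the cross-angle between two
β-strand axes (κ), and rupture-force extraction from a force–time trace.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .model import Selection, SelectionError, Trajectory
from .params import ATOMIC_MASSES

__all__ = [
    "AllosterySeries",
    "ForceTrace",
    "RuptureResult",
    "rmsd_series",
    "pull_distance_series",
    "dmc",
    "dmc_series",
    "cross_angle",
    "cross_angle_series",
    "mass_center",
    "rupture_force",
]


@dataclass
class AllosterySeries:
    """A named per-frame scalar series (Å or degrees)."""

    metric: str
    values: np.ndarray
    selection_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def name(self) -> str:
        return self.metric

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["frame", self.metric])
            for i, v in enumerate(self.values):
                w.writerow([i, repr(float(v))])

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "values": [float(v) for v in self.values],
            "selections": list(self.selection_labels),
        }


@dataclass
class ForceTrace:
    """A (time, force) trace, optionally with a per-frame interface N_HB."""

    time: np.ndarray  # ns
    force: np.ndarray  # pN
    n_hb: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time must be strictly increasing")
        if self.n_hb is not None:
            self.n_hb = np.asarray(self.n_hb)
            if self.n_hb.shape != self.time.shape:
                raise ValueError("n_hb must have one entry per trace point")

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_tsv(cls, path: str) -> "ForceTrace":
        """Read a 2–3 column TSV (time_ns, force_pN[, n_hb])."""
        df = pd.read_csv(path, sep="\t")
        n_hb = df["n_hb"].to_numpy() if "n_hb" in df.columns else None
        return cls(df["time_ns"].to_numpy(), df["force_pN"].to_numpy(), n_hb)

    def to_tsv(self, path: str) -> None:
        cols = {"time_ns": self.time, "force_pN": self.force}
        if self.n_hb is not None:
            cols["n_hb"] = self.n_hb
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


class RuptureResult(NamedTuple):
    force: float  # pN, smoothed peak
    frame: int  # index of the peak in the trace
    dissociated: bool  # whether the interface N_HB reached zero


def _resolve_selection_coords(trajectory: Trajectory, selection: Selection):
    if selection.structure is not trajectory.topology:
        raise SelectionError("selection does not belong to the trajectory topology")
    return trajectory.frames[:, selection.index_array, :]


def rmsd_series(
    trajectory: Trajectory,
    reference: Union[int, np.ndarray],
    selection: Selection,
) -> AllosterySeries:
    """Least-squares-superposed RMSD of a selection against a reference.

    Each frame is optimally superposed on the reference (rotation +
    translation, Kabsch) before the RMSD over the selected atoms is taken,
    so the series is invariant under rigid motion of any frame.

    ``reference`` is a frame index or an (n_atoms, 3) full-structure
    coordinate array.
    """
    X = _resolve_selection_coords(trajectory, selection)  # (F, n, 3)
    if isinstance(reference, (int, np.integer)):
        ref = X[int(reference)]
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (len(trajectory.topology), 3):
            raise SelectionError(
                "reference must be a frame index or full-structure coordinates"
            )
        ref = reference[selection.index_array]
    n = X.shape[1]
    ref_c = ref - ref.mean(axis=0)
    Xc = X - X.mean(axis=1, keepdims=True)
    # Kabsch via the trace formula: rmsd² = (|X|² + |Y|² − 2(σ1+σ2±σ3)) / n
    C = np.einsum("fni,nj->fij", Xc, ref_c)
    s = np.linalg.svd(C, compute_uv=False)
    sign = np.sign(np.linalg.det(C))
    sign[sign == 0] = 1.0
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    sq = (Xc**2).sum(axis=(1, 2)) + (ref_c**2).sum() - 2.0 * trace
    vals = np.sqrt(np.maximum(sq, 0.0) / n)
    return AllosterySeries("rmsd", vals, (selection.label,))


def pull_distance_series(
    trajectory: Trajectory,
    steered_atom: tuple[str, int, str],
    fixed_atom: tuple[str, int, str],
) -> AllosterySeries:
    """Euclidean steered–fixed atom distance per frame (Å).

    Atoms are addressed as (chain, residue_seq, atom name).
    """
    i = trajectory.topology.atom_index(*steered_atom)
    j = trajectory.topology.atom_index(*fixed_atom)
    vals = np.linalg.norm(
        trajectory.frames[:, i, :] - trajectory.frames[:, j, :], axis=1
    )
    return AllosterySeries(
        "pull_distance", vals, (":".join(map(str, steered_atom)),
                                ":".join(map(str, fixed_atom)))
    )


def _masses(selection: Selection) -> np.ndarray:
    m = np.empty(len(selection))
    for k, a in enumerate(selection.atoms()):
        m[k] = ATOMIC_MASSES.get(a.element.upper(), 12.011)
    return m


def mass_center(frame: np.ndarray, selection: Selection,
                mass_weighted: bool = True) -> np.ndarray:
    coords = np.asarray(frame, dtype=float)[selection.index_array]
    if mass_weighted:
        m = _masses(selection)
        return (coords * m[:, None]).sum(axis=0) / m.sum()
    return coords.mean(axis=0)


def dmc(
    frame: np.ndarray,
    loop1: Selection,
    loop2: Selection,
    mass_weighted: bool = True,
) -> float:
    """Distance between the mass centres of two loop selections (Å).

    Symmetric in its arguments and translation-invariant. With
    ``mass_weighted=False`` the geometric centroid is used instead.
    """
    c1 = mass_center(frame, loop1, mass_weighted)
    c2 = mass_center(frame, loop2, mass_weighted)
    return float(np.linalg.norm(c1 - c2))


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise SelectionError("degenerate strand: all atoms coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def cross_angle(
    frame: np.ndarray,
    strand_a: Selection,
    strand_b: Selection,
    folded: bool = True,
) -> float:
    """Angle between the principal axes of two Cα strand selections.

    The axis of each strand is the first principal component of its
    coordinates. By default the angle is folded to [0°, 90°]
    (arccos of the absolute unit dot product), making the metric
    orientation-free; ``folded=False`` returns the raw [0°, 180°] angle,
    which preserves signed trends along a trajectory.
    """
    if len(strand_a) < 3 or len(strand_b) < 3:
        raise SelectionError("each strand needs at least 3 atoms")
    frame = np.asarray(frame, dtype=float)
    u = _principal_axis(frame[strand_a.index_array])
    v = _principal_axis(frame[strand_b.index_array])
    dot = float(np.dot(u, v))
    if folded:
        dot = abs(dot)
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


def dmc_series(
    trajectory: Trajectory,
    loop1: Selection,
    loop2: Selection,
    mass_weighted: bool = True,
) -> AllosterySeries:
    """Per-frame DMC between two loop selections (vectorised)."""
    c1 = _resolve_selection_coords(trajectory, loop1)
    c2 = _resolve_selection_coords(trajectory, loop2)
    if mass_weighted:
        m1 = _masses(loop1)
        m2 = _masses(loop2)
        mc1 = (c1 * m1[None, :, None]).sum(axis=1) / m1.sum()
        mc2 = (c2 * m2[None, :, None]).sum(axis=1) / m2.sum()
    else:
        mc1 = c1.mean(axis=1)
        mc2 = c2.mean(axis=1)
    vals = np.linalg.norm(mc1 - mc2, axis=1)
    return AllosterySeries("dmc", vals, (loop1.label, loop2.label))


def cross_angle_series(
    trajectory: Trajectory,
    strand_a: Selection,
    strand_b: Selection,
    folded: bool = True,
) -> AllosterySeries:
    """Per-frame cross-angle κ between two strand axes."""
    vals = np.array(
        [
            cross_angle(frame, strand_a, strand_b, folded)
            for frame in trajectory.frames
        ]
    )
    return AllosterySeries("kappa", vals, (strand_a.label, strand_b.label))


def rupture_force(trace: ForceTrace, window: int = 11) -> RuptureResult:
    """Rupture force from a force–time trace (pN).

    The force series is smoothed with a centred moving average of
    ``window`` points; the rupture force is the global maximum of the
    smoothed series restricted to times before the interface hydrogen-bond
    count first reaches zero (when the trace carries one). If the interface
    never dissociates, a warning is issued and the global smoothed maximum
    is returned with ``dissociated=False``.
    """
    if len(trace) < window:
        raise ValueError(f"trace shorter than smoothing window ({window})")
    smoothed = (
        pd.Series(trace.force)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    dissociated = False
    stop = len(smoothed)
    if trace.n_hb is not None:
        zeros = np.nonzero(np.asarray(trace.n_hb) == 0)[0]
        if len(zeros):
            dissociated = True
            stop = max(int(zeros[0]), 1)
    if not dissociated:
        warnings.warn(
            "interface never dissociated; returning global smoothed maximum",
            stacklevel=2,
        )
    peak = int(np.argmax(smoothed[:stop]))
    return RuptureResult(float(smoothed[peak]), peak, dissociated)
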