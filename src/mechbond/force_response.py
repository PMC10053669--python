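"""Force-regulation statistics.

Dissociation probability from per-bond occupancies, force-response
profiles with replicate spread, biphasic-threshold detection, Gaussian
fitting of hydrogen-bond count frequencies, the five-mode catch/slip
classification and thin replicate-comparison plumbing.

The dissociation probability fD is the probability that *no* interfacial
hydrogen bond is formed, computed under the assumption that bonding events
are independent:

    fD = Π_i (1 − oᵢ)

where oᵢ is the occupancy of bond i. This is the unique joint-absence
probability consistent with the independence assumption; it is monotone
non-increasing in every occupancy and in the number of bonds.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .model import FitError

__all__ = [
    "ForceResponseProfile",
    "ModeLabel",
    "GaussianFit",
    "BiphasicResult",
    "dissociation_probability",
    "normalize_fd",
    "biphasic_threshold",
    "classify_mode",
    "fit_gaussian",
    "compare_replicates",
]

MODE_NAMES = (
    "steady",
    "catch_slip",
    "slip_catch",
    "catch_slip_catch",
    "slip_catch_slip",
)


@dataclass
class ForceResponseProfile:
    """A metric sampled over an ordered force grid with replicate spread."""

    metric: str
    forces: np.ndarray  # pN, strictly increasing
    replicate_values: list[np.ndarray]  # one array of replicates per force

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if len(self.forces) != len(self.replicate_values):
            raise ValueError("one replicate set required per force level")
        if len(self.forces) > 1 and not np.all(np.diff(self.forces) > 0):
            raise ValueError("force grid must be strictly increasing")
        self.replicate_values = [
            np.atleast_1d(np.asarray(v, dtype=float)) for v in self.replicate_values
        ]
        if any(len(v) < 1 for v in self.replicate_values):
            raise ValueError("each force level needs at least one replicate")

    @property
    def name(self) -> str:
        return self.metric

    @property
    def mean(self) -> np.ndarray:
        return np.array([v.mean() for v in self.replicate_values])

    @property
    def sem(self) -> np.ndarray:
        out = np.empty(len(self.forces))
        for i, v in enumerate(self.replicate_values):
            out[i] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        return out

    def to_tsv(self, path: str) -> None:
        nrep = max(len(v) for v in self.replicate_values)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["force_pN"]
                + [f"rep{i + 1}" for i in range(nrep)]
                + ["mean", "sem"]
            )
            for f, v, m, s in zip(
                self.forces, self.replicate_values, self.mean, self.sem
            ):
                reps = [repr(float(x)) for x in v] + [""] * (nrep - len(v))
                w.writerow([repr(float(f))] + reps + [repr(float(m)), repr(float(s))])

    @classmethod
    def from_tsv(cls, path: str, metric: str = "") -> "ForceResponseProfile":
        forces, reps = [], []
        with open(path, newline="") as fh:
            rd = csv.reader(fh, delimiter="\t")
            header = next(rd)
            rep_cols = [i for i, h in enumerate(header) if h.startswith("rep")]
            for rec in rd:
                forces.append(float(rec[0]))
                reps.append(
                    np.array([float(rec[i]) for i in rep_cols if rec[i] != ""])
                )
        return cls(metric or "profile", np.array(forces), reps)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "forces": [float(f) for f in self.forces],
            "replicates": [[float(x) for x in v] for v in self.replicate_values],
            "mean": [float(m) for m in self.mean],
            "sem": [float(s) for s in self.sem],
        }


@dataclass(frozen=True)
class ModeLabel:
    """Force-response mode of one bond, with its collapsed sign pattern."""

    label: str  # one of MODE_NAMES or "complex"
    pattern: str  # collapsed sign pattern, e.g. "+-"
    epsilon: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian fit to a bond-count frequency histogram."""

    mean: float
    sigma: float
    amplitude: float
    rss: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class BiphasicResult:
    """Interior extrema of a force-response mean curve.

    ``thresholds`` holds (force, "min"|"max") for each interior extremum.
    A clean biphasic profile has exactly one; monotone profiles have none;
    more than one is flagged non-biphasic.
    """

    thresholds: tuple[tuple[float, str], ...]
    monotone: bool

    @property
    def biphasic(self) -> bool:
        return len(self.thresholds) == 1

    @property
    def threshold(self) -> Optional[tuple[float, str]]:
        return self.thresholds[0] if self.biphasic else None


def dissociation_probability(occupancies: Sequence[float]) -> float:
    """Probability that no interfacial bond is formed: fD = Π(1 − oᵢ).

    An empty occupancy list means no bonds exist, hence certain
    dissociation: returns 1 with a warning.
    """
    occ = np.asarray(list(occupancies), dtype=float)
    if occ.size == 0:
        warnings.warn("no bonds supplied; fD = 1 (certain dissociation)",
                      stacklevel=2)
        return 1.0
    if np.any((occ < 0) | (occ > 1)):
        raise ValueError("occupancies must lie in [0, 1]")
    return float(np.prod(1.0 - occ))


def normalize_fd(
    profile: ForceResponseProfile, reference_force: Optional[float] = None
) -> ForceResponseProfile:
    """Normalise an fD profile by its reference condition.

    Every replicate value is divided by the reference *mean* (the first
    force level by default, or a named force on the grid), so the reference
    maps to 1. Raises if the reference fD is zero.
    """
    if reference_force is None:
        ref_idx = 0
    else:
        hits = np.nonzero(np.isclose(profile.forces, reference_force))[0]
        if not len(hits):
            raise ValueError(f"force {reference_force} not on the profile grid")
        ref_idx = int(hits[0])
    ref = profile.mean[ref_idx]
    if ref == 0:
        raise ZeroDivisionError(
            "reference fD is 0; normalisation is undefined"
        )
    return ForceResponseProfile(
        f"{profile.metric}_normalized",
        profile.forces.copy(),
        [v / ref for v in profile.replicate_values],
    )


def biphasic_threshold(profile: ForceResponseProfile) -> BiphasicResult:
    """Locate interior extrema of the replicate-mean curve on the force grid.

    Thresholds are reported on the grid only (no interpolation). Plateaus
    are skipped when deciding the sign of a trend.
    """
    m = profile.mean
    f = profile.forces
    if len(f) < 3:
        raise ValueError("need at least 3 force levels")
    signs = []  # (sign, index of the point ending the run)
    for i in range(len(m) - 1):
        d = m[i + 1] - m[i]
        if d != 0:
            signs.append((1 if d > 0 else -1, i + 1))
    thresholds = []
    for (s1, i1), (s2, _) in zip(signs, signs[1:]):
        if s1 != s2:
            kind = "max" if s1 > 0 else "min"
            thresholds.append((float(f[i1 - 0]), kind))
    # i1 is the index where the first run ends = the extremum grid point
    monotone = len({s for s, _ in signs}) <= 1
    return BiphasicResult(tuple(thresholds), monotone)


def classify_mode(
    occupancy_by_force: Sequence[float], epsilon: float = 0.05
) -> ModeLabel:
    """Classify a bond's occupancy-vs-force shape into the five modes.

    Successive differences along the ordered force grid are mapped to
    signs (+ if Δ > ε, − if Δ < −ε, 0 otherwise); zeros are dropped and
    consecutive equal signs collapsed. The collapsed pattern maps to:

    ========  ==========================================
    pattern   label
    ========  ==========================================
    ""        steady
    "+-","+"  catch_slip   ("+" flagged pure_catch)
    "-+","-"  slip_catch   ("−" flagged pure_slip)
    "+-+"     catch_slip_catch
    "-+-"     slip_catch_slip
    longer    complex (raw pattern preserved)
    ========  ==========================================
    """
    vals = np.asarray(list(occupancy_by_force), dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 force levels to classify")
    diffs = np.diff(vals)
    raw = ["+" if d > epsilon else "-" if d < -epsilon else "0" for d in diffs]
    collapsed = []
    for s in raw:
        if s == "0":
            continue
        if not collapsed or collapsed[-1] != s:
            collapsed.append(s)
    pattern = "".join(collapsed)
    flags: tuple[str, ...] = ()
    if pattern == "":
        label = "steady"
    elif pattern == "+-":
        label = "catch_slip"
    elif pattern == "+":
        label, flags = "catch_slip", ("pure_catch",)
    elif pattern == "-+":
        label = "slip_catch"
    elif pattern == "-":
        label, flags = "slip_catch", ("pure_slip",)
    elif pattern == "+-+":
        label = "catch_slip_catch"
    elif pattern == "-+-":
        label = "slip_catch_slip"
    else:
        label = "complex"
    return ModeLabel(label, pattern, epsilon, flags)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(
    counts: Sequence[float], frequencies: Sequence[float]
) -> GaussianFit:
    """Least-squares Gaussian fit to a bond-count frequency curve.

    ``counts`` are the (integer) bond counts, ``frequencies`` their
    observed frequencies. Initial values come from sample moments. Needs at
    least 4 distinct counts with nonzero frequency; non-convergence raises
    :class:`FitError` carrying the moment-based fallback.
    """
    x = np.asarray(list(counts), dtype=float)
    y = np.asarray(list(frequencies), dtype=float)
    if x.shape != y.shape:
        raise ValueError("counts and frequencies must align")
    support = np.nonzero(y > 0)[0]
    if len(np.unique(x[support])) < 4:
        raise ValueError(
            "need at least 4 distinct counts with nonzero frequency"
        )
    w = y[support] / y[support].sum()
    mu0 = float(np.sum(x[support] * w))
    sig0 = float(np.sqrt(np.sum(w * (x[support] - mu0) ** 2)))
    sig0 = max(sig0, 0.5)
    amp0 = float(y.max())
    fallback = GaussianFit(mu0, sig0, amp0, float("nan"))
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=[amp0, mu0, sig0], maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}",
                       fallback=fallback) from exc
    amp, mu, sigma = popt
    sigma = abs(float(sigma))
    rss = float(np.sum((y - _gauss(x, amp, mu, sigma)) ** 2))
    return GaussianFit(float(mu), sigma, float(amp), rss)


def compare_replicates(
    group_a: Sequence[float], group_b: Sequence[float], method: str = "t"
) -> float:
    """Two-sample p-value between replicate groups.

    ``method="t"`` is the unpaired equal-variance (Student's) t test;
    ``method="tukey"`` uses Tukey's honestly-significant-difference test on
    the two groups. Degenerate zero-variance groups with equal means give
    p = 1; zero variance with different means gives p = 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if method == "t":
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if method == "tukey":
        return float(stats.tukey_hsd(a, b).pvalue[0, 1])
    raise ValueError(f"unknown method {method!r}")
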