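# Methods

This note documents the models, conventions and numerical choices behind
`mechbond`, and what the synthetic ground truth does and does not show
about real trajectories.

## Hydrogen-bond model

A hydrogen bond exists in a frame when the donor–acceptor heavy-atom
distance is below `max_da_distance` (default 3.5 Å) **and** the D–H–A
angle deviates from linearity by less than `max_dha_deviation` (default
30°, i.e. ∠D–H–A ≥ 150°). The deviation-from-linearity reading of the
angle criterion follows the convention of the common visual-analysis
tools; it is configurable because other packages quote the complementary
angle. Donor chemistry is deliberately simple and table-driven: N and O
heavy atoms with a covalently attached hydrogen (within `max_dh_bond`,
default 1.25 Å, same residue) are donors; N and O are acceptors. Both
donor→acceptor directions across an interface are examined and each
qualifying (donor, H, acceptor) triple is counted once.

Structures must carry explicit hydrogens. A structure with none raises
`MissingHydrogenError` rather than placing hydrogens implicitly — implicit
placement would silently change the science. An N or O without an attached
hydrogen is simply not a donor (it can still accept).

**Occupancy** (survival ratio) of a residue pair is the fraction of frames
in which at least one qualifying bond connects the two residues; several
simultaneous atom-level bonds between the same residues collapse to one
event, because published survival-rate tables are residue-pair granular.
Pairs that never bond are omitted from tables; when replicate tables are
aggregated, a pair missing from one replicate contributes occupancy 0
there. Hydrogen attachment for trajectory-level statistics is resolved
once on the topology coordinates — covalent attachment is a topological
property, not a per-frame one.

**Salt bridges** pair side-chain carboxylate oxygens of Asp/Glu
(OD1/OD2/OE1/OE2) with side-chain basic nitrogens of Lys (NZ) and Arg
(NE/NH1/NH2) within 4 Å. Backbone oxygens and nitrogens are excluded by
default (the residue-class tables are arguments, so a broader reading is
one call away); one contact is reported per residue pair per frame with
its minimum O–N distance.

## Dissociation probability fD

Per-bond occupancies oᵢ are treated as marginal probabilities of
independent bonding events, so the probability that *no* interfacial bond
is formed — the dissociation probability — is

    fD = Πᵢ (1 − oᵢ).

This is the unique joint-absence probability consistent with the
independence assumption. It is monotone non-increasing in every oᵢ and in
the number of bonds; any permanently occupied bond forces fD = 0, and an
empty bond set gives fD = 1 (with a warning). Tests verify the product
against a 10⁵-draw Monte-Carlo joint simulation. `normalize_fd` divides a
profile by the mean of a reference condition (first force level by
default, or a named force), so the reference maps to 1; a zero reference
is an error, since the normalisation is then undefined. Independence is
an approximation: bonds sharing a residue or a loaded strand are
correlated in real interfaces, so fD is best read as a comparative
mechano-regulation factor, not an absolute off-rate.

## Surface area and interaction energy

SASA uses the Shrake–Rupley method with a 1.4 Å water probe and a
**deterministic golden-section spiral** point set (default 960
points/atom), making values bit-reproducible for a fixed point count; a
960-point sphere reproduces an isolated atom's analytic area within 1%.
Atom radii come from an element-keyed van der Waals table (Bondi-style;
hydrogens included at 1.2 Å). Buried SASA is two-sided —
SASA(A) + SASA(B) − SASA(AB) — which is symmetric and non-negative up to
quadrature error. Only the atoms of a selection occlude each other; this
"isolated molecule" convention is exactly what the difference formula
requires.

Interaction energy is a plain cross-selection nonbonded sum: Coulomb
k·qᵢqⱼ/r with k = 332.0636 kcal·Å·mol⁻¹·e⁻², plus 12-6 Lennard-Jones with
Lorentz–Berthelot combination, both scaled by a CHARMM-style switching
function active over 10–12 Å so the energy is continuous at the cutoff.
No Ewald summation or reaction field is applied: cross-selection lattice
electrostatics are not well defined for an isolated interface, and the
pipeline uses E for rankings and force-response trends, not absolute
binding free energies. Absolute values therefore differ from what a
periodic-boundary MD engine would report for the same frames.

## Allostery metrics

* **RMSD**: each frame is optimally superposed on the reference
  (least-squares rotation + translation) before the RMSD over the selected
  atoms is computed, via the Kabsch singular-value trace formula with the
  usual determinant sign correction; the series is invariant under rigid
  motion of any frame to ≤ 10⁻⁶ Å.
* **DMC**: distance between the mass centres of two loop selections,
  mass-weighted by default because the quantity is defined as a
  mass-centre distance; a geometric-centroid option exists. Typical loop
  choices for the reference complex are residues 72–79 of the receptor's
  first domain and 53–59 of the ligand.
* **Cross-angle κ**: the axis of each β-strand is the first principal
  component of its Cα coordinates (≥ 3 required); the angle between the
  two axes is folded to [0°, 90°] via |cos| so the metric is
  orientation-free. The raw [0°, 180°] angle is exposed (`folded=False`)
  for users tracking signed trends. Strand residue ranges are user
  configuration — the package does not auto-assign secondary structure.
* **Rupture force**: the force trace is smoothed with a centred moving
  average (default 11 points) and the rupture force is the smoothed
  maximum restricted to times before the interface bond count first
  reaches zero. If the interface never dissociates the global smoothed
  maximum is returned with a warning and a `dissociated=False` flag.

## Force-response statistics

**Biphasic thresholds** are interior extrema of a profile's replicate-mean
curve, reported on the force grid only (no interpolation — thresholds in
the literature are quoted at grid forces). Monotone profiles return no
threshold; more than one extremum is flagged non-biphasic with all extrema
listed.

**Mode classification** maps successive occupancy differences along the
force grid to signs with a dead band ε (default 0.05 occupancy units —
roughly five times the binomial standard error of a 2000-frame estimate,
so trajectory noise does not flip signs), drops zeros, collapses repeats,
and reads the pattern: "" steady, "+−" (or pure "+") catch–slip, "−+" (or
pure "−") slip–catch, "+−+" catch–slip–catch, "−+−" slip–catch–slip;
anything longer is labelled `complex` with the raw pattern preserved.
Sign decisions use replicate means.

**Gaussian fits** of the N_HB frequency use unit-width integer bins (bond
counts are integers) and Levenberg–Marquardt least squares with
moment-based initial values; at least 4 distinct non-empty counts are
required, and non-convergence raises an error carrying the moment
fallback. `compare_replicates` wraps the unpaired equal-variance t test
(default) and Tukey's HSD — deliberately thin plumbing around standard
tests.

## Synthetic ground truth

The generator emulates exactly the statistical structure the analysis
measures, and nothing more:

* Two chains of glycine-like residues (backbone N, H, CA, C, O). Each
  planted bond owns one donor residue (chain A) and one acceptor residue
  (chain B) in a private 24 Å slot; layout guarantees that planted bonds
  are the only geometry the detection criteria can ever accept, with
  ≥ 1.3 Å of margin after jitter. A residue may join at most one planted
  bond; study configurations whose source tables reuse residues map the
  duplicates to neighbouring free numbers and keep the original pair name
  in the bond label.
* Bond presence per frame is an independent Bernoulli event with
  probability o(F); occupancy is a time-fraction statistic, so dwell-time
  correlation is unnecessary for validating it. An optional two-state
  Markov persistence (off by default) is available for studying correlated
  frames; it preserves the stationary occupancy.
* Occupancy curves are Gaussian-bump parametrisations
  o(F) = baseline + Σ aᵢ·exp(−(F−cᵢ)²/2wᵢ²). Published force-response
  data constrain shapes (unimodal, inverted, triphasic), not functional
  forms, so bump count and sign encode the five modes and are validated at
  construction, as is o(F) ∈ [0, 1].
* Bound geometry: donor–acceptor distance 2.9 Å with the hydrogen tilted
  to give a D–H–A deviation of exactly 10° (solved numerically), i.e.
  comfortably inside the 3.5 Å/30° criteria; unbound geometry 5.0 Å,
  violating the distance criterion. All atoms get sub-0.05 Å uniform
  jitter.
* One seed plus the (force, replicate) pair feeds a `SeedSequence`, so
  every run is independently seeded yet fully reproducible, and replicate
  indices perturb seeds deterministically.

What passing tests show: the estimators are unbiased and correctly
calibrated against known Bernoulli ground truth, the detector and
generator agree frame-by-frame, and the classification/threshold logic
recovers planted shapes at realistic sampling noise. What they do not
show: robustness to force-field artefacts, water-mediated bonding,
conformational drift, or correlated bond dynamics in real proteins — the
synthetic complex has none of these.

## Study configurations and problem sizes

The packaged reference table (12 interface hydrogen bonds with wild-type
and domain-truncated survival ratios, three-run mean ± SD) defines the
equilibrium study: 12 planted bonds for the full-length system, 11 for the
truncation (the K190–E71 bond requires a residue the truncation removes —
its donor is the only one numbered above the 128-residue boundary, so
truncating chain A at residue 128 removes exactly that bond). Planted
occupancies sum to 6.14 (full) vs 4.93 (truncated) expected interfacial
bonds, and imply fD ≈ 2.1×10⁻⁵ vs ≈ 2.2×10⁻⁴ under the product rule —
an order-of-magnitude separation that replicate noise cannot invert.

Default campaign sizes — 2000 frames per run, three replicates, the
0/25/50/75/100 pN force grid — mirror a three-run clamp study sampled at
modest stride and give per-occupancy binomial σ ≤ 0.011, small enough to
classify modes whose planted trends are ≥ 0.2. Buried SASA is evaluated on
a frame stride (default every 50th frame) because it is the one per-frame
metric whose cost dominates; the stride is a config field and the SASA
series holds values constant between evaluation points.

## Numerical details and edge cases

* Occupancy/N_HB evaluation is vectorised over frame chunks (250 frames)
  to bound memory at a few tens of MB regardless of trajectory length.
* Report floats are written with round-trip `repr`, so written reports
  read back bit-exactly, and identical seeds yield byte-identical report
  files.
* Empty selections are construction-time errors — a selection of a residue
  range that does not exist in a (possibly truncated) structure fails
  loudly instead of yielding silent zeros.
* PDB reading keeps the first alternate location, rejects insertion codes
  (selections are keyed on plain integers), and reports unparseable
  records by line number. Trajectories use a documented plain multi-frame
  XYZ dialect whose comment line carries per-frame time and applied force.
* Degenerate inputs: an all-coincident strand (no principal axis), a
  zero-variance Gaussian histogram, a reference fD of zero, traces shorter
  than the smoothing window, and zero-frame trajectories all raise typed
  errors; two zero-variance replicate groups with equal means compare at
  p = 1.

## Known limitations

* fD's independence assumption ignores bond–bond correlation.
* The interaction energy is a switched-cutoff pair sum, not a free energy;
  no polarisation, no solvent screening beyond the implicit choice of
  dielectric 1.
* The synthetic generator plants i.i.d. frames by default; lifetime-based
  statistics (off-rates, dwell times) would need the Markov option and are
  not part of the analysis surface.
* Kinetic catch/slip models (two-pathway bond lifetimes vs force) are out
  of scope; the classification is shape-based only.
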