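# Methods

This note records the models implemented in `foldscape`, the conventions
and defaults behind every tunable parameter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the underlying protocol was genuinely open.

## Units and indexing

Coordinates are nanometres internally; PDB I/O converts from/to Å at the
boundary, and surface areas are reported in Å² (the unit hydrophobicity
results are conventionally quoted in).  Contact-map and network cutoffs
are taken in Å because that is how the corresponding protocols state
them.  Residues are indexed 0-based internally; the author (PDB)
numbering is retained on every residue for reporting.  Van der Waals
radii ship as editable two-column tables (Bondi element radii, plus a
united-atom set with inflated C/N radii that is auto-selected when a
structure carries no hydrogens; crystal structures therefore work out of
the box).  Atom polarity follows the hydrophobic-surface convention:
C and S nonpolar, N and O polar, hydrogens inherit the class of their
nearest heavy atom, ions default to polar (they can never join a patch).

## Order parameters

A native contact exists between residues i and j (|i−j| ≥ 3; the
spacing excludes trivially permanent short-range pairs) when the minimum
distance between their scoped atoms is ≤ 0.55 nm.  ρ uses side-chain
atoms only and *Q* all heavy atoms; both are the retained fraction of the
native list, counted per residue pair.  Whether the original protocol
counted atom pairs or residue pairs for *Q* is not stated anywhere we
could verify; residue-pair counting is implemented and the scope is
configurable.  RMSD uses closed-form Kabsch superposition (default: Cα).
RMSF superposes frames onto their iterative mean (2 passes) before
taking per-residue fluctuations.  SASA is a deterministic Shrake–Rupley
style dot surface on a Fibonacci sphere lattice; the default 960
dots/atom keeps the isolated-sphere quadrature error well under 1 %
(the suite asserts 2 %).  Densities below 32 are refused as unreliable.

## Free-energy maps

ΔA(i) = −RT ln(p_i/p_ref) on an n×n histogram (default 20×20) with
R = 8.314×10⁻³ kJ/(mol·K); the reference is the most probable cell (ties
break to the lexicographically smallest index).  Unoccupied cells carry
an explicit `+inf`, never a sentinel.  Bin ranges default to the data
range with the max-edge point in the last bin; analyses that compare
maps across ensembles should pass explicit ranges, as the acceptance
measurements do.  The barrier between two basins is the discrete minimax
surrogate — the smallest achievable path-maximum of ΔA over 8-connected
paths through occupied cells, minus ΔA at the start — computed by
union-find over cells sorted by ΔA, which is exact and O(n² α(n)).
Window-based ensemble extraction uses closed (inclusive) windows on both
axes.  Melting curves count frames with RMSD inside the unfolded window
(default 0.3–0.9 nm) per temperature; T_m is the midpoint of a
least-squares logistic fit to the 0–1 min-max-normalized curve, refused
when the curve is flat or never crosses ½.

## Secondary structure

Hydrogen bonds use the Kabsch–Sander electrostatic model with partial
charges folded into the constant 0.084·332 kcal·Å/mol and a −0.5
kcal/mol threshold; the amide hydrogen, when absent, is placed 1 Å from
N opposite the preceding carbonyl C=O direction.  Pairs closer than two
residues in the same chain are excluded, and a 9 Å Cα screen bounds the
search.  Helices need two consecutive n-turns (n = 4, 3, 5 — α, 3₁₀, π,
all reduced to H); strands are residues in parallel or antiparallel
bridge patterns (both bridge types reduce to E, so explicit ladder
merging is unnecessary at 3-state granularity); helix assignment takes
priority.  Incomplete backbones and chains of < 3 residues are coil.
mdtraj's DSSP port serves as an independent cross-check only; it trims
one residue at each antiparallel ladder edge relative to the strict
bridge patterns, which is the only systematic disagreement observed
(measured agreement on the mixed α/β/coil test structure: 100 %).

Propensities are per-frame class occupancies per residue; the
native-normalized value is the fraction of frames a residue spends in
its own native class.  Transition events compare the native label with
the modal ensemble label: (H→C, E→C, C→E, H→E) are the four event
classes, everything else is `unchanged`, and modal ties conservatively
resolve to `unchanged`.  Dihedrals follow the IUPAC sign convention
(verified against both an explicit right-hand-rule construction and
mdtraj's φ/ψ on the ideal helix).

## Hydrogen bonds vs HDX protection

A protein–solvent bond is an N/O–N/O pair within 0.35 nm; when explicit
hydrogens exist an H–D–A angle ≤ 30° is additionally required, while
heavy-atom-only structures use the distance alone (water hydrogen
orientations are not reconstructable).  Identical-position duplicate
records are deduplicated, making counts a function of the geometry set.
Mainchain N–H···O=C counting differs deliberately: the backbone amide H
*is* always reconstructable, and a distance-only rule would also count
the helical N(i+3)···O(i) approach at ≈3.2 Å, so the angle term applies
in both modes (the ideal 10-residue helix then yields exactly the six
i→i+4 bonds).  Sequence separation ≥ 2 excludes the covalent
O(i)–N(i+1) shadow.  Per-segment normalization keeps the first 4 + last
3 residues ("seven terminal residues"; the 4+3 split is configurable to
3+4); segments shorter than 7 are excluded with an explicit marker
rather than an error.  Concordance with HDX protection classes counts
less-protected segments whose mean strictly exceeds the more-protected
class mean.

## Hydrophobic patches

Dots are generated on nonpolar atoms at radius r_vdw + probe (probe
0.14 nm); a dot survives when outside every other atom's accessible
sphere, polar atoms' spheres being inflated by the polar expansion
radius (default 0.14 nm, distinct in role though numerically equal to
the probe).  Exposed nonpolar atoms are clustered by accessible-sphere
overlap (d < r_i + r_j + 2·probe), patch area is the sum of member dot
weights, and per-residue contributions sum exactly to the patch area.
Significance is top-5 by area, then ≥ 300 Å² — in that order, so a sixth
large patch is never promoted.  "Total surface hydrophobicity" is the
sum over significant patches.  EHSC attributes each contributing
residue's patch area to its transition-event class and normalizes to
the significant-patch total.  Motif residue sets (e.g. GroES-like
binding motifs) are explicit inputs — never inferred from sequence
patterns — and motif exposure is total motif SASA over motif residue
count.  The numerical-occlusion oracle used for validation integrates
each accessible sphere on a latitude–longitude grid with sin θ weights
and shares no code with the dot engine.

## Contacts and networks

Contact maps default to Cα–Cα at 7 Å with |i−j| ≥ 3 (a minimum-heavy-
atom mode exists because the original metric is unstated; outputs record
which was used).  Pairs are classified against the native structure's
contacts at the same cutoff; non-native pairs at ≥ 50 % frame persistence
are reported in descending frequency.

Commute time is the population variance of the Cα pair distance; the
mean-offset δ(ij) in the defining expression is the time mean, so
CT = Var(d) exactly, symmetric with a zero diagonal.  The 0.1 pathway
threshold applies to the max-normalized matrix (a raw-Å² mode exists)
because a unitless threshold on raw variances would be length-scale
dependent.  Neighbor edges require time-averaged minimum heavy-atom
distance < 3.6 Å; interaction edges a ≤ 3.9 Å heavy-atom contact
(a standard non-bonded distance; the original protocol delegates to an
external contact program without stating one) in ≥ 50 % of frames with
|i−j| ≥ 2.  Pathways grow greedily: seed at the interacting pair of
minimal CT, repeatedly append the lowest-indexed residue that interacts
with ≥ 1 member and has CT ≤ threshold to *every* member, retire members
from the pool, discard chains shorter than 3.  The growth conditions are
re-checkable on the output, and determinism (lowest-index tie-break) is
part of the contract.  Graphs export to GraphML/GEXF with node degree
("communication efficiency"), pathway membership and typed edges.

## Synthetic data: what it emulates, what it does not

The generators are statistical phantoms, not physical models: they
reproduce exactly the features the analyses measure (state populations,
secondary-structure patterns, surface decompositions, distance moments)
while making no claim to force-field realism.  Noise is i.i.d. Cartesian
Gaussian with no bonded-geometry repair; hairpin turns are geometric
interpolations; cross-strand side-chain packing in the sheet template is
tighter than physical.  Consequently, passing tests demonstrate the
correctness of the measurement machinery — not that any real protein
behaves like the phantoms.

Templates build poly-alanine backbones by NeRF chain extension with
standard bond geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å;
ω = 180°); L-chirality of the Cβ construction was verified against an
RDKit-embedded L-alanine.  The helix uses (φ, ψ) = (−57°, −47°).  The
antiparallel sheet uses the planar fully-extended template for both
strands because only a zero-twist (pure-translation) repeat lets a rigid
partner strand register the entire hydrogen-bond ladder; the partner is
the first strand rotated 180° in-plane and placed by a deterministic
grid scan maximizing registered N···O pairs without backbone clashes.
The two-state trajectory hops between the sheet and a strand-separated
copy (a poly-alanine helix has no Cβ–Cβ contacts under 0.55 nm, which
would leave ρ undefined); defaults are 80/20 populations, σ = 0.01 nm
coordinate noise, 400 K, 50 000 frames for the free-energy recovery
measurement.  With those defaults each basin occupies a single cell of
the fixed-range (0–2.5 nm × 0–1) 20×20 grid, so the measured gap is the
pure counting estimate −RT ln(n₂/n₁), binomially distributed around
−RT ln(0.25).  The unfolding ensemble plants one segment per event class
(helix and coil controls included) in a 71-residue chain with segments
spaced 1.8 nm apart; "core" residues — those whose label the template
pins (helix/strand interiors, whole coil segments) — define the planted
truth, since template edges are legitimately ambiguous under any
assignment scheme.  The distance process standardizes a Gaussian series,
so requested mean and variance are exact sample identities, not
asymptotics.

## Problem sizes and determinism

The test and acceptance workloads are sized for interactive runs on one
CPU: 50 000 frames for the two-state recovery, 10-frame label ensembles,
36-atom patch phantoms with a 180×360-point oracle grid, 4×4 exhaustive
barrier enumerations, 50-water hydrogen-bond fixtures.  Every stochastic
fixture takes an explicit seed, all generators are pure functions of
their inputs, and the CLI writes fixed-format tables so identical
configs produce byte-identical outputs.

## Known limitations

- The dot lattice is fixed in the lab frame, so patch *areas* are
  rotation-invariant only to quadrature precision (the decomposition
  itself is exact); tests budget 2 %.
- No mmCIF input, ligand parameterization or protonation prediction.
- The Kabsch–Sander reduction stops at 3 states; turn/bend classes and
  π-helix-specific analyses are out of scope.
- HDX concordance uses hydrogen-bond counts as a surrogate; actual
  protection factors or exchange rates are not modeled.
- Crystal-structure patch benchmarks require an external PDB download;
  the offline suite validates the same operations against the planar
  phantom and its independent numerical oracle instead.
- WHAM/MBAR reweighting across temperatures and kinetic rates from the
  maps are out of scope.
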