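# Methods

## Mass model

All arithmetic is monoisotopic.  Constants: proton 1.007276 Da, water
18.010565 Da, PMP label (C₁₀H₁₀N₂O) 174.0793 Da.  Residue masses are derived
from elemental formulas at registry load (via pyteomics) and any explicitly
stated mass must agree with its formula to 1e-4 Da.  The built-in registry
covers the residue classes distinguishable by mass at this resolution:

| code   | formula    | mass (Da) | class               |
|--------|-----------|-----------|---------------------|
| Hex    | C₆H₁₀O₅   | 162.0528  | hexose              |
| HexNAc | C₈H₁₃NO₅  | 203.0794  | N-acetylhexosamine  |
| dHex   | C₆H₁₀O₄   | 146.0579  | deoxyhexose         |
| Pent   | C₅H₈O₄    | 132.0423  | pentose             |
| HexA   | C₆H₈O₆    | 176.0321  | hexuronic acid      |
| QuiS   | C₆H₁₀O₇S  | 226.0147  | sulfoquinovose      |

Sulfoquinovose (6-deoxy-6-sulfohexose) is modeled as C₆H₁₀O₇S; mass alone
cannot distinguish isomers (Man vs Glc within "Hex"), and the package never
pretends otherwise.  Average masses reproduce none of the reference m/z
values, monoisotopic arithmetic reproduces all of them to ≤ 0.01 Da, which
fixes the choice.  Only singly protonated positive-mode ions are defaulted;
the `IonSpec` abstraction admits other adducts and charges but nothing in
the analysis chain requires them.

## Composition solver

Depth-first search over residue codes in lexicographic order, counting each
code from 0 up to its bound while the accumulated residue-sum mass stays
within tolerance of the target (observed m/z × charge − adduct − water −
label delta).  Two prunes are applied: overshoot beyond tolerance (masses
are positive, so the branch is dead) and unreachability (even filling every
remaining slot with the heaviest remaining residue cannot reach the
target).  Neither prune can discard a feasible vector, so the search is
complete within its bounds; the test suite and the acceptance script verify
exact set equality against an independent exhaustive scan on randomized
queries.  Results are ordered by |mass error|, then fewer residues, then
lexicographic code sequence — a total order, so output is reproducible.

Defaults: absolute tolerance 0.30 Da (generous enough for 2-decimal printed
precursors plus drift; the worked example uses 0.05 Da), per-residue bound
10, total bound 15.  Absolute-Da and ppm tolerances are mutually exclusive
by construction.

## Fragment universe and annotation

For a composition C the single-cleavage universe is: the precursor; Y ions
for every non-empty sub-multiset S (m/z = masses(S) + water + label delta +
adduct); B ions for every non-empty proper sub-multiset (m/z = masses(S) +
adduct); and neutral-loss entries, one per distinct residue, at precursor −
residue mass.  A Y ion whose complement is exactly one residue has the same
m/z as the corresponding neutral loss; the universe carries such masses
under the neutral-loss label only, because a precursor-minus-one-residue
peak cannot be distinguished from an in-source loss and the lost-residue
reading is the informative one for ladder interpretation.  Composition-level
fragments deliberately over-generate relative to any one topology;
topology-consistent filtering happens later.

Annotation assigns each peak the in-tolerance fragment with the smallest
|error|, ties broken precursor > Y > B > neutral-loss (label-retaining
assignments are more informative for reducing-end-labeled analytes), then
by sub-composition string.  Default tolerance 0.02 Da.  Unmatched peaks are
reported, and all candidate annotations for a peak remain retrievable.
Internal (double-cleavage) fragments and cross-ring cleavages are out of
scope.

## Adjacency rule and its soundness

For same-series annotated compositions S₁ ⊂ S₂ with S₂ = S₁ ⊎ {x}, where S₁
is homogeneous in chemical class c, the rule emits "class(x) attached to c".
Neutral losses are first normalized to their complementary root-side
composition (precursor minus lost residue); the precursor itself counts as
the full root-side fragment.

On noise-free single-cleavage fragment sets the rule is sound by a closure
argument.  A root-side component contains the root and is closed under
taking parents; so if its composition is k residues of class c plus one x,
the x-labeled node's parent lies in the component and belongs to class c
(when x's class is c itself, any non-root node's parent does).  Subtrees
(B fragments) are the dual case, closed under children.  Hence every
emitted hypothesis is an edge of the generating tree — the basis for the
zero-false-adjacency property that the test suite checks over randomized
trees.

## Topology enumeration and filtering

Rooted trees over the composition's label multiset are enumerated
recursively — choose a root label, partition the remainder into child
subtree label sets, recurse — with children kept in canonically sorted
nested-tuple form, so each isomorphism class is produced exactly once.
Sub-results are memoized across calls.  Branching is capped at 4 children
per node (ring-hydroxyl valence), configurable; compositions beyond
`max_nodes` (default 8) raise a size error rather than attempt an
enumeration that would be astronomically large.

A candidate tree is retained iff (i) every annotated Y composition equals
the root-side component of some single edge cut, (ii) every annotated B
composition equals some subtree, and (iii) every adjacency hypothesis is
realized by an edge between the stated classes.  Neutral-loss annotations
are *not* used as cut evidence (an internal residue can be lost in-source,
as the reference peak list itself illustrates: the precursor-minus-QuiS
peak coexists with Y evidence that places QuiS internally); they
contribute through composition filtering and adjacency inference only.
Linkage positions and anomeric configuration are not modeled — this kind
of evidence cannot resolve them.

## Chromatograms

Peak detection is scipy's local-maxima finder with a height threshold
(default 5% of the trace maximum), apex at the sample maximum, area by
trapezoid between flanking monotone minima.  Standards matching is
nearest-within-tolerance with each standard claiming at most one peak
(closest wins, ties to the earlier-eluting peak).  Condition diffing
greedily pairs peaks across traces within the retention tolerance (default
0.2 min); unpaired peaks are consumed/produced, and mutually nearest
consumed/produced pairs are flagged as candidate shifts.  A "shift" is a
flag, not an identification: pulsed amperometric detection carries no
analyte identity, so the module never claims that a shifted peak is the
same molecule.  Retention times are instrument-specific user input; the
synthetic fixtures use invented minutes (only the 7.2 → 8.3 min substrate
shift echoes reported values) and are labeled as constructions.

## Conservation

Key positions are 1-based in the ungapped reference, matching "Phe66"-style
nomenclature; conservation means strict identity with the reference letter
(no similarity groups — a deliberate mirror of the "same residues"
criterion).  Gap at a key column classifies as `gap` and excludes the
sequence from the fully conserved set.  A mismatch between a stated expected
letter and the actual reference letter triggers a stale-coordinates warning
but classification proceeds against the reference as given.

## Synthetic data

The spectrum simulator cuts one glycosidic edge at a time, emitting the Y
ion of the root-side component and the B ion of the leaf-side subtree plus
the precursor, then applies Gaussian m/z jitter (default sd 0.005 Da),
Bernoulli fragment dropout, and uniform decoy peaks.  Intensities are drawn
log-uniform over one decade — arbitrary, as no intensity model is claimed
anywhere in the analysis.  What it does not emulate: isotope envelopes,
multiple charge states, internal fragments (unless enabled), intensity
structure, or chemical noise correlated with real fragmentation propensity.
Passing round-trip tests therefore demonstrates the bookkeeping and the
logic of inference, not robustness to every artifact of real spectra.

Random test topologies draw their labels from a 3-code subset of the
registry per tree: natural oligosaccharides of this size are built from a
handful of residue classes, and the bound also keeps exhaustive enumeration
of the candidate tree space tractable.  The bundled 7-residue fixture tree
(HexNAc-HexNAc-QuiS-Hex-Hex-Hex-Hex, reducing end first) is one topology
consistent with the fragment evidence for the E11-6 glycan — the unique
chain arrangement in which both HexNAc₂ and HexNAc₂QuiS₁ arise as root-side
single cuts while QuiS is bonded to HexNAc (the hexose arm could equally
branch); it is documented as an emulation, not a determined structure.

Chromatogram simulation is a sum of Gaussians on a uniform grid (default
0.01 min) plus white noise.  Alignment simulation plants an exact number of
homologues conserved at all key positions; non-conserved homologues are
substituted at ≥ 1 key position, background columns mutate and gap at
configurable rates, and the reference stays ungapped.  Every simulator is a
deterministic function of its config and seed.

## Problem sizes and numerical choices

The shipped test suite checks solver completeness on 50 randomized queries
(≤ 4 residue types, bounds ≤ 6 — sizes where the brute-force oracle is
itself fast), round-trip annotation on 25 simulated spectra, and topology
recovery on 100 noise-free plus 100 jittered random 5–8-residue trees; the
acceptance script repeats these at the same sizes.  Ties everywhere break
by documented total orders (mass error, then size, then lexicographic), so
identical inputs give byte-identical outputs.  Mass comparisons use full
floating precision internally; printed values are rounded to 2 decimals
only in human-readable output.

## Known limitations

- Composition inference is mass-based: isomeric residues are
  indistinguishable, and an exotic residue absent from the registry will
  either be missed or mis-assigned to an isobaric combination.
- The adjacency rule is sound but not complete — it only fires when the
  smaller fragment is single-class, so some true adjacencies go unstated.
- Exhaustive tree enumeration is intended for glycan-sized problems
  (≤ 8 residues); larger structures need constraint-based approaches out of
  scope here.
- Chromatogram diffing assumes comparable run conditions between traces; no
  retention alignment or baseline-drift correction beyond what peak
  detection tolerates.
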