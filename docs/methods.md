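# Methods

## The model

`structcd` treats CD spectrum generation as structure-conditioned nearest-
neighbor regression. The premise: proteins with similar secondary-structure
content, similar packing of structural elements, and similar overall folds
have similar far-UV CD spectra, because the peptide backbone is the dominant
chromophore in the 175–240 nm range. The method therefore never models the
photophysics; it looks up and averages measured spectra of structural
neighbors. Its accuracy is bounded by the coverage of the basis set: a query
in a sparsely populated region of content space is extrapolated and will
score poorly, which is a diagnostic rather than a defect.

Three descriptors capture three structural length scales:

1. **ABO** (content): per-residue labels from a Kabsch–Sander hydrogen-bond
   assignment, reduced to percentages (α = %H, β = %E, ο = the rest).
   3₁₀-helix (G) is counted in the "other" term rather than the helix term,
   since the short 3₁₀ geometry contributes to the spectrum more like
   irregular structure than like α-helix. Matching is the Euclidean distance
   on the 0–100 percentage scale, subject to the bracketing rule below.
2. **TOP** (local topology): maximal H or E runs of ≥ 3 residues become
   elements, each with a least-squares axis (first principal component of
   its Cα positions, oriented N→C, endpoints the axis projections of the
   terminal Cα atoms). Element pairs whose axis segments approach within
   13 Å contribute their inter-axis angle to a 36-bin histogram (three
   groups α–α, β–β, α–β; twelve 30° bins each). The angle is
   chirality-signed: the unsigned angle θ ∈ [0°, 180°] is kept when
   `dot(cross(d₁, d₂), m₂ − m₁) ≥ 0` on the canonically ordered pair
   (α before β, else chain/sequence order) and reflected to 360° − θ
   otherwise. An unsigned angle would leave half the bins structurally
   unreachable; the signed convention distinguishes left- from right-handed
   packing.
3. **ZSC** (global fold): a sequence-order-preserving structural alignment
   scores each chain pair as `n_aligned / (1 + RMSD)`; the query's
   self-alignment score (its chain lengths, since self-RMSD is 0) is the
   normalizer, making ZSC(q, q) exactly 1. Multi-chain structures are
   matched by an exact maximum-weight one-to-one chain assignment
   (Hungarian method; greedy only beyond 12 chains, where exactness stops
   mattering before cost does).

## Secondary-structure assignment

The assigner implements the Kabsch–Sander electrostatic criterion: the
amide hydrogen is placed 1 Å from N opposite the preceding carbonyl, and a
donor–acceptor pair is hydrogen-bonded when
`0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`.
From the bond matrix, two consecutive i→i+4 turns label an α-helix (H), two
consecutive i→i+3 turns a 3₁₀-helix (G), and ladders of parallel or
antiparallel bridges label strands (E); everything else is O. This is a
deliberate subset of the full classification — π-helices, isolated bridges,
turns and bends all collapse into O, matching the three-way content split
the descriptors need. Chains are split into segments at numbering gaps or
Cα–Cα steps above 4.5 Å, so neither hydrogen placement nor helices span
unobserved loops. Residues missing backbone atoms fall back to O with a
warning. A table-driven `header` mode (HELIX/SHEET records) and a
`provided` mode (caller-supplied labels) keep the pipeline testable
independently of the geometry.

## Matching, refinement, generation

**Bracketing.** The content selector returns the globally nearest entry,
the nearest entry strictly below the query on its primary axis, and the
nearest strictly above ("mainly helical" means α_q ≥ β_q; otherwise β is
the primary axis). Duplicates are resolved by the next-nearest entry
satisfying the unmet condition; if either side cannot be filled by a
distinct entry the selector falls back to the plain distance top three.
Strict inequalities are honored: an entry exactly equal to the query on the
primary axis can only enter as the nearest-overall member. Ties everywhere
break by basis manifest order, which keeps the pipeline deterministic.

**Refinement.** The nine pooled spectra are averaged with multiplicity (an
entry picked by two methods counts twice — agreement between methods is
itself evidence). Each distinct protein is scored by the number of
wavelengths where |CD_i,l − CD_µ,l| > 2σ_l, a two-sided outlier test; the
worst protein is removed (all its pooled occurrences at once) whenever its
count exceeds ⌊points/6⌋ — 11 of the default 66 — and the loop repeats
until nothing is removed or one distinct protein remains. σ with a
single-member pool is defined as 0, so the loop cannot empty the pool. Ties
on the count prefer the larger total squared deviation, then the first id.

**Generation.** Within each method the retained neighbors' native scores
become weights normalized to mean 1: similarities (ZSC) are used directly,
distances (ABO, TOP) through 1/(d + ε) with ε = 10⁻⁹ guarding exact-zero
distances. The final spectrum divides the weighted sum by n_A + n_T + n_Z,
so it is a convex combination of retained spectra — the output can never
leave their per-wavelength envelope, and equally-good matches reduce to a
plain average. The distance→weight map is one function
(`pipeline._method_weights`) so rank- or linear-decay alternatives can be
swapped in one place.

**NRMSD.** `√(Σ_l (e_l − o_l)²)/M` over the common grid. M is a single
scalar per basis: the largest per-wavelength absolute difference between
any two basis spectra. This makes the metric unit-free and invariant under
joint rescaling of spectra and basis, and gives every cross-validation fold
the same normalizer. A basis of identical spectra (M = 0) is rejected.

## Structural alignment

The aligner is combinatorial-extension-flavored rather than a port: octamer
Cα distance-matrix windows give a similarity `max(0, 3.0 − mean |ΔD|)`
between every position pair; a semi-global dynamic program (linear gap cost
0.5, free end gaps) chains them into an initial correspondence. Because
locally periodic structure (helices) supports register-shifted matches that
cannot all be satisfied by one rigid transform, the initial correspondence
plus up to eight diverse single-window anchors each seed a refinement loop:
least-squares (Kabsch) superposition on the current pairs, iterative
trimming of pairs deviating > 5 Å, then re-derivation of the
correspondence from spatial proximity (capture radius 8 Å, sequence order
preserved) in the superposed frame. The seed maximizing
`n_aligned/(1 + RMSD)` wins. Reported RMSD is over the final pairs only.
ZSC values are rounded to nine decimals so downstream rankings and weights
are invariant to coordinate-frame floating-point jitter — the pipeline's
output is bit-identical under rigid transformation and chain re-ordering
of the query.

## Input handling

PDB files are read through gemmi. Only the first model of a multi-model
(NMR) file is used; HETATM records and waters are dropped; alternate
locations resolve to the highest occupancy, ties to the first encountered.
Residues with insertion codes keep file order and are renumbered minimally
when their numbers collide. Non-standard residues with a Cα are retained
and assign as O, contributing to the "other" term rather than vanishing.

## The synthetic data generator

The generator exists so every stage is testable without downloading any
reference data. It emulates a reference collection like SP175 — structures
paired with spectra on the 175–240 nm grid — with two deliberate
simplifications:

* **Spectrum law.** Spectra are `(α·C_H + β·C_E + ο·C_O)/100` plus optional
  Gaussian noise, where the three component curves are fixed sums of
  Gaussians loosely shaped like textbook helix (positive lobe near 193 nm,
  negative lobes near 208/222 nm), strand and coil bases. These constants
  are fixture conventions, not physical claims. The law is evaluated at the
  content the assigner actually measures on the built structure, so the
  synthetic spectrum is an exact function of the structure. An optional
  architecture-dependent bump term lets tests create cases where content
  alone is ambiguous.
* **Structure family.** Every entry is assembled from one parametric
  family: ideal-geometry helices (φ = −57°, ψ = −47°, NeRF-built) filling
  up to eight fixed ring slots, an antiparallel sheet (φ = −139°,
  ψ = 135°) whose strands repeat a calibrated flip-plus-offset transform,
  and a coil segment with a fixed torsion stream. Because the layout is
  shared, entries with similar content have genuinely similar folds, so the
  topology and fold descriptors act as consistent (not contradictory)
  signals for the content-driven law. Component anchor points drift
  slightly (0.12 Å per content percentage point) so fold similarity also
  *decreases* smoothly with content distance in both directions.

Geometry choices that look arbitrary are calibrations against the
assigner, frozen once: the inter-strand transform (offset (3.5, 4.5,
−0.25) Å with a 6° propeller twist) maximizes recognized ladder hydrogen
bonds across strand lengths; strands are anchored on a central residue
because centroid anchoring shifts the hydrogen-bond register with strand
parity; helix slots lean outward by distinct angles (8°–29°) and the sheet
carries the twist so that no element-pair angle sits on a 30° histogram
bin boundary, where coordinate rounding would flip bins. Strand length is
capped at 10 residues (the rigid twist strains longer registers); extra
strand content becomes more strands. Target content is reached by a
bracketing bisection on the helix/strand residue budgets, since the
achieved percentages are stepwise functions of the budgets and a pure
multiplicative update can limit-cycle; entries land within ±5 percentage
points of target, usually ±2.

What passing synthetic tests does **not** show: real proteins violate the
generator's assumptions in every particular — irregular geometry, kinked
helices, mixed sheet topologies, side-chain and disulfide contributions to
the spectrum, solution flexibility, and a structure→spectrum relation that
is nothing like linear in content. Synthetic results validate the
machinery (descriptors, selection, refinement, weighting, metric), not the
empirical accuracy on real spectra, which depends on a real measured basis
set.

## Default problem sizes

The reference synthetic basis has 20 entries of ~140 residues on a content
lattice spanning α ∈ [5, 75] and β up to ~55; recovery checks use ten
interior queries. These sizes give stable statistics while keeping the
full suite and the acceptance script comfortably within a desk-scale run;
the generator accepts larger requests unchanged.

## Known limitations

* The Kabsch–Sander subset omits π-helices, isolated bridges and bends;
  content percentages can differ by a few points from a full assigner near
  chain ends and bulges.
* The aligner is a CE-style heuristic; it is pluggable (anything returning
  an `AlignmentResult` can stand in) but makes no optimality guarantee.
* The 13 Å element-pair cutoff is applied to the minimum axis-segment
  separation; reading it as a maximum or mean separation would prune long
  adjacent strands.
* Spectra are assumed already in mean-residue Δε on a common grid; no unit
  conversion, smoothing or baseline correction is performed.
* Membrane proteins and chromophore-rich proteins fall outside the method's
  premise that backbone geometry determines the spectrum.
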