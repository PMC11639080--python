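# Methods

## The energy model

`satfold` folds single-stranded DNA under a loop-based nearest-neighbor
model at a fixed 310.15 K (37 °C).  A secondary structure is a
pseudoknot-free set of base pairs (hairpin loops ≥ 3 unpaired bases);
its free energy is the sum over the loops of the structure:

* **Stack** (i,j)/(i+1,j-1): `stack[pt(i,j), pt(j-1,i+1)]`.
* **Hairpin** of size s: length penalty from the table (Jacobson–
  Stockmayer log extrapolation `ΔG(30) + 1.07856·ln(s/30)` beyond 30);
  size 3 adds the terminal A·T penalty, larger hairpins the terminal
  mismatch of the closing pair.
* **Bulge**: length penalty; size 1 keeps the flanking stack term,
  larger bulges add the terminal A·T penalty at both closing pairs.
* **Interior loop**: length penalty + capped asymmetry (ninio) +
  terminal mismatches at both closing pairs.
* **Multiloop**: linear model `a + b·(branches+1) + c·unpaired`, the
  closing pair and every branch adding the d2 dangle contributions on
  both sides plus the terminal A·T penalty.
* **Exterior branches**: terminal A·T penalty plus d2 dangles where a
  neighboring base exists.
* **G-quadruplex**: four G-runs of equal length L ∈ [2,5] separated by
  linkers of 1–7 nt, scoring `a·(L−1) + b·ln(ℓ_tot−2)` (defaults
  a = −18, b = +12 kcal/mol); quadruplexes compete with base pairing
  in the exterior and inside multiloops (where they pay the branch
  penalty) and contribute no base pairs.

The **d2 dangle convention** adds both the 5′ and the 3′ dangle of a
helix end unconditionally, whether or not the neighboring base is
paired elsewhere; ends at the sequence boundary add only the existing
side.  **No lonely pairs** restricts the search to canonical structures
in which every pair stacks on an adjacent pair; this is implemented at
the grammar level (a branch is "outer pair forced onto an inner V"),
which makes the DP's structure space exactly equal to a post-filter on
enumerated structures — the property the oracle tests exploit.

Simplifications relative to full reference implementations of this
model family: no special 1×1/2×1/2×2 interior-loop tables, one
terminal-mismatch table shared by hairpin and interior loops, no
tetraloop bonuses, no enthalpy tables (the model exists only at 37 °C),
no salt correction (the salt concentration is metadata describing the
condition baked into the parameter set).  These choices trade small
per-structure energy shifts for a compact, fully self-consistent model;
numeric equality with other folding engines at kilobase scale is not a
goal and is not claimed.

## Algorithms

* **MFE**: Zuker-style dynamic programming over V (closed), M/M1
  (multiloop segments, first/last-branch decompositions) and F
  (exterior) tables; interior loops capped at total size 30.  The
  traceback re-derives decisions with the identical floating-point
  operation order, so the reported MFE equals the loop-decomposition
  energy of the reported structure exactly.  Ties prefer a pairing
  decomposition and the first candidate in scan order, making results
  deterministic.
* **Partition function**: the same (unambiguous) grammar with sums in
  place of minima; every weight is scaled per nucleotide by
  κ = exp(1.05·MFE/(n·RT)) so that 10 kb windows stay in double range.
  Base-pair probabilities come from an outside recursion over the same
  grammar; under no-lonely-pairs a pair is counted either as a branch
  top pair or as a V-closing pair, never both.  Ensemble diversity is
  ⟨d⟩ = 2·Σ_{i<j} p_ij(1−p_ij), the expected symmetric-difference
  distance between two independent ensemble draws.
* **Enumeration oracle**: exhaustive generation of all valid
  structures (guarded to 20 nt) with explicit Boltzmann summation.
  The test-suite checks, on 200 random 10–18-mers, that the DP MFE
  equals the enumerated minimum exactly and that ensemble free energy,
  every p_ij and the diversity match the explicit sums to 1e-6
  (quadruplexes are excluded from these comparisons and validated
  against the closed-form energy instead).
* **Dyad/two-armed scans**: hits live on anti-diagonals of the match
  matrix.  A hit is one maximal run of consecutive arm matches — the
  innermost matching pair within the gap limit, extended outward,
  truncated to the arm cap; sub-arms are never reported separately.
  Because only runs whose innermost pair lies within the gap limit
  qualify, each anti-diagonal needs O(gap/2) probes, making the scan
  effectively linear.  Naive character-level oracles (separate
  implementations in the test-suite) must agree exactly on random
  2 kb corpora.
* **Sampling**: windows are drawn uniformly over the valid start
  positions of a region's intervals (never across interval
  boundaries), non-overlapping when feasible with an overlapping
  fallback that logs a warning; N-heavy windows are redrawn up to a
  bound and then accepted flagged.  Identical seeds give identical
  windows; a chi-square test on the empirical start distribution
  guards uniformity.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| temperature | 310.15 K | fixed; no enthalpy rescaling |
| RT | 0.61633 kcal/mol | gas constant × temperature |
| dangle model | d2 | both-side end contributions, unconditional |
| no_lonely_pairs | on | helices ≥ 2 stacked pairs |
| gquad | on | layered-quadruplex states in the DP |
| window length | 4,000 nt | alternates 500 and 1,000 |
| windows/region | 5 | per chromosome |
| palindrome scan | arm 5–100, gap ≤ 20, 0 mismatches, overlaps kept | dyad density input |
| non-B thresholds | inverted/mirror arm ≥ 10, spacer ≤ 100; direct unit ≥ 10 (≤ 60), spacer ≤ 10; A-phased ≥ 3 tracts of 3–9 nt at 10±1; Z-DNA ≥ 10 alternating dinucleotides; G4 = 4×G≥3 with 1–7 nt linkers; STR unit 1–9, total ≥ 20 | all exposed in `MotifConfig` |

The bundled parameter file (`dna_unified_dg37.par`) carries the
published unified DNA/DNA ΔG°37 stack values, Jacobson–Stockmayer-
extrapolated loop tables anchored at hairpin(3) = 3.5, bulge(1) = 3.6
and interior(4) = 3.6 kcal/mol, small uniform mismatch/dangle
stabilizations (−0.2 to −0.4 kcal/mol), a multiloop model of
(3.40, 0.40, 0.10) kcal/mol for closing/branch/unpaired, terminal A·T
penalty 0.05 kcal/mol, and G·T wobble entries marked INF (supplying a
file with finite G·T energies enables wobble pairing; there is no
hard-coded pairing alphabet).  Loader and writer speak the ViennaRNA
2.x text dialect (integers in dekacal/mol, INF sentinel), so the DNA
Mathews 2004 file is accepted directly.

Direct-repeat units are capped at 60 nt by default so the quadratic
reference oracle stays cheap; the cap is configuration, not code.
Mirror/direct hits whose whole region is a single repeated base are
suppressed by default (homopolymer runs are reported as short tandem
repeats instead).

## The synthetic generator

The generator emulates the sequence organization the analysis assumes:
tandem arrays of a random ~171 nt monomer (exact base composition at
the GC target, so one monomer's compositional noise is not amplified
across the array) arranged into HOR units whose copies diverge by
i.i.d. substitutions (uniform over the three alternatives, no indels);
i.i.d. centric-transition / coding / rDNA-like sequence at their GC
targets; inserted inverted repeats (arm + spacer + reverse complement)
and, in rDNA-like regions, mirror repeats, at non-overlapping
seed-chosen positions with truth coordinates.

The default preset (`gradients`, 8 chromosomes) encodes the
observed gradients: GC 0.46/0.40/0.36 (+ a ±0.04 cross-chromosome
gradient) for transition/active/divergent, coding 0.52, rDNA 0.65 with
mirror repeats on the first five chromosomes; dyad insertions of
90+3k / 40+2k / 6+k per region (k the chromosome index), chosen so the
measured dyad density dominates the ~0.22 background level of random
DNA and realizes transition > divergent > active; divergence 0.12
(divergent) vs 0.02 (active); one chromosome without a divergent array
and one whose divergent array is 3,420 nt, exercising the exclusion
rules at the 4,000 nt window length.  The synthetic missegregation
table falls linearly with the chromosome index (plus seeded noise), so
the designed |MFE|–missegregation correlation is negative.

What the generator does **not** emulate: phylogenetically realistic
satellite evolution (no indels, no monomer-level phylogeny), CENP-A /
chromatin context, assembly gaps, and the specific repeat families of
real centromeres.  Passing the trend tests therefore shows the
pipeline recovers gradients *it can see in sequence*, not that real
centromeres behave this way; real-genome conclusions require real
assemblies and annotations, which this package accepts as
FASTA/BED/TSV inputs (including explicit window-coordinate tables to
bypass the sampler).

A note on scale: under this model family, balanced-composition random
DNA folds near 0 kcal/mol without quadruplexes, and predicted
stability is driven largely by G-run density and GC content.  The
region-level MFE gradients the synthetic preset produces at 500–1,000
nt windows (HOR arrays least negative, transition/coding more
negative, rDNA most negative) reproduce the qualitative ordering of
the real analysis; absolute kcal/mol values at 4 kb depend on the
exact parameter file and engine details and are not comparison
targets here.

## Numerical choices and degenerate inputs

* Energies are file integers / 100, kept as float64; reports round
  half-away-from-zero to 2 decimals; internal arithmetic is unrounded.
* Sequences are uppercased on ingest; U is rejected (DNA only); N
  never pairs, matches nothing in scanners, and is excluded from the
  GC denominator (all-N windows flag GC 0).
* Sequences with no stabilizing structure return the open chain at
  exactly 0.00.
* Zero-variance correlation inputs raise an explicit error rather
  than returning NaN; the pipeline therefore correlates only the three
  centromeric region classes (the control regions have designed-
  constant GC).
* Dyad density is a literal sum (no overlap deduplication, spacers
  excluded); pathological inputs can exceed 1 and are reported with a
  warning.
* Per-(chromosome, region) sampling seeds are derived from the run
  seed via CRC32 and kept below 2^31.

## Design choices where the design was open

* Fig-style feature correlations pair per-chromosome mean window
  |MFE| with region-wide GC/dyad density; per-window pairing is a
  config alternative.  The generator's GC gradient acts mostly across
  region classes, so the GC-sign acceptance check pools windows of the
  three centromeric classes.
* Eligibility distinguishes "region absent", "span < window" and
  "no interval ≥ window" (a fragmented region can have enough total
  span yet no hosting interval; windows never cross interval
  boundaries).
* Whether the five windows may overlap and how N-gaps are handled are
  config toggles (`allow_overlap_fallback`, `max_n_fraction`,
  `max_redraws`) with the defaults above.
* The multiloop d2 dangles of the closing pair use the reversed pair
  type with the loop-side neighbors (5′ = j−1, 3′ = i+1).

## Known limitations

* No suboptimal-structure enumeration at scale, MEA/centroid
  structures, constraint or circular folding.
* Mismatch-tolerant palindrome arms are not implemented (the scan the
  analysis uses runs at 0 mismatches).
* The partition function is exact for the model but the model itself
  omits the special small-interior-loop tables; ensemble quantities
  at kilobase scale shift accordingly.
* Quadruplex states carry no base-pair probabilities; windows whose
  ensemble is quadruplex-dominated legitimately show low diversity.
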