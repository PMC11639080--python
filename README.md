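# satfold

DNA secondary-structure landscapes of centromeric satellite and genic
regions: nearest-neighbor folding of single-stranded DNA, non-B motif
scanning, and region-level statistics.

## The problem

Centromeres are built from megabase-scale arrays of ~171 bp
alpha-satellite monomers organized into higher-order repeats (HORs).
When this DNA becomes transiently single-stranded, intra-strand
complementarity lets it fold into hairpins, cruciforms and
quadruplexes.  How stable those structures are — and how that
stability varies between the active HOR (the kinetochore site), the
flanking divergent HOR, the pericentromeric centric transition region,
ribosomal DNA and ordinary coding sequence — is a sequence property
one can compute, and it correlates with how often individual
chromosomes missegregate.

`satfold` is a library (plus a thin CLI) for exactly this analysis:

* **Folding engine** — Zuker-style minimum free energy (MFE)
  prediction and a McCaskill-style partition function for ssDNA under
  a loop-based nearest-neighbor model at 37 °C.  The free energy of a
  structure is the sum over its loops,

  ΔG(S) = Σ stacks + Σ hairpins + Σ interior/bulge loops
          + Σ multiloops (a + b·branches + c·unpaired) + end terms,

  with d2-style dangles (both-side end contributions added
  unconditionally at every helix end), no lonely pairs (every helix ≥ 2
  stacked pairs), and a layered G-quadruplex term
  E(L, ℓ) = a·(L−1) + b·ln(ℓ−2).  The ensemble free energy is
  −RT·ln Z over all structures, base-pair probabilities p_ij come from
  an outside recursion, and the ensemble diversity
  ⟨d⟩ = 2·Σ_{i<j} p_ij(1−p_ij) is the expected base-pair distance
  between two draws from the Boltzmann ensemble.
* **Motif scanner** — EMBOSS-palindrome-style dyad symmetries (arm
  5–100, spacer ≤ 20) with dyad density = Σ(2·arm)/length, and the
  seven non-B DNA motif classes (inverted, mirror and direct repeats,
  A-phased repeats, Z-DNA, G4, short tandem repeats) with per-class
  occupancy.
* **Window sampling** — stochastic, seed-deterministic sampling of
  fixed-length windows (default five of 4,000 nt; 500/1,000 as
  alternates) per region per chromosome, with the eligibility rules
  that exclude chromosomes whose region is absent or shorter than the
  window.
* **Landscape statistics** — per-window profiles (MFE, |MFE|, GC,
  dyad density, ensemble quantities), per-region aggregates, Pearson
  correlations of |MFE| against GC and dyad density, and the
  correlation of per-chromosome |MFE| with missegregation
  probabilities.
* **Synthetic genome generator** — seed-deterministic satellite
  fixtures (tandem HOR arrays with tunable divergence, GC gradients,
  inserted dyads/mirrors, designed exclusion chromosomes) with truth
  tables, so the full pipeline is testable without downloads.

Energy parameters are read from files in the ViennaRNA 2.x text
dialect; a compact DNA ΔG°37 set assembled from the published unified
nearest-neighbor stack values ships with the package
(`satfold/data/dna_unified_dg37.par`), and any file in the dialect —
including the DNA Mathews 2004 set — can be passed instead.

## Worked example

```python
from satfold import FoldOptions, fold, load_parameters, default_parameter_path
from satfold.sequence import revcomp

params = load_parameters(default_parameter_path())
arm = "GCCGTAGGCA"
seq = "TTAAT" + arm + "TTTT" + revcomp(arm) + "TAATT"
res = fold(seq, params, FoldOptions())
print(res.dotbracket())
print(res.mfe_report, res.ensemble_free_energy, res.ensemble_diversity)
```

prints

```
.....((((((((((....)))))))))).....
MFE                    -12.07 kcal/mol
ensemble free energy   -12.19 kcal/mol
ensemble diversity       0.69
```

The inserted dyad symmetry folds back on itself into a 10-bp stem
with a 4-nt loop.  The MFE of −12.07 kcal/mol is the stability of that
hairpin; the ensemble free energy sits just below it and the diversity
of 0.69 means the ensemble is essentially this one structure.

The `examples/` directory holds one short script per capability
(folding, motif scanning, simulate-and-profile, missegregation
correlation), and the `satfold` command exposes the same steps as
subcommands (`simulate`, `sample`, `fold`, `scan`, `profile`,
`correlate`, `run`):

```
satfold simulate --seed 1 -o syn
satfold run --genome syn/genome.fa --annotation syn/regions.bed \
    --missegregation syn/missegregation.tsv --length 500 --seed 1 -o run
```

`run` writes the per-window profile, aggregates, correlation tables,
motif BEDs, dot-bracket structures and a manifest with the seed,
parameter-file header and config hash; reruns are byte-identical.

## Layout

```
src/satfold/
  params.py      nearest-neighbor tables (ViennaRNA 2.x dialect IO)
  sequence.py    DNA containers and encoding
  structure.py   base-pair sets, dot-bracket
  energy.py      loop-decomposition energy of explicit structures
  fold.py        MFE, partition function, ensemble diversity
  _kernels.py    numba DP kernels (inside + outside recursions)
  enumerate.py   exhaustive structure enumeration (test oracle, <= 20 nt)
  motifs.py      dyad scan + seven non-B motif classes
  sampling.py    region annotations, eligibility, window sampling
  stats.py       profiles, aggregates, correlations
  synth.py       synthetic satellite genome generator
  pipeline.py    one-shot orchestration with manifest
  cli.py         click CLI
docs/methods.md  model, parameters, design choices, limitations
```
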