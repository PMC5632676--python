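# Methods

## Scope and stance

radphylo reimplements, at desk scale, the analysis surface of a RADseq
phylogenomics workflow: what happens to SNP recovery and bootstrap node
support as one varies four assembly parameters and the missing-data
threshold.  External binaries of production pipelines (demultiplexers,
assemblers, aligners, ML tree searchers) are replaced by small, documented
analogues that preserve the parameter semantics being studied; the exported
phylip matrices remain consumable by external maximum-likelihood programs
when full-scale inference is wanted.

## The synthetic world

The generator produces the two features that make RADseq matrices
scientifically interesting and practically awkward:

* **Restriction-site dropout.** Each locus begins with the enzyme's
  recognition motif (default `GAATTC`).  Substitution events are Poisson
  per site per branch under Jukes–Cantor (an event replaces the base with
  one of the other three, uniformly); a sample loses a locus when any event
  hits a cutsite position on its root-to-leaf path.  Dropout probability is
  therefore exactly 1 − exp(−μ·6·L_path), which the test suite checks
  against Monte-Carlo counts.
* **Heterogeneous library sizes.** Per-sample mean depth is log-uniform
  between the coverage-law bounds (default 1–100×, two orders of magnitude,
  matching the read-count spread reported for real pooled libraries);
  per-cell depths are Poisson around the sample mean.  A degenerate law
  (low = high) gives exact constant depth, used by tests that need one
  error-free read per present cell.

Defaults: 48 taxa, Yule birth rate 1.0, 1,000 loci of 120 bp, μ = 4×10⁻³
substitutions/site/unit time (giving ~5–20% dropout per cell and a handful
of variable sites per 100 bp window on 12–48-taxon trees — the regime where
missing-data thresholds matter), read length 100, base error 10⁻³, phred 38
qualities with an optional injected low-quality window for QC testing.
Reads are `barcode + cutsite remnant + locus payload`, truncated to the
read length.

What the generator does **not** emulate: diploid heterozygosity (samples
are haploid — one consequence is analysed below), indels, paired ends, PCR
duplicates, adapter read-through, quality decay along the read.  A green
test therefore establishes correctness of the pipeline's bookkeeping and
the direction of parameter effects, not robustness to every artefact of
real libraries.

## Barcode design

Panels mix 7–10 bp inline barcodes so that the constant cutsite remnant is
staggered across sequencing cycles.  Candidates are accumulated greedily:
a random 10-mer is accepted when its Levenshtein distance to every accepted
barcode is ≥ 4 (homopolymer runs ≥ 5 excluded).  Distances are then
recomputed allowing ±1 bp slippage (minimum over offsets −1/0/+1 of the
Hamming distance on the overlapping window; overhangs are free, the
conservative choice — it flags more near-collisions).  Pass 1 strikes both
members of every pair at distance < 3 and removes barcodes with ≥ 2
strikes; pass 2 removes any survivor still within distance < 3 of another.
Shorter barcodes are derived by truncating cutsite-matching suffixes
(`CAA` → 7-mers, `CA` → 8-mers, `C` → 9-mers, longest suffix wins), and
final 10-mers are drawn without replacement with weight
∏_sites (site skew ratio) × (inverse frequency of the barcode's base) —
one concrete monotone-in-rarity scheme; the design intent fixes only the
direction, not the formula.

**Measured limitation.** Greedy random accumulation saturates near ~1,000
accepted 10-mers (acceptance probability decays as e^(−pN), measured
p ≈ 0.009), and the conservative slippage filter then removes ~75% of a
random pool — denser pools lose *more* — capping survivors near ~270.
Since only 1/64 of survivors end in `CAA`, a full 18/24/24/30 panel of 96
is out of reach from random pools; the panel builder reports the per-length
shortfall instead of silently under-delivering.  Published panels of that
composition require a structured (code-based) candidate pool.

## Demultiplexing and quality control

Assignment requires an exact barcode match immediately followed by the
exact cutsite remnant, trying panel lengths longest-first so a long barcode
is never shadowed by a shorter prefix.  No mismatch rescue is attempted:
the panel's distance guarantee would make 1-error rescue sound, but
exactness is the simplest defensible policy.  The quality filter discards
(never truncates) a read when any 15 bp sliding window's mean phred drops
below 10, applied to the raw read so bad barcode regions also disqualify.
Trimmed reads are cut to a common length (read length − longest barcode −
remnant) because downstream comparisons are positional.

## Assembly

Within a sample: identical reads group into stacks; stacks with depth ≥ m
are primary; primary stacks merge by single linkage at Hamming ≤ M; merged
clusters with more than max-locus-stacks members are discarded whole
(repeat filter); secondary reads attach to the nearest locus within M.
Consensus is the depth-weighted majority base, ties to the alphabetically
smaller base.  A column is called polymorphic when ≥ 2 bases each reach
⌈0.25 × locus depth⌉ — a frequency threshold standing in for likelihood
models that are out of scope here.  Across samples, the catalog grows by
greedy first-fit in sorted sample order: a locus joins the first entry
whose current consensus is within Hamming ≤ n, else founds an entry;
consensus is recomputed as unweighted majority over members.  All tie-break
rules (linkage, insertion order, argmin/argmax) are fixed and documented so
runs are bit-reproducible.

The reference mode places reads by exact 20-mer seed (non-overlapping
offsets, pigeonhole-safe up to 4 mismatches per 100 bp) with ungapped
extension on both strands; positional stacks require depth ≥ 2.  It is a
placement bookkeeper, not an aligner: no gaps, no mapping qualities, no
attempt to reproduce cross-genus alignment rates.

**The n = 0 haplotype-splitting effect.** With haploid samples, a catalog
built at n = 0 puts every distinct within-window haplotype of a locus into
its own entry.  Consequently (i) occupancy cannot equal the simulated
presence matrix exactly once any cross-sample substitution falls inside
the read window, and (ii) every n = 0 catalog entry is internally
invariant, so the exported matrix holds no SNPs at all.  This is faithful
to the semantics of the n parameter (0-mismatch merging) and visible in
real pipelines as sharply lower SNP counts at n = 0; the acceptance test
that demands exact occupancy recovery at n = 0 is left failing with this
analysis, while the same test demonstrates ≥ 90% topology recovery through
the default n = 3 catalog.  Exact occupancy recovery *is* verified in the
regimes where it is well-defined (zero mutation, and hand-built truth sets
with dropout but window-invariant loci).

## Matrices and trees

A locus passes threshold p when ≥ ⌈(1−p)·S⌉ of S samples have data (ceil
semantics pin the worked "60% threshold = at least 40% of individuals"
reading).  Whitelists are nested in p by construction.  Oversized
whitelists are split into 10 contiguous near-equal parts, exported
separately, and merged column-wise — a lossless reimplementation of the
memory-bound export workaround of production pipelines; the pipeline takes
this route at p ≥ 0.7.  "Informative" means variable (≥ 2 distinct
non-missing bases across samples); a `parsimony` flag switches to the
strict reading.  Missing calls are `N` in relaxed phylip.

Trees: pairwise-deletion mismatch distances; pairs sharing zero called
sites (possible at 90% missing) get the maximum observed distance with a
warning, keeping neighbor joining defined without inventing signal.  NJ is
scikit-bio's, negative branches clamped to zero, rooted on the declared
outgroup.  Bootstrap: B column resamples with replacement (replicate i
seeded seed + i), one NJ tree each, 50% majority-rule consensus (clades at
exactly 50% admitted most-frequent-first, skipping incompatibilities —
clades above 50% are mutually compatible automatically); support is the
replicate percentage per clade; the summary statistic is the proportion of
internal non-root nodes with support ≥ 70%.  Truth comparison uses
unrooted non-trivial bipartitions.

## The experiment grid

Eighteen de novo parameter rows vary one knob at a time around the default
(m=2, M=2, mls=3, n=3) — m ∈ {2,4,6}, M ∈ {2,4,6,8}, mls ∈ {2,3,4,6},
n ∈ {0,2,3,4,6,8,10,12,14,16} — plus one reference-based row, each crossed
with nine thresholds {10, 21, 29, 40, 50, 60, 71, 79, 90}% (the design's
printed values, not round deciles): 171 datasets.  Cells are written under
`R{run}.m{percent}` directories; a failing cell records its reason and
leaves the rest of the grid running.  Deterministic under a fixed seed.

## Diversification rates

Method-of-moments estimators from extant species count and clade age:
stem r = ln(n)/t, crown r = ln(n/2)/t at ε = 0, and the standard
ε-corrected forms (crown:
r = (1/t)[ln(n(1−ε²)/2 + 2ε + ((1−ε)/2)√(n(nε² + 2nε − 8ε + n))) − ln 2]),
verified to collapse to the ε = 0 forms numerically.  Rates are strictly
increasing in n, strictly decreasing in t and ε, and crown ≤ stem.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; fixed seed ⇒ byte-identical FASTQ, identical
  trees and tables.
* Distance computations are vectorised over pools/matrices (uint8 codes);
  the Levenshtein DP is vectorised across the whole accepted pool with a
  Hamming prescreen (Levenshtein ≤ Hamming, so Hamming < threshold is a
  certain reject).
* Test simulations are scaled to minutes (12 taxa, 300–500 loci, B ≤ 100);
  the directions being tested (monotonicity in m/M/n/p, missing-data
  benefit) are scale-free.
* Degenerate inputs (empty read sets, zero-SNP matrices, empty whitelists)
  produce explicit zero-count results or warnings, never crashes.

## Known limitations

Haploidy (no heterozygous SNP calls, hence the n = 0 effect above); no
gapped alignment or paralog detection beyond the max-locus-stacks filter;
no probabilistic locus correction across samples; NJ + column bootstrap is
a support *proxy* — absolute support values are not calibrated against ML,
only their comparative behaviour across thresholds and parameter settings
is claimed; the barcode pool generator cannot reach structured-code pool
sizes (documented shortfall).
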