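# Methods

This note documents the models implemented in `temelano`, the parameters
that matter, the numerical choices made where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## Coordinates and randomness

All in-memory coordinates are 0-based half-open; conversion to 1-based
happens only at the GFF3 input and nowhere else (BED output is already
half-open). One user-facing seed governs all randomness; each component
derives an independent 31-bit stream by SHA-256 hashing of
`(seed, component name)` (`temelano._rng`), so adding or reordering a stage
never perturbs another stage's draws. Equal-score alignment ties are broken
by a hash of `(seed, read id)` — a per-read deterministic substream — so the
outcome is invariant under read reordering or parallel execution.

## Seeded aligner (masking, read mapping, relocation)

The masker is a desk-scale seeded aligner, not a competitor to
RepeatMasker/cross_match on real genomes:

- **Seeds**: exact k-mers (default k = 12, valid range 8–32) located through
  a sorted numpy index; k-mers containing non-ACGT symbols are skipped.
- **Chaining**: seed matches on the same reference chain into one candidate
  locus when their diagonals agree within 50 bp and successive target
  positions advance by < 400 bp. At 20% divergence the expected spacing of
  matching 12-mers is ~15 bp, so a chain break is vanishingly unlikely
  within a real copy. Genome scans require ≥ 2 seeds per cluster (suppresses
  the ~0.3 spurious single-seed clusters expected per consensus on a
  multi-Mb genome); read mapping accepts single seeds.
- **Verification**: the consensus fragment spanned by the seeds is aligned
  inside a padded genomic window with edlib (edit-distance-optimal path),
  then rescored under the reporting scheme match +1 / mismatch −2 / gap −3
  per gapped base. For the substitution-dominated divergence this pipeline
  targets, the edit-distance optimum and the rescored optimum coincide for
  all practical purposes.
- **End extension**: hit ends are extended ungapped with an X-drop rule
  (default 30). Because only the best-scoring prefix is kept, a generous
  X-drop cannot extend a hit into flanking sequence; it determines how large
  a local mismatch cluster the extension survives. An X-drop of 12 was
  observed to truncate roughly one copy end per ~600 planted copies at 20%
  divergence (a ~0.1% random-walk dip probability per end), which breaks the
  exactness of full-length calling; at 30 the dip probability is ~1e-7.
- **Reporting**: hits below `min_score` (default 50 for genome scans, 40 for
  100 nt reads) are dropped. Identity is matches / alignment columns
  (gapped columns included).

Read relocation on the genome drops reads with more than `max_locations`
(default 999) equal-best placements, then keeps one placement under the same
per-read random-choice contract as library mapping.

## Library curation

- **Length filter**: consensi < 80 nt are removed (80 nt itself is kept).
- **Terminal repeats**: the first and last halves of a consensus are locally
  aligned (match +1, mismatch −1, gap −2) — equivalent to self-alignment
  with the trivial diagonal masked; a pair of ≥ `min_repeat_len` columns at
  identity ≥ `min_identity` flags an LTR/satellite candidate. The thresholds
  are explicit configuration because dot-plot inspection has no canonical
  numeric rule.
- **Redundancy**: a pair is redundant when its best local alignment
  (match +1 / mismatch −2 / gap −3) has e-value < 1e-20 and spans ≥ 80% of
  *both* sequences. E-values use ungapped Karlin–Altschul statistics with λ
  solved numerically for the +1/−2 scheme at uniform base composition and
  K fixed at 0.1 (a typical ungapped DNA value); only a monotone transform
  of the score matters for a fixed threshold, so the constant K does not
  affect which pairs fall below the cut in practice. Consensi are visited
  longest-first (ties: id ascending) and kept greedily unless redundant with
  an already-kept one — keep-longest maximizes retained information, and the
  greedy order makes curation idempotent and order-invariant.
- **Unknown renaming**: six-frame stop-free peptide segments (≥ 20 aa) of
  each *Unknown* consensus are locally aligned (BLOSUM62, gap open −11 /
  extend −1) against a labeled TE-protein set; the best hit ≥ `min_bits`
  (default 50) donates its classification. An optional host-protein decoy
  set removes consensi whose best decoy hit reaches threshold and outscores
  every TE protein — the stand-in for screening against a general protein
  database, which cannot be bundled.
- **Candidate import**: SINE-detector candidates redundant with an existing
  consensus reannotate it to class SINE; all other non-redundant candidates
  are appended, and the merged set is deduplicated under the standard rule.

## Masking post-processing and coverage

Overlap resolution visits hits in descending score (ties: longer, then
leftmost, then family id) and *discards* — never trims — any hit overlapping
a kept hit by ≥ 1 bp. Fragment merging joins same-family, same-strand,
same-chromosome hits whose half-open gap is < 20 bp (a gap of exactly 20 is
not merged); merging is transitive, scores add, identity is length-weighted,
and consensus intervals union. Merging across strands is refused because it
would fabricate chimeric copies. The coverage table keeps full precision
internally and rounds to one decimal only for report output; the per-class
"% of TEs" column is each class's share of the summed TE coverage.

## Divergence landscape

A true multiple alignment is replaced by consensus-anchored star alignment:
each genomic copy is globally aligned to its family consensus (match +1,
mismatch −1, gap −2, free end gaps so truncated copies pay nothing), and
copies are projected into the consensus coordinate frame; insertions
relative to the consensus open shared gap columns. This costs O(copies)
alignments instead of O(copies²) and is adequate for identity histograms.
Copies with < 50% of their bases alignable to the consensus are excluded and
logged. Pairwise identity is matches / columns where neither copy has a gap;
pairs with no comparable columns are recorded as missing. Per family, the
identity histogram (percent bins, default width 1; the top bin is closed at
100) is scaled so its masses sum to the family's genomic density — the
landscape therefore conserves total genomic TE mass, which the tests assert
exactly. This normalization is one reading of "pair counts reported to
genomic density"; it is the documented, tested contract.

## Read quantification and annotation

Mapping to the library and relocation on the genome are deliberately two
separate operations (each independently testable) rather than one fused
step. Adjacency filtering keeps a read iff another read on the same
chromosome starts within 1 kb (inclusive, start-to-start — the simplest
symmetric contract); the sorted sweep is property-tested against the
quadratic definition. Genomic annotation uses standard precedence:
exon > intron > intergenic, with `exon_last` (overlap with a transcript's
strand-aware 3'-most exon) taking precedence over `exon_other` when several
transcripts disagree. Unstranded gene models yield indeterminate last-exon
calls, flagged separately. Both read-level tallies and per-gene tallies are
emitted, since "genes with reads in the last exon" can be counted either way.

## Differential expression

Counts K(f, s) are modeled as NB with mean sf(s)·μ(f, cond(s)) and variance
μ + αμ².

- **Size factors**: median-of-ratios; families containing any zero are
  excluded from the reference. Size factors are identifiable only up to a
  global constant: multiplying one of m samples by c multiplies its factor
  by c^(1−1/m) and the others by c^(−1/m), so factor *ratios* scale by c and
  normalized counts are invariant up to c^(1/m). The tests assert this exact
  form. A pseudo-reference fallback (geometric mean over positive entries)
  is available for sparse matrices.
- **Dispersion**: per-family method of moments on normalized counts,
  α = max(0, (pooled within-condition variance − mean)/mean²), floored at
  1e-8. No empirical-Bayes shrinkage toward a mean trend — a documented
  simplification that keeps the estimator independently testable.
- **Wald test**: log2FC = log2(mean_tg / mean_wt), with a 0.5 pseudocount
  added to a condition mean only when it is zero (config-exposed). The
  standard error follows from the delta method on the NB variances of the
  condition means. The statistic is referred to a **t distribution with
  n_a + n_b − 2 degrees of freedom** rather than the standard normal:
  without dispersion shrinkage the plug-in method-of-moments dispersion is
  noisy, and the normal reference was measured (in a pre-implementation
  prototype) at null type-I ≈ 0.065–0.073 at n = 10 + 10 — the t reference
  restores calibration to ≈ 0.05 and converges to the normal tail as the
  design grows. This mirrors how the reference DE tools buy calibration
  through shrinkage; here the same end is achieved through the reference
  distribution instead.
- **Selection**: the strict rule |log2FC| > 1 AND raw p < 0.05 AND
  baseMean > 100, exactly as used in the original study; BH-adjusted
  p-values are reported alongside for modern practice but do not enter the
  selection.
- **Class aggregates**: per-class sums of normalized counts per sample,
  compared between conditions with the same exact Mann-Whitney test as the
  qPCR stage (the class-level test family is not otherwise pinned down).
  Note that a shift planted in *all* families is absorbed by normalization
  by construction; class-level signal is only identifiable against stable
  classes.

## Structure

ORF policy: ATG-initiated, stop-terminated, ≥ `min_aa` residues (default
100 aa); within a stop-bounded segment the 5'-most ATG defines the ORF.
Reverse-strand ORFs are reported in forward coordinates with negative frame;
`end − start` includes the stop codon. Domain scanning is local BLOSUM62
alignment (open −11 / extend −1) of ORF peptides against user-supplied
reference peptides — labels are free text, so accession-style names can be
carried through. Full-length calling: a (merged) genomic copy is full-length
when its consensus interval covers ≥ 90% of the consensus. Score-ratio
colors partition (0, 1] as blue ≤ 0.25 < green ≤ 0.70 < orange ≤ 0.90 < red,
so bin frequencies under uniform ratios are 0.25/0.45/0.20/0.10.

## qPCR statistics

Relative expression is 2^−(Ct_target − Ct_reference) after averaging
technical duplicates to one Ct per sample; samples lacking a reference Ct
are excluded and logged. The Mann-Whitney U uses midranks; for
n_a + n_b ≤ 16 the two-sided p is exact by enumeration of all C(n, n_a)
group assignments conditioned on the observed midranks (valid under ties),
doubling the smaller tail and capping at 1 — two-sided doubling is the
conservative default since the original comparisons are plain two-group
contrasts. Larger samples use the normal approximation with tie correction
and a 0.5 continuity correction. scipy's implementation serves only as an
independent oracle in the tests (its exact method ignores ties, so the
comparison is restricted to tie-free data).

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical skeleton of a two-condition larval
RNA-seq TE study: a mixed-class consensus library (LTR consensi carry exact
terminal repeats, default 300 nt; LINE consensi end in a 20 nt poly-A
tract), genomes with full-length and truncated copies at controlled
divergence, NB counts with planted log2 fold changes, uniform reads with
i.i.d. substitution errors, and small-n Ct tables. Defaults follow the study
design where stated (10 samples per condition; the DE selection thresholds)
and otherwise use desk-scale values chosen once: read length 100 nt
(configurable — the original library-prep parameters are not published
beyond poly-A enrichment), consensus lengths 500–3000 nt, divergence grid
0.02–0.20 spanning young to middle-aged insertion cohorts, dispersion 0.05
(a typical bulk RNA-seq value), truncated copies keep a uniform 20–70%
fraction so fragments never straddle the 90% full-length boundary, and
insertions are placed with ≥ 50 bp spacing so the 20 bp merge rule cannot
fuse independent copies.

Deliberately not emulated: quality-dependent sequencing errors, adapters,
duplicates, paired ends, spliced transcripts, indel-rich divergence (indel
rate is configurable but defaults to 0 so Hamming-distance oracles stay
exact), CpG-accelerated substitution, and nested insertions. Passing the
planted-truth tests therefore demonstrates correctness of the algorithms
under substitution-dominated divergence at desk scale, not sensitivity
parity with production repeat annotators on real genomes.

Read names carry their truth tag (source family, start) in the FASTQ
description field, which production code paths never read.

## Problem sizes

The test suite and the acceptance script run at deliberately modest sizes:
a 5 Mb single-chromosome genome with 30 families × 20 copies for the
masking/landscape/full-length pipeline (~30 s), 2000 null families at
n = 10 + 10 for type-I calibration, 400 families (100 with planted
|log2FC| ≥ 1.5 at baseMean ≥ 200) for selection sensitivity, and 200–400
simulation seeds for the small-n power and calibration checks. These sizes
were chosen so each contract is measured with comfortable Monte-Carlo margin
while the whole suite stays interactive.

## Known limitations

- The seeded masker requires exact k-mer seeds; sensitivity collapses beyond
  ~30% divergence. Copies shorter than ~50 bp or scoring below `min_score`
  are not reported.
- The DE stage fits a two-group design only: no covariates, no outlier
  replacement, no independent filtering.
- Landscape identities are raw (no multiple-hit correction such as Kimura
  distances), matching the contract of gap-excluded percent identity.
- The coverage table reports the computed class sum; a supplied total that
  disagrees with its own column sum (as in the published medaka table, whose
  printed total exceeds the column sum by ~100 Mb) is surfaced rather than
  reproduced.
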