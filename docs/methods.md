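# Methods

This note documents the statistical procedures atlaskit implements, the
choices made where a published description leaves room, and what the
synthetic-data generators do and do not emulate.

## Library-correlated genes

Each gene row of the FPKM matrix is standardized across libraries,
z_i = (x_i − μ)/s.  The standard deviation uses the sample formula
(ddof = 1) by default, matching the common spreadsheet/statistics default
for small library counts; `compute_zscores(..., ddof=0)` switches to the
population formula.  Both calling thresholds are strict inequalities:
z > 1.5 and FPKM > 1.  Genes with s = 0 carry all-zero z-scores and are
never correlated with any library: a constant gene expresses no library
preference, and z is undefined there anyway.

Because z-scores are scale-free, multiplying a gene's row by a positive
constant never changes its z-row; set membership can then change only
through the FPKM > 1 filter.  Raising either threshold can only shrink the
per-library sets (monotonicity), which the suite verifies.

When rRNA or mitochondrial reads were excluded from a library's mapped-read
total after its FPKM values were computed, `composition.adjust_library_sizes`
rescales that library by 1/(1 − f), f the excluded fraction; rank order
within a library is unaffected.

## Library similarity

The overlap of two libraries' correlated-gene sets is tested against the
hypergeometric null: drawing an x-set and a y-set independently and
uniformly from n genes, the probability of sharing at least c genes is the
tail sum given in the README.  Implementation choices:

* All terms are evaluated in natural-log space with the log-gamma function
  and combined with log-sum-exp.  The factorial form overflows double
  precision near n ≈ 170; the log form is exact to ~1e-15 relative error and
  is verified against exact rational arithmetic for every (n ≤ 30, x, y, c).
* The two set sizes are swapped into canonical order before summation so
  that symmetry in (x, y) holds bit-exactly, not just to rounding.
* Corrected p-values use m = L × L ordered comparisons, including self-pairs
  and both orders, and are capped at 1, so the mapping score
  −log10(p_corrected) is ≥ 0.  Scores are computed from log10 p directly,
  never from the (possibly underflowed) p itself, so a corrected p of
  10^−10000 still yields score 10000.
* The diagonal is computed like any other pair (c = x = y), which makes each
  diagonal score the maximum of its row.
* log2(score), the conventional plotting transform, is undefined at
  score = 0; such cells are exported as missing values rather than −∞.
* Dependence calls are strict: score > 10 (and, on the plotting scale,
  log2 score > 4 ⇔ score > 16 for "closely similar").

The tail test is conservative at discrete c: under the null with n = 2000
and x = y = 100, the observed fraction of p < 0.05 over 1000 seeded
replicates is ~0.02, and the suite requires ≤ 0.07.

## Coverage strata

Depths are normalized to BPKM = depth × 10⁹ / total mapped bases, which is
invariant to uniform depth scaling.  Scaffolds shorter than 200,000 bases
are removed before stratification (strict <): short scaffolds are typically
rRNA/mitochondrial fragments whose reads would dominate the top ranks.

Bases are ranked by BPKM descending; ties are broken by (scaffold id,
position) ascending.  Group means are tie-invariant, but shares can differ
at ties, so the deterministic rule is part of the contract and is tested
against a brute-force full sort (exact share agreement to 1e-12 on a
10⁶-base track).  Only nonzero-depth bases occupy ranks; zero-depth bases
and any transcribed bases ranked past 400·2^18 form an explicit remainder,
so group shares plus remainder always account for all aligned bases (to
1e-9).  A group whose rank span runs past the available nonzero bases is
empty (mean 0) rather than padded.

Annotation coverage is strand-agnostic: a base is covered by a feature class
if any interval of that class overlaps it on either strand.  Coordinates are
1-based inclusive on input (GTF convention) and converted to 0-based
half-open internally.  A gene's span is the maximum distance between its
exons' edges, derived per gene from its exon records; explicit gene rows are
used only for genes without exon records.

Coverage-vs-depth regression is ordinary least squares with intercept,
fitted separately per sequencing mode (single-end vs paired-end), with
per-library residuals reported for outlier inspection.  A mode with fewer
than two points is skipped with a warning rather than an error.

## Composition classifiers

The six-frame ORF scan requires an ATG start by default and counts residues
from the Met through the last codon before the stop; an ORF may run off the
3′ end without a stop (`allow_open_end`, default on), and
`require_atg=False` additionally admits ORFs entering from beyond the 5′
edge.  Codons containing N extend an ORF as unknown residues but can never
serve as the ATG start.  The coding threshold is strict: > 100 residues.

Gene categories apply in precedence order mitochondrial → rRNA → coding →
noncoding, with the scaffold sets required to be disjoint.  Hit-title
categories apply in the fixed order rRNA → mitochondrion → phage →
M. sexta → E. coli → Oryza → others, case-insensitive substring matching,
first match wins; "sexta" alone is deliberately kept as an M. sexta trigger
and "e.coli" matches with a literal dot.  Per-library category fractions sum
to 1 whenever the library has any reads; an all-zero library is flagged
`empty` and reports zeros.

## Codon usage

Genome-based tables pool in-frame codon counts over CDS sequences; a length
not divisible by 3 is an error naming the record, and codons containing N
are excluded with a tally.  CDS counting keeps stop codons (an annotated CDS
includes its stop); ORF-based transcriptome counting excludes the terminal
stop by default (`include_stop` flips it).  Both totals are therefore
available.

Transcriptome usage weights each transcript's ORF codon counts by FPKM,
sums per library, converts to percentages, and averages the percentage
tables *unweighted* across libraries, so deep libraries do not dominate the
mean.  A library whose weighted counts are all zero has undefined
percentages: it is flagged and excluded from the mean.  With all FPKM equal
the weighting cancels and the per-library table equals pooled unweighted
counts — verified exactly.  Frequency tables normalize to 1000 (per-thousand)
or 100 (percent) within 1e-6.

tRNA correlation is the Pearson coefficient between per-amino-acid usage
(synonymous codons summed, stops kept separate) and tRNA gene counts over
the 20 standard amino acids; it is undefined (raised as an error) when
either side has zero variance.

## Synthetic atlases

The generators provide seeded, bit-reproducible inputs with planted truth:

* **FPKM matrices.**  Gene baselines are log-normal (default μ = 1, σ = 1 on
  the natural-log scale — median FPKM ≈ e, heavy right tail, as FPKM
  distributions are in practice), with multiplicative log-normal noise per
  cell (σ = 0.3).  The default design is 8 tissues × 2 stages = 16
  libraries, a scaled-down analogue of a multi-tissue atlas; 5% of genes per
  tissue are planted as tissue-exclusive markers boosted 8-fold in their
  home libraries.  At these defaults a marker is *recovered* — called
  correlated with at least one home library — ≥ 99% of the time, and the
  background false-positive rate per (gene, library) pair is ~7–8%
  (consistent with the ~7% one-sided tail the z > 1.5 cut implies for 16
  near-normal values).
* **Depth tracks.**  Depths are one multinomial draw of the requested total
  over a truncated discrete power law on ranks (weight ∝ rank^−a), shuffled
  onto positions, so total mass is conserved exactly and the top ranks
  dominate (with a = 1.2 on 10⁶ bases, the top 400 ranks carry most of the
  mass).
* **Transcriptomes.**  Each transcript is ATG + internal sense codons drawn
  from a 64-entry weight vector + one stop; stop codons never occur
  internally, and realized codon counts are recorded as ground truth.
* **Hit tables.**  Titles embed each category's keyword with randomized
  casing and keyword-free flanking text; "others" titles contain no keyword.

What the generators do **not** emulate: read-level sampling noise,
gene-length and GC effects on FPKM, shared markers between tissues, library
size imbalance, splice structure, or rRNA/mito contamination gradients.
Passing recovery tests therefore demonstrates that the statistics behave
correctly under their stated model, not that any particular biological
dataset meets that model.

## Problem sizes

The test and acceptance workloads use 2000-gene × 16-library atlases,
10⁶-base depth tracks with 5 × 10⁶ mapped bases, 1000-replicate null
calibrations, and exact-oracle sweeps to n = 30 — sizes at which exact
brute-force oracles remain feasible alongside the production code paths.

## Known limitations

* The correlated-gene definition is threshold-based, not a calibrated test;
  its false-positive rate scales with library count.
* The hypergeometric null treats correlated sets as uniform random draws;
  real sets are structured (housekeeping genes recur), so mapping scores are
  a similarity measure more than a literal p-value.
* Stratification ranks only whole bases; fractional tie-splitting at group
  boundaries is intentionally not implemented (the deterministic tie rule is
  documented instead).
* The ORF scan does not model translation initiation context or
  frameshifts; it is a sequence-level proxy for coding capacity.
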