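# atlaskit

Comparative statistics for multi-library RNA-seq expression atlases.

When an organism has been sequenced across dozens of cDNA libraries spanning
tissues and life stages — as in the *Manduca sexta* 67-library atlas this
package's methods were built around — the basic questions are operational:
which genes are *specific* to a library, how similar are two libraries, how
concentrated is transcription across the genome, what did each library
actually sequence, and how does expression shape codon usage?  atlaskit
implements the whole chain as a tested Python library with a thin CLI, plus a
seeded synthetic-atlas generator that plants known ground truth for every
stage.

## The statistics

**Library-correlated genes.**  For a gene with FPKM values x_i across
libraries, z_i = (x_i − μ)/s with μ and s the gene's mean and standard
deviation over libraries.  A gene is *correlated* with library i when
z_i > 1.5 and x_i > 1.

**Library similarity (mapping score).**  With n genes total, x and y
correlated genes in libraries X and Y, and c shared, the probability of
observing at least c shared genes under independence is the hypergeometric
tail

P = Σ_{i=c}^{min(x,y)} [ x! y! (n−x)! (n−y)! ] / [ n! i! (x−i)! (y−i)! (n+i−x−y)! ]

Bonferroni-corrected by the m = L × L ordered pairwise comparisons (for
67 libraries m = 4489), and reported as the mapping score
−log10(corrected p).  A score above 10 rejects independence; log2(score) > 4
(score > 16) marks closely similar libraries.  All probability work is done
in log-gamma space, so the factorial form never overflows and extreme
significance never underflows.

**Coverage strata (BPKM).**  Per-base depth is normalized to BPKM — bases
per kilobase per million mapped bases, i.e. bases mapped to one base out of
one billion mapped bases.  All bases, sorted by BPKM, are divided into 19
geometric rank groups: group 1 is the top 400 bases and group g covers ranks
(400·2^(g−2), 400·2^(g−1)], so groups 1–4 end at rank 3,200, 1–6 at 12,800,
and 1–12 at 819,200.  Group means, aligned-base shares, and cross-library
z-scores quantify how much of a library's signal a handful of bases carries.

**Composition.**  Genes are classed mitochondrial / rRNA (by scaffold) /
coding (six-frame longest ORF > 100 residues) / noncoding; unmapped-read hit
titles are binned into seven keyword categories (rRNA, mitochondrion, phage,
M. sexta, E. coli, Oryza, others) with first-match-wins priority.

**Codon usage.**  Genome-based usage pools in-frame CDS codon counts;
transcriptome-based usage weights each transcript's longest-ORF codons by
its FPKM per library, takes percentages, and averages them across libraries;
amino-acid-level usage is correlated with tRNA gene counts.

## Worked example

```python
from atlaskit import synthetic_data as sd, expression as ex, similarity as sim

cfg = sd.AtlasConfig(n_genes=2000, seed=42)          # 8 tissues x 2 stages
matrix, truth = sd.generate_fpkm_matrix(cfg)
sets = ex.call_correlated_genes(matrix)              # z > 1.5 and FPKM > 1
print(sets.sizes().head(4))
out = sim.similarity_matrix(sets, n=cfg.n_genes)
print(out.n_comparisons,
      round(out.score.loc["head-L5", "head-A"], 2),
      round(out.score.loc["head-L5", "midgut-L5"], 2))
```

prints

```
head-L5        187
head-A         179
fat_body-L5    199
fat_body-A     179
256 47.53 0.0
```

Each of the 16 libraries carries ~180–200 correlated genes (100 planted
markers per tissue plus background genes that fluctuate past z = 1.5 by
chance).  Of the m = 256 pairwise tests, the two head libraries share their
planted markers and get mapping score 47.5 — far beyond the dependence
threshold of 10 — while head vs midgut shares only chance overlap and scores
0.  Across this atlas, `sets.census()` reports 1836 of the 2000 genes
correlated with at least one library.

The same steps run from the shell:

```
atlaskit simulate --config config.yaml --outdir atlas --seed 42
atlaskit correlate --fpkm atlas/fpkm.tsv --out sets.tsv
atlaskit similarity --sets sets.tsv --n-genes 2000 --out scores.tsv
```

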