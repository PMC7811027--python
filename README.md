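# chalm

Read-level ("clonal") DNA methylation quantification for bulk bisulfite
sequencing, for epigenomics researchers studying how promoter methylation
represses transcription.

## Why

Bulk bisulfite libraries average over a heterogeneous cell population.
The traditional region summaries — the mean of per-CpG ratios,
`(1/n) Σ Cᵢ/(Cᵢ+Tᵢ)`, and the weighted level `Σ Cᵢ / Σ (Cᵢ+Tᵢ)` — treat
CpGs as exchangeable across cells, so a promoter where 20% of cells are
fully methylated is indistinguishable from one where *every* cell carries
a single methylated CpG.  Since one mCpG suffices to recruit
methyl-binding repressors, those two promoters should be repressed in
20% versus 100% of cells.

The clonal quantification treats each read as a proxy for one cell: a
read with ≥ 1 mCpG is a *methylated read*, and the region's level is

    chalm = n_m / (n_m + n_u)

— the methylated-read fraction, 0.2 and 1.0 in the two scenarios above.

The package also provides the surrounding toolchain, exercised entirely on
synthetic or in-repo data:

- **regions**: BED/GTF/refFlat parsing and promoter-CGI derivation
  (CGIs overlapping 2-kb windows around TSSs), 0-based half-open
  coordinates throughout.
- **reads**: SAM/BAM (Bismark-style `XM` tags, via pysam) and a canonical
  TSV dialect; mate merging (disagreements → NA); per-CpG pileup with the
  ≥ 4-read coverage filter; region read-matrices.
- **quantify**: the three quantifications plus the per-CpG clonal
  transform (mCpG propagated along reads) for de novo DMR tools.
- **differential**: beta-binomial empirical-Bayes model per condition;
  posterior-difference p-values by grid convolution of conjugate Beta
  posteriors; BH-FDR with the |Δ| ≥ 0.1, q < 0.05 significance rule;
  Metilene-format export.
- **impute**: EM-estimated low-rank SVD completion of read matrices and
  read extension to a 300-bp effective length.
- **correlation**: balanced promoter subsetting (200 bins × up to 60),
  Spearman correlation, and the pooled-split permutation test comparing
  two correlation coefficients (B = 10,000, no smoothing).
- **readimage / nn**: the 200 × 10 × 2 read-image encoding (f_m-sorted
  pseudo-reads × CpG bins × {methylation, TSS distance}), the
  mCpG-shuffle clonal-disruption control, and a compact numpy CNN
  (kernels (5,1), (4,1), (3,1), ReLU, dropout 0.2, Adam/MSE) for
  expression prediction.
- **simulate**: clonal epiallele mixtures with exact ground truth.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Two populations over one promoter CGI (5 CpGs, 10 reads each): population
A has 2 fully methylated and 8 fully unmethylated reads; population B has
exactly one mCpG on every read.

```sh
chalm quantify --reads popA.tsv --regions promoter.bed --method all
```
```
region          n_reads n_cpgs  chalm   mean    weighted
chr1:1000-1100  10      5       0.2     0.2     0.2
```
```sh
chalm quantify --reads popB.tsv --regions promoter.bed --method all
```
```
region          n_reads n_cpgs  chalm   mean    weighted
chr1:1000-1100  10      5       1       0.2     0.2
```

Both traditional summaries report 0.2 for both populations; the clonal
level separates them (0.2 vs 1), matching the fraction of cells carrying
promoter methylation.  The same computation in Python:

```python
from chalm import MethRead, GenomicInterval, chalm

promoter = GenomicInterval("chr1", 1000, 1100)
cpgs = (1010, 1030, 1050, 1070, 1090)
pop_a = [MethRead(f"m{i}", "chr1", 1000, 1100, "+",
                  tuple((p, "M") for p in cpgs)) for i in range(2)] + \
        [MethRead(f"u{i}", "chr1", 1000, 1100, "+",
                  tuple((p, "U") for p in cpgs)) for i in range(8)]
summary = chalm(pop_a, promoter)
print(summary.chalm, summary.mean_meth)   # 0.2 0.2
```

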