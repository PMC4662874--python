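# chromexo

Analysis pipeline for asking how promoter chromatin marks (the histone
variant H2A.Z, deposited by SWR-C, and H3-K56 acetylation, catalyzed by
Rtt109) and the nuclear RNA exosome (Rrp6) jointly shape coding and
noncoding transcription and higher-order chromosome folding in budding
yeast. Many regulatory effects in this system are invisible in steady-state
RNA because the exosome degrades the relevant transcripts — cryptic unstable
transcripts (CUTs) only become measurable in *rrp6Δ* backgrounds — so the
pipeline is built around genotype contrasts such as *rrp6Δ* vs WT and
double-mutant vs *rrp6Δ*.

The package implements every computational stage of such a study and, since
the original microarray / ChIP-seq / Micro-C datasets are not consumed,
ships a first-class synthetic-data generator that plants known effects so
every estimator is validated by parameter recovery:

- **Tiling expression** (`chromexo.expression`) — probe intensities are
  normalized against a genomic-DNA reference, `x = log2(I/ref)` with
  per-sample median centering, and each transcript is quantified by the
  *midpoint of the shorth*: with order statistics `x(1) ≤ … ≤ x(n)` and
  `h = ⌊n/2⌋+1`, the estimate is `(x(i*) + x(i*+h−1))/2` for the
  width-minimal window `i*` — a robust location estimate that ignores up to
  `⌊(n−1)/2⌋` outlying probes. A background filter keeps transcripts whose
  mean exceeds the noise floor in at least one genotype.
- **Differential classification** (`chromexo.differential`) — an
  empirical-Bayes moderated t: per transcript, `s̃²g = (d₀s₀² + dg s²g)/(d₀+dg)`
  with `(d₀, s₀²)` estimated by moment matching of `log s²g` against its
  scaled-F marginal (digamma/trigamma closed forms, validated against
  Bioconductor limma to 1e-8), BH step-up FDR, and classification into the
  transcript groups A/B (exosome-sensitive and interference ORFs), C/D
  (H3-K56Ac- and H2A.Z-dependent CUTs) and up-regulated ncRNAs at
  FDR < 0.1 and |LFC| > 0.59.
- **Novel-transcript segmentation** (`chromexo.segmentation`) — above-
  threshold runs on the mutant-minus-control difference track, merged
  across ≤ 100 bp gaps, categorized against the annotation (intergenic,
  5′/3′ extension, overlaps-known) and tested in the discovery contrast.
- **RNAPII occupancy** (`chromexo.occupancy`) — library-scaled IP/input
  mean depth per feature and strict >1.3-fold change counting per biotype.
- **Chromosome folding** (`chromexo.contacts`) — distance-decay curves,
  insulation-square profiles, boundary calling, chromosome interaction
  domain (CID) segmentation, per-domain compaction scores
  `CS = log2(Σ observed / Σ expected)` against the matrix's own
  per-distance mean, two-sample KS comparison of CS distributions, and 3C
  anchor-profile normalization to a control region.

## Worked example

The numbered drivers under `analysis/` run each arm of the study on the
default synthetic conditions (six genotypes × three replicates, probe noise
0.25 log2, planted effects ±1.0 log2, hidden novel transcripts at
+1.5 log2):

```
$ python analysis/02_expression_groups.py --seed 1
background threshold 0.398 log2; retained 72/72 transcripts
contrast rrp6_vs_WT: prior df d0=30.10, s0^2=0.0039
group calls: {'none': 44, 'up_ncRNA': 6, 'unchanged_ncRNA': 6, 'A': 4, 'B': 4, 'D': 4, 'C': 4}
agreement with planted truth: 72/72
upstream-vs-downstream Spearman rho = -0.038 (permutation p = 0.808, n = 38 ORFs)
```

Every planted group label is recovered: the four exosome-sensitive ORFs
(group A) are up in *rrp6Δ* and restored in *rtt109Δ rrp6Δ*, the
H2A.Z-and-H3-K56Ac-dependent CUTs land in group D, and the upstream window
(−100..TSS) does not predict gene-body signal, as expected when ORF
induction is not termination read-through. Likewise:

```
$ python analysis/05_chromosome_folding.py --seed 1
boundaries: 11 called in WT; positions identical in the mutant; mean strength change -7.7% (boundaries largely intact)
compaction scores: median dCS = -0.466 (planted log2 0.7 = -0.515); KS D = 1.000, p = 0
3C WT: terminal/penultimate = 3.12 -> gene ends loop
3C swr1: terminal/penultimate = 0.78 -> gene ends do not loop
```

i.e. the mutant weakens intra-domain compaction (planted 0.7×) while CID
boundaries stay in place — the folding phenotype the pipeline is designed
to detect.

The same stages are available as a CLI
(`chromexo run --seed 1 --outdir out`, or per stage:
`simulate`, `quantify`, `diff`, `classify`, `segment`, `occupancy`,
`contacts`, `report`), driven by a validated YAML config whose resolved
copy is written next to the outputs; identical config + seed gives
byte-identical outputs.

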