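# Methods

## The synthetic study

All estimators are validated by parameter recovery on simulated data, so
the generator (`chromexo.synthetic`) defines the study conditions.

**Genome and annotation.** Two 60 kb chromosomes carry an ORF cassette
every 3 kb (lengths uniform 1–2 kb) on a `+ + − −` strand pattern, which
yields tandem, convergent and divergent gene junctions in fixed
proportions. Divergent CUTs (lengths log-normal around a 400 bp median,
clipped to 120–900 bp) sit on the opposite strand of `+` ORF promoters,
separated by a 150 bp nucleosome-free spacer; SRTs occupy the 3′–3′ gap of
convergent pairs; SUTs run antisense within two ORFs; NOVEL transcripts
are placed at tandem junctions, either free-standing (intergenic, ≥150 bp
from the upstream ORF end) or contiguous with an ORF's 3′ end (20 bp gap;
a 3′ extension). NOVELs are withheld from the emitted annotation so the
segmentation stage can be scored on rediscovery. Coordinates are 0-based
half-open throughout; each generator draws from its own RNG stream
(`seed + fixed offset`) so adding one output never perturbs another.

**Expression model.** Six genotypes (WT, rrp6, swr1 rrp6, rtt109 rrp6,
swr1, rtt109) × 3 replicates. Each feature belongs to an archetype whose
planted log2 level per genotype encodes the biology: CUTs are at
background unless rrp6 is inactivated; group-A ORFs gain +1 log2 in rrp6
and lose it again in rtt109 rrp6; group-D CUTs additionally lose 1 log2 in
swr1 rrp6; up-regulated SRTs gain +1 log2 in swr1 rrp6; hidden NOVELs are
+1.5 log2 in swr1 rrp6 only. Probe intensity is
`reference(pos) · 2^(level + N(0, 0.25))` — log-normal probe noise with no
extra between-replicate variance component; the reference track is
strictly positive with ±0.5 log2 positional jitter. Probe spacing (8 bp)
and noise SD (0.25 log2) are simulator choices, not literature values.

**Coverage model.** Input is uniform Poisson depth (50×/bp); IP
multiplies the input mean by the planted IP/input enrichment (ORFs 2.0,
CUTs 1.5, else 1.0), with 15% of ORFs/CUTs reduced 1.5-fold in rtt109
backgrounds. The 15% fraction is an analytic design choice: feature-level
occupancy uses total-signal library scaling, which absorbs any *global*
occupancy shift into every ratio — at 15% affected the genome-mean shift
is ≈0.05 log2, small against the planted 0.585 log2 effect. The same
caveat applies to real data: total-count normalization cannot see a fully
uniform polymerase loss, only relative ones. For the same reason the
recoverable parameter is the WT:mutant fold per feature (the quantity the
fold-change counter thresholds), not the absolute enrichment.

**Contact model.** Matrices are Poisson samples of
`E[c(i,j)] = scale · |i−j|^(−α) · m(i,j)` with α = 1 and 200 bp
(nucleosome-scale) bins. `m` multiplies in the domain intensity for
same-domain pairs and one boundary-depletion factor `b = 0.2` per planted
boundary crossed. The depletion factor is deliberate: boundary strength in
an insulation profile scales with `log2(intensity/b)`, so without an
independent boundary mechanism any compaction loss would erase boundaries
too; with it, reducing intensity 2.0 → 1.4 (the swr1 condition) changes
boundary strength by ~15% while compaction drops — matching the observed
phenotype of weakened domains with intact boundaries. Default domains tile
the chromosome every 25 bins (~5 kb, one to five genes each).

Two dedicated configurations avoid estimator-model interactions:
`decay_scenario` has no planted structure (pure power law) for
decay-exponent recovery, and `compaction_scenario` plants four sparse
25-bin domains on a 1200-bin chromosome (WT intensity 1.0, mutant 0.7).
Sparsity matters because the expected model is the matrix's own
per-distance mean: when domains tile the chromosome the expectation
absorbs the planted intensity and compaction scores compress toward zero;
with ~8% of bins in domains the analytic bias of ΔCS is <0.07 log2, so
the median ΔCS reads out log2 0.7 directly.

**3C model.** Anchor-fragment frequencies decay with fragment-index
distance to the power −α; the terminal fragment is boosted by the loop
strength (4 in the looped genotype, 1 otherwise); replicate scatter is
log-normal (0.2 log2); a fixed control-fragment frequency provides the
normalization unit.

## Estimators

**Shorth midpoint.** `h = ⌊n/2⌋ + 1` (strict majority), width-minimal
window of `h` consecutive order statistics, ties broken by the smallest
left endpoint; midpoint of that window. Equal to an exhaustive
interval-enumeration oracle; translation- and scale-equivariant; breakdown
point ⌊(n−1)/2⌋. Features with <5 probes are flagged (`few_probes`), not
dropped: the window statistic is unstable below that.

**Normalization.** log2(intensity/reference), then per-sample median
centering (each array's genome-wide median → 0). Centering is exposed as a
switch (`median_center`) since reference normalization alone already
removes sequence effects; the default removes array-scale differences
without distorting within-array ratios.

**Background threshold.** Mean + 2 SD of normalized values at unannotated
positions, estimated per run. A transcript is retained when its mean in at
least one genotype exceeds the threshold — this keeps exosome targets that
are silent in WT but high in rrp6 backgrounds.

**Moderated t.** Pooled two-sample variance `s²g` on `dg = n₁+n₂−2` df;
prior `(d₀, s₀²)` by moment matching of `log s²g` (mean/variance matched to
digamma/trigamma expressions; trigamma inverse by Newton, d₀ capped at 500
and treated as infinite above it, in which case the normal limit is used
for p-values). Posterior `s̃²g = (d₀s₀² + dg s²g)/(d₀+dg)`; t on `d₀+dg`
df; BH step-up per contrast over background-retained transcripts. The
implementation reproduces Bioconductor limma's eBayes on a frozen fixture
to 1e-8 and collapses to the ordinary pooled t at d₀ = 0.

**Group rules.** Strict inequalities at the printed cutoffs (padj < 0.1,
LFC > 0.59 or < −0.59). The second gate of groups A–D ("reduced by more
than 0.59 LFC in the double mutant") is an LFC-only condition, read as
LFC < −0.59. Precedence yields one label per transcript: D before C for
CUTs, then A/B for ORFs, then up_ncRNA for any ncRNA, then
unchanged_ncRNA for remaining SRTs, else none.

**Segmentation.** Discovery runs on mean(swr1 rrp6) − mean(rrp6) log2
signal rather than the raw mutant track: on raw signal a 3′ extension
merges with its constitutively expressed parent ORF into one
overlaps-known segment whose quantification is dominated by unchanged ORF
probes, so extension-type novels would be systematically missed. The
difference track isolates newly appearing signal and directly encodes the
discovery contrast. Threshold = background + 3 SD of the difference track
(per-probe false-mark rate ≈0.1%; at 2 SD an analytic run-length estimate
gives ~1 spurious run per chromosome); gaps ≤100 bp merged; runs need
≥150 bp and ≥5 probes. Categorization: ≥50% overlap with a same-strand
feature → overlaps_known; else contiguity (≤100 bp gap) with a feature's
3′ (or 5′) end → extension; else intergenic. Passing novels must be
significant in swr1 rrp6 vs rrp6 (padj < 0.1, LFC > 0.59) and below
background in WT and swr1. All parameters are exposed; the curation the
original workflow did by hand is replaced by these logged rules.

**Occupancy.** Mean per-bp depth over [start, end) divided by total track
signal, ratio = scaled IP / scaled input; zero-input features flagged
`undefined` and excluded from counts; the >1.3-fold counter uses strict
inequalities on the ratio of ratios.

**Contacts.** d_min = 2 bins everywhere (self and adjacent-bin pairs are
dominated by self-ligation artifacts at nucleosome resolution). Decay
curves default to log2(mean + pseudocount) with mean-of-log exposed as a
switch. The insulation pseudocount is calibrated to the genome-mean
insulation square so the centered profile is exactly scale invariant;
window w = 4 bins by default. Boundaries are insulation minima with
prominence ≥0.5; strength = mean flanking maxima − minimum. CIDs tile
between consecutive boundaries (chromosome ends closing the first/last);
domains shorter than 5 bins are discarded. The compaction score uses no
pseudocount so the expectation-equal and doubled-domain identities are
exact; a domain with no eligible pair is flagged `too_short`. KS p-values
are asymptotic (sample sizes here make the limit adequate); the
observed/expected CS formula is this package's operationalization,
validated by planted-truth recovery rather than claimed bit-equivalence to
any published pipeline.

**Interference correlation.** Spearman rho between shorth midpoints of the
[TSS−100, TSS) and [TSS, TSS+100) windows on the ORF's own strand (strand
aware: upstream lies at larger coordinates for − ORFs), with a two-sided
permutation p (999 permutations). Rank correlation is used because the
expression scale is heavy tailed.

## Problem sizes

Defaults are desk scale by design: 120 kb genome, 30,000 probes per
sample × 18 samples, 300-bin contact matrices, 5–10 simulation seeds per
recovery estimate in the acceptance script. The full pipeline runs in a
few seconds; the acceptance script in well under a minute.

## What passing does and does not show

The generator emulates log-normal probe noise, Poisson counts, planted
group structure, hidden transcripts, block-structured domains over a
power-law decay, and a single gene loop. It does not emulate probe
cross-hybridization or sequence-dependent probe affinity, biological
replicate variance beyond measurement noise, mappability or GC artifacts
in coverage, matrix-balancing biases, trans contacts, or condition-
dependent annotation errors. Recovery results therefore demonstrate
correctness of the estimators under the stated noise models, not
robustness to every artifact of the original assays. The classifier's
near-perfect label recovery at the default settings reflects the large
planted effects relative to probe noise averaged over many probes; real
transcripts near the significance thresholds would be classified with
error rates governed by the same moderated-t power curve.
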