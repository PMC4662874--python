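"""Synthetic-data generators with planted ground truth.

The toy genome is a cassette layout: ORFs every ``orf_spacing_bp`` on a
``+ + - -`` strand pattern, which creates tandem, convergent and divergent
junctions.  Divergent CUTs sit on the opposite strand of ``+`` ORF promoters,
SRTs occupy the 3'-3' gap of convergent pairs, SUTs run antisense to a few
ORFs, and NOVEL transcripts (withheld from the public annotation so the
segmentation stage can be scored on rediscovery) are placed at tandem
junctions either as free-standing intergenic units or as 3' extensions of an
ORF.

Noise model: log-normal on probe intensities (normal in log2), Poisson on
sequencing-type counts.  Each generator draws from its own RNG stream seeded
``seed + fixed offset`` so adding one output never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromexo.config import ARCHETYPE_LABELS, SimulationConfig

# fixed per-generator seed offsets (one stream per generator)
_SEED_ANNOTATION = 11
_SEED_PROBES = 23
_SEED_COVERAGE = 37
_SEED_CONTACTS = 53
_SEED_THREEC = 71

FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "biotype"]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class ProbeTable:
    """Per-probe, per-strand, per-sample tiling intensities.

    ``data`` columns: chrom, pos, strand, sample, and either ``intensity``
    (raw) or ``value`` (log2 ratio after normalization).  ``reference`` maps
    (chrom, pos) to the strictly positive genomic-DNA reference intensity.
    """

    data: pd.DataFrame
    reference: pd.DataFrame  # columns: chrom, pos, ref
    normalized: bool = False

    @property
    def value_column(self) -> str:
        return "value" if self.normalized else "intensity"


@dataclass
class CoverageTrack:
    """Per-bp read depth, one array per chromosome."""

    genotype: str
    values: dict[str, np.ndarray]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class ContactMatrix:
    """Symmetric nucleosome-bin contact counts for one chromosome."""

    chrom: str
    bin_size_bp: int
    counts: np.ndarray  # dense (n_bins, n_bins), symmetric

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(c, c.T):
            raise ValueError("contact matrix must be symmetric")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("contact counts must be finite and non-negative")
        self.counts = c


@dataclass
class ThreeCProfile:
    """Anchor-based 3C interaction profile over one model gene.

    ``fragments`` columns: fragment_id, start, end, dist (fragment index
    distance from the anchor), raw (replicate mean), raw_sd, and after
    :func:`chromexo.contacts.normalize_3c` also normalized / normalized_sd.
    """

    anchor_id: str
    fragments: pd.DataFrame
    control_raw: float
    n_replicates: int = 1


@dataclass
class GroundTruth:
    """Everything the generators planted, keyed the way the scorers need it.

    ``features`` has one row per transcript (including withheld NOVELs) with
    planted per-genotype expression (``expr_<genotype>``, log2 above
    background), IP/input occupancy (``occ_<genotype>``), the archetype, the
    true differential-group label, and for NOVELs the true category.
    """

    features: pd.DataFrame
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    domains: pd.DataFrame | None = None

    def public(self) -> pd.DataFrame:
        """The emitted annotation: every feature except the hidden NOVELs."""
        pub = self.features[self.features["biotype"] != "NOVEL"]
        return pub[FEATURE_COLUMNS].reset_index(drop=True)


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------
def _sample_cut_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    ln = config.cut_median_bp * 2.0 ** rng.normal(0.0, config.cut_length_log2_sd)
    return int(np.clip(round(ln), 120, 900))


def generate_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Lay out the toy genome and plant the ground truth.

    Returns ``(annotation, truth)`` where ``annotation`` is the public
    feature table (NOVELs withheld) and ``truth`` records every planted
    feature, expression level, occupancy ratio, and the contact-domain
    geometry.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + _SEED_ANNOTATION)
    L = config.chrom_length_bp
    spacing = config.orf_spacing_bp
    lo, hi = config.orf_length_range
    n_slots = (L - hi) // spacing
    if n_slots < 8:
        raise ValueError(
            f"genome too small: {L} bp per chromosome places only {n_slots} ORF "
            f"cassettes at {spacing} bp spacing; >= 8 are needed to plant every "
            "feature archetype"
        )

    rows: list[dict] = []
    counters: dict[str, int] = {}

    def add(chrom, start, end, strand, biotype, archetype, category="", parent=""):
        counters[biotype] = counters.get(biotype, 0) + 1
        fid = f"{biotype}_{chrom}_{counters[biotype]:03d}"
        rows.append(dict(feature_id=fid, chrom=chrom, start=int(start),
                         end=int(end), strand=strand, biotype=biotype,
                         archetype=archetype, novel_category=category,
                         parent_id=parent))
        return fid

    for chrom in config.chromosomes:
        counters.clear()
        starts = [1000 + i * spacing for i in range(n_slots)]
        strands = ["+", "+", "-", "-"]
        orf_lens = rng.integers(lo, hi + 1, size=n_slots)

        # archetype assignment: shuffle slot indices once per chromosome
        slot_order = rng.permutation(n_slots)
        orf_arch = {int(slot_order[0]): "ORF_A", int(slot_order[1]): "ORF_A",
                    int(slot_order[2]): "ORF_B", int(slot_order[3]): "ORF_B"}

        orf_ids, orf_iv = [], []
        for i, s in enumerate(starts):
            e = s + int(orf_lens[i])
            strand = strands[i % 4]
            arch = orf_arch.get(i, "ORF_NONE")
            fid = add(chrom, s, e, strand, "ORF", arch)
            orf_ids.append(fid)
            orf_iv.append((s, e, strand))

        # divergent CUTs on the opposite strand of + ORF promoters
        plus_slots = [i for i in range(n_slots) if strands[i % 4] == "+"]
        cut_arch_cycle = (["CUT_C", "CUT_D"] * 2 + ["CUT_UP"]
                          + ["CUT_STABLE"] * (len(plus_slots) - 5))
        cut_slots = rng.permutation(plus_slots)
        for arch, i in zip(cut_arch_cycle, cut_slots):
            s_orf = starts[i]
            ln = _sample_cut_length(rng, config)
            cend = s_orf - 150
            cstart = cend - ln
            # avoid same-strand (-) overlap with the previous cassette's ORF
            if i > 0 and strands[(i - 1) % 4] == "-":
                prev_end = starts[i - 1] + int(orf_lens[i - 1])
                cstart = max(cstart, prev_end + 50)
            if cend - cstart >= 100:
                add(chrom, cstart, cend, "-", "CUT", arch)

        # SRTs in the 3'-3' gap of convergent (+ then -) pairs
        conv = [i for i in range(n_slots - 1)
                if strands[i % 4] == "+" and strands[(i + 1) % 4] == "-"]
        srt_arch = ["SRT_UP", "SRT_UP"] + ["SRT_UNCH"] * (len(conv) - 2)
        for arch, i in zip(srt_arch, rng.permutation(conv)):
            gap_lo = starts[i] + int(orf_lens[i]) + 120
            gap_hi = starts[i + 1] - 50
            ln = min(400, gap_hi - gap_lo)
            if ln >= 150:
                add(chrom, gap_lo, gap_lo + ln, "+", "SRT", arch)

        # SUTs antisense to two plain ORFs
        plain = [i for i in range(n_slots)
                 if orf_arch.get(i, "ORF_NONE") == "ORF_NONE"]
        for i in rng.permutation(plain)[:2]:
            s = starts[i] + 200
            anti = "-" if strands[i % 4] == "+" else "+"
            add(chrom, s, s + 600, anti, "SUT", "SUT")

        # NOVEL transcripts at + tandem junctions (withheld from annotation)
        tandem = [i for i in range(n_slots - 1)
                  if strands[i % 4] == "+" and strands[(i + 1) % 4] == "+"]
        tandem = list(rng.permutation(tandem))
        n_ext = 1
        for k, i in enumerate(tandem[:4]):
            e_orf = starts[i] + int(orf_lens[i])
            if k < n_ext:  # 3' extension: contiguous with the parent ORF
                add(chrom, e_orf + 20, e_orf + 20 + 400, "+", "NOVEL",
                    "NOVEL", category="extension_3prime", parent=orf_ids[i])
            else:          # free-standing intergenic unit
                s = e_orf + 150
                add(chrom, s, s + 450, "+", "NOVEL", "NOVEL",
                    category="intergenic")

    feats = pd.DataFrame(rows)
    arch_table = config.expression_archetypes()
    for g in config.genotypes:
        feats[f"expr_{g}"] = [arch_table[a][g] for a in feats["archetype"]]
    feats["true_label"] = [ARCHETYPE_LABELS[a] for a in feats["archetype"]]

    # planted RNAPII occupancy ratios
    base_occ = feats["biotype"].map(
        {"ORF": config.orf_enrichment, "CUT": config.cut_enrichment}
    ).fillna(1.0)
    eligible = feats["biotype"].isin(["ORF", "CUT"]).to_numpy()
    drop = np.zeros(len(feats), dtype=bool)
    idx = np.flatnonzero(eligible)
    n_drop = int(round(config.occupancy_fraction * len(idx)))
    drop[rng.choice(idx, size=n_drop, replace=False)] = True
    feats["occ_decreased"] = drop
    for g in config.genotypes:
        occ = base_occ.copy()
        if g.startswith("rtt109"):
            occ = occ.where(~drop, occ / config.occupancy_drop)
        feats[f"occ_{g}"] = occ

    _check_no_same_strand_overlap(feats)

    boundaries = {c: np.asarray(config.domain_boundaries(), dtype=int)
                  for c in config.chromosomes}
    domains = pd.DataFrame(
        [dict(chrom=c, start_bin=s, end_bin=e)
         for c in config.chromosomes for s, e in config.domains()]
    )
    truth = GroundTruth(features=feats, boundaries=boundaries, domains=domains)
    return truth.public(), truth


def _check_no_same_strand_overlap(feats: pd.DataFrame) -> None:
    for (_, _), grp in feats.groupby(["chrom", "strand"]):
        g = grp.sort_values("start")
        bad = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if bad.any():
            raise AssertionError("generator placed overlapping same-strand features")


# ----------------------------------------------------------------------
# probes
# ----------------------------------------------------------------------
def simulate_probes(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    noiseless: bool = False,
) -> ProbeTable:
    """Simulate strand-specific probe intensities for every sample.

    intensity = reference(pos) * 2**(planted level + N(0, noise_sd)), where
    the planted level is the background log2 level plus the feature's
    genotype-specific expression for probes inside a (true) feature.  The
    public ``annotation`` argument is accepted for interface symmetry; levels
    are planted from ``truth`` so that hidden NOVELs emit signal too.
    """
    if config.noise_sd < 0:  # config already guards; defensive for ad-hoc calls
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(config.seed + _SEED_PROBES)
    L = config.chrom_length_bp
    pos = np.arange(0, L, config.probe_spacing_bp, dtype=int)
    bg_log2 = float(np.log2(config.background_mean))

    # reference track: strictly positive, deterministic per position
    ref_by_chrom = {
        chrom: config.reference_level
        * 2.0 ** rng.uniform(-config.reference_jitter, config.reference_jitter,
                             size=pos.size)
        for chrom in config.chromosomes
    }

    # per (chrom, strand, genotype) planted level arrays
    levels: dict[tuple[str, str, str], np.ndarray] = {}
    for chrom in config.chromosomes:
        for strand in "+-":
            for g in config.genotypes:
                levels[(chrom, strand, g)] = np.full(L, bg_log2)
    for row in truth.features.itertuples():
        for g in config.genotypes:
            lv = getattr(row, f"expr_{g}")
            arr = levels[(row.chrom, row.strand, g)]
            arr[row.start:row.end] = bg_log2 + lv

    frames = []
    sg = config.sample_genotypes
    for chrom in config.chromosomes:
        ref = ref_by_chrom[chrom]
        for strand in "+-":
            for sample in config.samples:
                lv = levels[(chrom, strand, sg[sample])][pos]
                noise = 0.0 if noiseless else rng.normal(0.0, config.noise_sd,
                                                         size=pos.size)
                frames.append(pd.DataFrame(dict(
                    chrom=chrom, pos=pos, strand=strand, sample=sample,
                    intensity=ref * 2.0 ** (lv + noise))))
    data = pd.concat(frames, ignore_index=True)
    reference = pd.concat(
        [pd.DataFrame(dict(chrom=c, pos=pos, ref=ref_by_chrom[c]))
         for c in config.chromosomes],
        ignore_index=True,
    )
    return ProbeTable(data=data, reference=reference, normalized=False)


# ----------------------------------------------------------------------
# coverage
# ----------------------------------------------------------------------
def simulate_coverage(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    genotype: str = "WT",
    noiseless: bool = False,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate (IP, input) per-bp coverage for one genotype.

    input is uniform depth with Poisson noise; IP multiplies the input mean
    by the planted IP/input occupancy ratio over each feature (strandless,
    as for a Pol II ChIP).  In noiseless mode both tracks are the exact
    Poisson means.
    """
    if genotype not in config.genotypes:
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(config.seed + _SEED_COVERAGE
                                + config.genotypes.index(genotype))
    L = config.chrom_length_bp
    ip_vals, in_vals = {}, {}
    for chrom in config.chromosomes:
        ratio = np.ones(L)
        # only ORFs and CUTs carry IP enrichment; antisense features (occ = 1)
        # must not overwrite their host ORF in the strandless paint
        sub = truth.features[(truth.features["chrom"] == chrom)
                             & truth.features["biotype"].isin(["ORF", "CUT"])]
        for row in sub.itertuples():
            ratio[row.start:row.end] = getattr(row, f"occ_{genotype}")
        mean_in = np.full(L, config.coverage_depth)
        mean_ip = mean_in * ratio
        if noiseless:
            in_vals[chrom], ip_vals[chrom] = mean_in, mean_ip
        else:
            in_vals[chrom] = rng.poisson(mean_in).astype(float)
            ip_vals[chrom] = rng.poisson(mean_ip).astype(float)
    return (CoverageTrack(genotype=genotype, values=ip_vals),
            CoverageTrack(genotype=genotype, values=in_vals))


# ----------------------------------------------------------------------
# contacts
# ----------------------------------------------------------------------
def expected_contact_matrix(
    config: SimulationConfig, genotype: str
) -> np.ndarray:
    """Noise-free expected counts: scale * |i-j|^-alpha * m(i, j).

    m multiplies in the planted domain intensity for same-domain pairs and
    one boundary-depletion factor per planted boundary crossed; the diagonal
    is zero (self pairs carry no distance signal and are excluded
    downstream).
    """
    n = config.n_bins_per_chromosome
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.abs(i - j).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, config.contact_scale * d ** -config.decay_exponent,
                         0.0)
    intensity = config.domain_intensity.get(
        genotype, config.domain_intensity.get(genotype.split("_")[0], 1.0))
    m = np.ones((n, n))
    dom_id = np.full(n, -1)
    for k, (s, e) in enumerate(config.domains()):
        dom_id[s:e] = k
    same = (dom_id[i] >= 0) & (dom_id[i] == dom_id[j])
    m[same] = intensity
    bounds = np.asarray(config.domain_boundaries(), dtype=int)
    if bounds.size and config.boundary_depletion < 1.0:
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        crossed = (np.searchsorted(bounds, hi, side="right")
                   - np.searchsorted(bounds, lo, side="right"))
        m = m * config.boundary_depletion ** crossed
    return decay * m


def simulate_contacts(
    config: SimulationConfig,
    genotype: str = "WT",
    chrom_index: int = 0,
    noiseless: bool = False,
) -> ContactMatrix:
    """Poisson-sample a symmetric contact matrix for one chromosome."""
    expected = expected_contact_matrix(config, genotype)
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(
            config.seed + _SEED_CONTACTS
            + 101 * chrom_index
            + 7 * (config.genotypes.index(genotype)
                   if genotype in config.genotypes else 0)
        )
        upper = np.triu(rng.poisson(expected).astype(float))
        counts = upper + np.triu(upper, 1).T
    chrom = config.chromosomes[min(chrom_index, config.n_chromosomes - 1)]
    return ContactMatrix(chrom=chrom, bin_size_bp=config.bin_size_bp,
                         counts=counts)


# ----------------------------------------------------------------------
# 3C
# ----------------------------------------------------------------------
def simulate_3c(
    config: SimulationConfig,
    loop_strength: float = 1.0,
    n_replicates: int | None = None,
    noiseless: bool = False,
) -> ThreeCProfile:
    """Anchor-fragment 3C profile over a model gene with an optional 5'-3' loop.

    Fragments F1..Fk tile the gene; interaction of Fi with the anchor F1
    decays as the fragment-index distance to the power -decay_exponent, and
    the terminal (3') fragment is boosted by ``loop_strength``.  A control
    fragment's raw frequency is stored for normalization.
    """
    if loop_strength <= 0:
        raise ValueError("loop_strength must be > 0")
    k = config.threec_n_fragments
    if k < 4:
        raise ValueError("at least 4 fragments are required to span the gene")
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(config.seed + _SEED_THREEC)

    dist = np.arange(1, k, dtype=float)  # F2..Fk
    mean = config.threec_base * dist ** -config.decay_exponent
    mean[-1] *= loop_strength
    if noiseless:
        reps = np.tile(mean, (n_rep, 1))
    else:
        reps = mean * 2.0 ** rng.normal(0.0, config.threec_noise_sd,
                                        size=(n_rep, mean.size))
    frag_len = 400
    frags = pd.DataFrame(dict(
        fragment_id=[f"F{i + 2}" for i in range(k - 1)],
        start=[500 + (i + 1) * frag_len for i in range(k - 1)],
        end=[500 + (i + 2) * frag_len for i in range(k - 1)],
        dist=dist.astype(int),
        raw=reps.mean(axis=0),
        raw_sd=reps.std(axis=0, ddof=1) if n_rep > 1 else 0.0,
    ))
    return ThreeCProfile(anchor_id="F1", fragments=frags,
                         control_raw=config.threec_control,
                         n_replicates=n_rep)
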