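"""Discovery of unannotated transcripts from tiling signal.

Discovery runs per strand on a summary track — by default the mean log2
signal of the discovery genotype minus the mean of its control (the
mutant-vs-control difference isolates newly appearing signal from
constitutively expressed neighbours).  Probes above a level threshold are
merged into runs (gaps up to ``max_gap_bp`` bridged), short runs dropped,
and surviving segments categorized against the public annotation as
overlapping-known, 5'/3' extensions, or intergenic.  Candidate novels are
then re-quantified per sample and tested in the discovery contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromexo import differential, expression
from chromexo.synthetic import ProbeTable

CATEGORIES = ("intergenic", "extension_5prime", "extension_3prime",
              "overlaps_known")


@dataclass(frozen=True)
class SegmentationParams:
    level_threshold: float = 0.61   # background + 3 SD of the difference track
    max_gap_bp: int = 100
    min_len_bp: int = 150
    min_seg_probes: int = 5
    link_gap_bp: int = 100
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_gap_bp", "min_len_bp", "min_seg_probes", "link_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.overlap_frac <= 1):
            raise ValueError("overlap_frac must be in (0, 1]")


def segment_signal(
    probes_norm: ProbeTable,
    samples: list[str],
    params: SegmentationParams = SegmentationParams(),
    baseline_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Call above-threshold segments on the (optionally baselined) mean track.

    Probes must be position-sorted within each (chrom, strand); the mean
    over ``samples`` (minus the mean over ``baseline_samples`` when given)
    is thresholded, marked runs separated by <= max_gap_bp are merged, and
    runs with length >= min_len_bp and >= min_seg_probes probes are emitted
    with mean_level = shorth midpoint of their member track values.
    """
    if not probes_norm.normalized:
        raise ValueError("segment_signal expects normalized probes")
    data = probes_norm.data
    for (chrom, strand, sample), grp in data.groupby(["chrom", "strand",
                                                      "sample"]):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(
                f"probes not sorted by position ({chrom}{strand}, {sample})")
    tracks = []
    for (chrom, strand), grp in data.groupby(["chrom", "strand"]):
        wide = grp.pivot_table(index="pos", columns="sample", values="value")
        track = wide[samples].mean(axis=1)
        if baseline_samples is not None:
            track = track - wide[baseline_samples].mean(axis=1)
        tracks.append((chrom, strand, wide.index.to_numpy(), track.to_numpy()))

    segs = []
    for chrom, strand, pos, track in tracks:
        marked = np.flatnonzero(track > params.level_threshold)
        if marked.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos[marked]) > params.max_gap_bp)
        run_starts = np.r_[0, breaks + 1]
        run_ends = np.r_[breaks, marked.size - 1]
        for a, b in zip(run_starts, run_ends):
            idx = marked[a:b + 1]
            start, end = int(pos[idx[0]]), int(pos[idx[-1]]) + 1
            if end - start < params.min_len_bp or idx.size < params.min_seg_probes:
                continue
            segs.append(dict(
                chrom=chrom, strand=strand, start=start, end=end,
                n_probes=int(idx.size),
                mean_level=expression.shorth_midpoint(track[idx])))
    out = pd.DataFrame(segs, columns=["chrom", "strand", "start", "end",
                                      "n_probes", "mean_level"])
    out = out.sort_values(["chrom", "strand", "start"]).reset_index(drop=True)
    out.insert(0, "segment_id", [f"seg_{i + 1:04d}" for i in range(len(out))])
    return out


def merge_segments(segments: pd.DataFrame, max_gap_bp: int) -> pd.DataFrame:
    """Merge same-strand segments separated by <= max_gap_bp (idempotent)."""
    rows = []
    for (chrom, strand), grp in segments.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("start")
        cur = None
        for r in grp.itertuples():
            if cur is not None and r.start - cur["end"] <= max_gap_bp:
                cur["end"] = max(cur["end"], r.end)
                cur["n_probes"] += r.n_probes
            else:
                if cur is not None:
                    rows.append(cur)
                cur = dict(chrom=chrom, strand=strand, start=r.start,
                           end=r.end, n_probes=r.n_probes,
                           mean_level=r.mean_level)
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end",
                                      "n_probes", "mean_level"])
    out = out.sort_values(["chrom", "strand", "start"]).reset_index(drop=True)
    out.insert(0, "segment_id", [f"seg_{i + 1:04d}" for i in range(len(out))])
    return out


def annotate_segments(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    params: SegmentationParams = SegmentationParams(),
) -> pd.DataFrame:
    """Categorize segments against the public annotation.

    Overlap with a same-strand known feature covering >= overlap_frac of the
    segment -> overlaps_known.  Otherwise a segment contiguous with (within
    link_gap_bp of) a same-strand feature's 3' end is a 3' extension of that
    feature, mirrored for 5'; anything else is intergenic.
    """
    out = segments.copy()
    out["category"] = "intergenic"
    out["parent_id"] = ""
    by_key = {k: g for k, g in annotation.groupby(["chrom", "strand"])}
    for i, seg in out.iterrows():
        feats = by_key.get((seg["chrom"], seg["strand"]))
        if feats is None:
            continue
        s, e = seg["start"], seg["end"]
        ov = np.minimum(feats["end"], e) - np.maximum(feats["start"], s)
        frac = ov.clip(lower=0) / (e - s)
        if (frac >= params.overlap_frac).any():
            out.at[i, "category"] = "overlaps_known"
            out.at[i, "parent_id"] = feats.loc[frac.idxmax(), "feature_id"]
            continue
        # 3' end of a + feature is its end; of a - feature its start
        if seg["strand"] == "+":
            gap3 = s - feats["end"]     # segment downstream of feature
            gap5 = feats["start"] - e   # segment upstream of feature
        else:
            gap3 = feats["start"] - e
            gap5 = s - feats["end"]
        for gaps, cat in ((gap3, "extension_3prime"), (gap5, "extension_5prime")):
            cand = gaps[(gaps >= -(e - s) // 2) & (gaps <= params.link_gap_bp)]
            if len(cand):
                out.at[i, "category"] = cat
                out.at[i, "parent_id"] = feats.loc[cand.idxmin(), "feature_id"]
                break
    return out


def differential_segments(
    segments: pd.DataFrame,
    probes_norm: ProbeTable,
    sample_genotypes: dict[str, str],
    background_threshold: float,
    discovery: str = "swr1_rrp6",
    control: str = "rrp6",
    absent_in: tuple[str, ...] = ("WT", "swr1"),
    fdr: float = 0.1,
    lfc_threshold: float = 0.59,
    min_probes: int = 5,
) -> pd.DataFrame:
    """Test candidate segments for discovery-specific expression.

    Each segment is quantified per sample (shorth midpoint), tested
    discovery-vs-control with the moderated t, and reported if
    padj < fdr, LFC > lfc_threshold, and its mean level stays below the
    background threshold in every genotype listed in ``absent_in``.
    """
    genotypes = set(sample_genotypes.values())
    for g in (discovery, control, *absent_in):
        if g not in genotypes:
            raise KeyError(f"missing genotype: {g}")
    feats = segments.rename(columns={"segment_id": "feature_id"})[
        ["feature_id", "chrom", "start", "end", "strand"]].copy()
    expr = expression.quantify(probes_norm, feats, min_probes=min_probes)
    by_geno = {g: [s for s, gg in sample_genotypes.items() if gg == g]
               for g in genotypes}
    diff = differential.fit_contrast(expr, by_geno[control], by_geno[discovery])
    tab = diff.table

    out = segments.set_index("segment_id").join(
        tab[["lfc", "padj"]], how="left")
    for g in absent_in:
        out[f"mean_{g}"] = expr.values[by_geno[g]].mean(axis=1)
    absent_ok = np.ones(len(out), dtype=bool)
    for g in absent_in:
        absent_ok &= (out[f"mean_{g}"] < background_threshold).to_numpy()
    out["passed"] = ((out["padj"] < fdr) & (out["lfc"] > lfc_threshold)
                     & absent_ok)
    return out.reset_index()


def category_counts(report: pd.DataFrame) -> pd.Series:
    """Counts of passing novel segments by category."""
    passed = report[report["passed"] & (report["category"] != "overlaps_known")]
    return passed["category"].value_counts()
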