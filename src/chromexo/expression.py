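"""Tiling-signal quantification.

Probe intensities are normalized against a genomic-DNA reference
(log2 ratio, then per-sample median centering), transcripts are quantified
by the midpoint of the shorth of their same-strand probe values, and a
background filter masks transcripts that never rise above the noise floor
in any genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromexo.synthetic import ProbeTable


# ----------------------------------------------------------------------
# shorth
# ----------------------------------------------------------------------
def shorth_midpoint(values) -> float:
    """Midpoint of the shorth: the shortest interval covering half the values.

    With the values sorted and ``h = floor(n/2) + 1`` (a strict majority),
    the width-minimal window of ``h`` consecutive order statistics is found
    and its midpoint ``(min + max) / 2`` returned.  Width ties are broken by
    the smallest left endpoint, which makes the estimator deterministic.

    Robust to outliers: up to ``floor((n-1)/2)`` arbitrarily wild values
    cannot drag the estimate outside the clean data's shorth window.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("shorth_midpoint requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("shorth_midpoint requires finite values (NaN/inf found)")
    x = np.sort(x)
    n = x.size
    h = n // 2 + 1
    if h > n:  # n == 1
        return float(x[0])
    widths = x[h - 1:] - x[: n - h + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float((x[i] + x[i + h - 1]) / 2.0)


def shorth_midpoint_columns(matrix: np.ndarray) -> np.ndarray:
    """Column-wise shorth midpoints of a 2-D array (rows = observations)."""
    x = np.sort(np.asarray(matrix, dtype=float), axis=0)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty matrix")
    h = n // 2 + 1
    widths = x[h - 1:, :] - x[: n - h + 1, :]
    i = np.argmin(widths, axis=0)
    cols = np.arange(x.shape[1])
    return (x[i, cols] + x[i + h - 1, cols]) / 2.0


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------
def normalize_probes(probes: ProbeTable, median_center: bool = True) -> ProbeTable:
    """log2(intensity / genomic-DNA reference), then per-sample median centering.

    Every probe must have a strictly positive reference value; probes with a
    missing or non-positive reference raise an error naming the offending
    positions.  Median centering (each sample's genome-wide median log2
    ratio becomes 0) removes array-to-array scale; it can be switched off.
    """
    if probes.normalized:
        raise ValueError("probe table is already normalized")
    ref = probes.reference
    bad = ref[~(ref["ref"] > 0)]
    merged = probes.data.merge(ref, on=["chrom", "pos"], how="left")
    missing = merged[merged["ref"].isna() | ~(merged["ref"] > 0)]
    if len(missing) or len(bad):
        culprits = pd.concat([missing[["chrom", "pos"]], bad[["chrom", "pos"]]])
        locs = culprits.drop_duplicates().head(5).itertuples(index=False)
        desc = ", ".join(f"({c}, {p})" for c, p in locs)
        raise ValueError(
            f"missing or non-positive genomic-DNA reference at probe position(s) {desc}"
        )
    out = merged[["chrom", "pos", "strand", "sample"]].copy()
    out["value"] = np.log2(merged["intensity"] / merged["ref"])
    if median_center:
        out["value"] -= out.groupby("sample")["value"].transform("median")
    return ProbeTable(data=out, reference=probes.reference, normalized=True)


# ----------------------------------------------------------------------
# quantification
# ----------------------------------------------------------------------
@dataclass
class ExpressionMatrix:
    """Transcripts x samples log2 expression with a background mask."""

    values: pd.DataFrame            # index: feature_id, columns: samples
    flags: pd.Series                # per-feature QC flag ("" if clean)
    threshold: float = float("-inf")
    retained: pd.Series | None = None          # set by background_filter
    below_background: pd.DataFrame | None = None

    def retained_values(self) -> pd.DataFrame:
        if self.retained is None:
            return self.values
        return self.values.loc[self.retained[self.retained].index]


def quantify(
    probes_norm: ProbeTable,
    features: pd.DataFrame,
    min_probes: int = 5,
) -> ExpressionMatrix:
    """Per-feature, per-sample shorth-midpoint of in-feature probe values.

    Only probes on the feature's own strand with pos in [start, end) are
    used.  Features with fewer than ``min_probes`` probes (or none at all)
    are quantified anyway where possible but flagged, never silently
    dropped.
    """
    if not probes_norm.normalized:
        raise ValueError("quantify expects normalized probes")
    data = probes_norm.data
    samples = sorted(data["sample"].unique())
    # wide layout per (chrom, strand): positions x samples
    wide: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), grp in data.groupby(["chrom", "strand"]):
        p = grp.pivot_table(index="pos", columns="sample", values="value")
        p = p.reindex(columns=samples).sort_index()
        wide[(chrom, strand)] = (p.index.to_numpy(), p.to_numpy())

    values = np.full((len(features), len(samples)), np.nan)
    flags = [""] * len(features)
    for k, row in enumerate(features.itertuples()):
        key = (row.chrom, row.strand)
        if key not in wide:
            flags[k] = "no_probes"
            continue
        pos, mat = wide[key]
        a, b = np.searchsorted(pos, [row.start, row.end])
        n = b - a
        if n == 0:
            flags[k] = "no_probes"
            continue
        if n < min_probes:
            flags[k] = "few_probes"
        values[k] = shorth_midpoint_columns(mat[a:b])
    vals = pd.DataFrame(values, index=pd.Index(features["feature_id"],
                                               name="feature_id"),
                        columns=samples)
    return ExpressionMatrix(values=vals,
                            flags=pd.Series(flags, index=vals.index))


# ----------------------------------------------------------------------
# background filtering
# ----------------------------------------------------------------------
def estimate_background_threshold(
    probes_norm: ProbeTable, features: pd.DataFrame, n_sd: float = 2.0
) -> float:
    """Background mean + n_sd * SD, estimated from unannotated probe positions."""
    if not probes_norm.normalized:
        raise ValueError("expects normalized probes")
    data = probes_norm.data
    mask = np.zeros(len(data), dtype=bool)
    pos = data["pos"].to_numpy()
    for (chrom, strand), grp in features.groupby(["chrom", "strand"]):
        sel = (data["chrom"] == chrom) & (data["strand"] == strand)
        sel = sel.to_numpy()
        inside = np.zeros(sel.sum(), dtype=bool)
        p = pos[sel]
        for row in grp.itertuples():
            inside |= (p >= row.start) & (p < row.end)
        mask[np.flatnonzero(sel)[inside]] = True
    bg = data.loc[~mask, "value"].to_numpy()
    if bg.size == 0:
        raise ValueError("no unannotated probes to estimate background from")
    return float(bg.mean() + n_sd * bg.std(ddof=1))


def background_filter(
    expr: ExpressionMatrix,
    threshold: float,
    sample_genotypes: dict[str, str],
) -> ExpressionMatrix:
    """Retain transcripts whose mean value in >= 1 genotype exceeds threshold.

    Everything else is masked for all downstream statistics.  The per-cell
    below-background mask is recorded as well; retained/total counts are
    available from the returned object.
    """
    if not np.isfinite(threshold) and threshold != float("-inf"):
        raise ValueError("threshold must be finite or -inf")
    geno = pd.Series(sample_genotypes).reindex(expr.values.columns)
    geno_means = expr.values.T.groupby(geno).mean().T
    retained = (geno_means > threshold).any(axis=1)
    return ExpressionMatrix(
        values=expr.values,
        flags=expr.flags,
        threshold=threshold,
        retained=retained,
        below_background=expr.values <= threshold,
    )
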