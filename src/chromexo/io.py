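"""Readers and writers for the pipeline's interchange formats.

Everything is plain text: GFF3 / BED6 for annotation, TSV for probe tables
and matrices, bedGraph for coverage, and a sparse triplet TSV (``i  j
count`` with a header line carrying chrom / bin size / bin count) for
contact matrices.  Floats are written with a fixed format so identical runs
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from chromexo.synthetic import (
    ContactMatrix,
    CoverageTrack,
    ProbeTable,
    ThreeCProfile,
)

FLOAT_FMT = "%.6g"


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------
def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in features.itertuples():
            attrs = f"ID={r.feature_id};biotype={r.biotype}"
            fh.write(f"{r.chrom}\tchromexo\ttranscript\t{r.start + 1}\t{r.end}"
                     f"\t.\t{r.strand}\t.\t{attrs}\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, _, start, end, _, strand, _, attrs = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            rows.append(dict(feature_id=fields.get("ID", ""), chrom=chrom,
                             start=int(start) - 1, end=int(end), strand=strand,
                             biotype=fields.get("biotype", "")))
    return pd.DataFrame(rows)


def write_bed6(features: pd.DataFrame, path: str | Path,
               extra_columns: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for r in features.itertuples():
            row = [r.chrom, str(r.start), str(r.end), r.feature_id, "0", r.strand]
            for c in extra_columns or []:
                row.append(str(getattr(r, c)))
            fh.write("\t".join(row) + "\n")


# ----------------------------------------------------------------------
# probes
# ----------------------------------------------------------------------
def write_probes(probes: ProbeTable, path: str | Path,
                 reference_path: str | Path | None = None) -> None:
    probes.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if reference_path is not None:
        with open(reference_path, "w") as fh:  # reference as bedGraph
            for r in probes.reference.itertuples():
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.ref:.6g}\n")


def read_probes(path: str | Path,
                reference_path: str | Path | None = None) -> ProbeTable:
    data = pd.read_csv(path, sep="\t")
    normalized = "value" in data.columns
    if reference_path is not None:
        ref = pd.read_csv(reference_path, sep="\t",
                          names=["chrom", "start", "end", "ref"])
        ref = ref.rename(columns={"start": "pos"})[["chrom", "pos", "ref"]]
    else:
        ref = pd.DataFrame(columns=["chrom", "pos", "ref"])
    return ProbeTable(data=data, reference=ref, normalized=normalized)


# ----------------------------------------------------------------------
# coverage
# ----------------------------------------------------------------------
def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded bedGraph of a per-bp track."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            breaks = np.flatnonzero(np.diff(v) != 0)
            starts = np.r_[0, breaks + 1]
            ends = np.r_[breaks + 1, v.size]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def read_bedgraph(path: str | Path, genotype: str = "") -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"])
    values = {}
    for chrom, grp in df.groupby("chrom"):
        arr = np.zeros(int(grp["end"].max()))
        for r in grp.itertuples():
            arr[r.start:r.end] = r.value
        values[chrom] = arr
    return CoverageTrack(genotype=genotype, values=values)


# ----------------------------------------------------------------------
# contact matrices
# ----------------------------------------------------------------------
def write_contacts(m: ContactMatrix, path: str | Path) -> None:
    """Sparse upper-triangle triplets ``i  j  count`` (i <= j)."""
    iu, ju = np.triu_indices(m.n_bins)
    c = m.counts[iu, ju]
    keep = c != 0
    with open(path, "w") as fh:
        fh.write(f"#chrom={m.chrom}\tbin_size_bp={m.bin_size_bp}"
                 f"\tn_bins={m.n_bins}\n")
        for i, j, v in zip(iu[keep], ju[keep], c[keep]):
            fh.write(f"{i}\t{j}\t{v:.6g}\n")


def read_contacts(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n")
        meta = dict(kv.split("=", 1) for kv in header.split("\t"))
        n = int(meta["n_bins"])
        counts = np.zeros((n, n))
        for line in fh:
            i, j, v = line.split("\t")
            i, j, v = int(i), int(j), float(v)
            counts[i, j] = v
            counts[j, i] = v
    return ContactMatrix(chrom=meta["chrom"],
                         bin_size_bp=int(meta["bin_size_bp"]), counts=counts)


# ----------------------------------------------------------------------
# 3C
# ----------------------------------------------------------------------
def write_3c(profile: ThreeCProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#anchor={profile.anchor_id}\tcontrol_raw="
                 f"{profile.control_raw:.6g}\tn_replicates={profile.n_replicates}\n")
        profile.fragments.to_csv(fh, sep="\t", index=False,
                                 float_format=FLOAT_FMT)


def read_3c(path: str | Path) -> ThreeCProfile:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n")
        meta = dict(kv.split("=", 1) for kv in header.split("\t"))
        frags = pd.read_csv(fh, sep="\t")
    return ThreeCProfile(anchor_id=meta["anchor"], fragments=frags,
                         control_raw=float(meta["control_raw"]),
                         n_replicates=int(meta["n_replicates"]))


# ----------------------------------------------------------------------
# generic tables
# ----------------------------------------------------------------------
def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
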