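"""Feature-level RNAPII occupancy from IP and input coverage.

Per feature, the mean per-bp depth of each track over [start, end) is
library-size scaled (divided by the track's total signal) and the
occupancy ratio is scaled IP / scaled input — so multiplying either full
track by a constant leaves every ratio unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chromexo.synthetic import CoverageTrack


def feature_occupancy(
    ip: CoverageTrack,
    inp: CoverageTrack,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Per-feature library-scaled IP/input ratio.

    Features with zero input signal get ratio = NaN and flag "undefined";
    features outside the track extent raise.
    """
    ip_total, in_total = ip.total(), inp.total()
    if ip_total <= 0 or in_total <= 0:
        raise ValueError("library sizes must be > 0")
    rows = []
    for row in features.itertuples():
        for track in (ip, inp):
            arr = track.values.get(row.chrom)
            if arr is None or row.end > arr.size or row.start < 0:
                raise ValueError(
                    f"feature {row.feature_id} outside coverage extent "
                    f"({row.chrom}:{row.start}-{row.end})")
        ip_mean = ip.values[row.chrom][row.start:row.end].mean() / ip_total
        in_mean = inp.values[row.chrom][row.start:row.end].mean() / in_total
        if in_mean > 0:
            ratio, flag = ip_mean / in_mean, ""
        else:
            ratio, flag = np.nan, "undefined"
        rows.append(dict(feature_id=row.feature_id, biotype=getattr(
            row, "biotype", ""), ip_mean=ip_mean, input_mean=in_mean,
            ratio=ratio, log2_ratio=np.log2(ratio) if ratio and ratio > 0
            else np.nan, flag=flag))
    return pd.DataFrame(rows).set_index("feature_id")


def count_changed(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    fold: float = 1.3,
) -> dict:
    """Count features whose occupancy changes more than ``fold`` between
    genotypes (strict inequality; flagged/undefined features excluded).

    decreased: wt.ratio / mut.ratio > fold; increased symmetric.  Counts
    are reported per biotype and direction, along with the per-feature
    table.
    """
    if not wt.index.equals(mut.index):
        raise ValueError("feature sets of the two occupancy tables differ")
    ok = (wt["flag"] == "") & (mut["flag"] == "")
    rel = wt.loc[ok, "ratio"] / mut.loc[ok, "ratio"]
    table = pd.DataFrame(dict(biotype=wt.loc[ok, "biotype"],
                              wt_ratio=wt.loc[ok, "ratio"],
                              mut_ratio=mut.loc[ok, "ratio"],
                              wt_over_mut=rel))
    table["direction"] = "unchanged"
    table.loc[rel > fold, "direction"] = "decreased"
    table.loc[1.0 / rel > fold, "direction"] = "increased"
    counts = (table[table["direction"] != "unchanged"]
              .groupby(["biotype", "direction"]).size())
    return dict(counts=counts, table=table,
                decreased_ids=table.index[table["direction"] == "decreased"],
                increased_ids=table.index[table["direction"] == "increased"])
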