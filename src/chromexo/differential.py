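"""Empirical-Bayes moderated differential expression and group classification.

For each transcript g in a two-group contrast, LFC is the difference of
group means and s_g^2 the pooled residual variance on d_g = n1 + n2 - 2 df.
Variances are shrunk toward a common prior: assuming the true residual
variances follow a scaled inverse chi-square with prior df d0 and location
s0^2, the marginal distribution of log s_g^2 has mean and variance given by
digamma/trigamma expressions, and (d0, s0^2) are estimated by matching the
empirical moments of log s_g^2 (the classical closed-form estimator family
used by moderated-t packages).  The posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t = LFC / (s~_g * sqrt(1/n1 + 1/n2)) is referred to a t
distribution on d0 + d_g df.  d0 = 0 recovers the ordinary pooled t;
d0 = inf collapses every posterior variance to s0^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from chromexo.expression import ExpressionMatrix, shorth_midpoint
from chromexo.synthetic import ProbeTable

D0_CAP = 500.0  # prior df above this are treated as effectively infinite

NCRNA_BIOTYPES = frozenset({"CUT", "SUT", "SRT", "NOVEL"})


# ----------------------------------------------------------------------
# BH step-up
# ----------------------------------------------------------------------
def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ----------------------------------------------------------------------
# prior estimation (moment matching on log s^2)
# ----------------------------------------------------------------------
def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of the prior df d0 and prior variance s0^2.

    Let z_g = log s_g^2 and e_g = z_g - digamma(d_g/2) + log(d_g/2); then
    E[e_g] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var[e_g] = trigamma(d_g/2) + trigamma(d0/2).  Solving the second for d0
    via the trigamma inverse and substituting into the first gives closed
    forms.  d0 is capped at ``D0_CAP`` (returned as inf when the empirical
    variance of e is at or below its sampling floor).
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    if d0 > D0_CAP:
        return float("inf"), float(np.exp(emean))
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s02


# ----------------------------------------------------------------------
# contrast fitting
# ----------------------------------------------------------------------
@dataclass
class DiffResult:
    """Per-transcript moderated-t results for one two-group contrast."""

    table: pd.DataFrame  # lfc, s2, df, s2_post, t, p, padj, flag
    d0: float
    s02: float
    n1: int
    n2: int


def fit_contrast(
    expr: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    d0: float | None = None,
    s02: float | None = None,
) -> DiffResult:
    """Moderated two-group contrast: LFC = mean(group2) - mean(group1).

    Transcripts with fewer than 2 usable replicates on either side are
    flagged and excluded from prior estimation and from p-values.  Pass
    ``d0`` / ``s02`` to force the prior (0 -> ordinary pooled t; inf -> full
    shrinkage to s02, p from the normal limit).
    """
    vals = expr.retained_values()
    missing = [s for s in list(group1) + list(group2) if s not in vals.columns]
    if missing:
        raise KeyError(f"samples not in expression matrix: {missing}")
    x1 = vals[list(group1)].to_numpy()
    x2 = vals[list(group2)].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    usable = (np.sum(np.isfinite(x1), axis=1) >= 2) & \
             (np.sum(np.isfinite(x2), axis=1) >= 2)

    m1, m2 = np.nanmean(x1, axis=1), np.nanmean(x2, axis=1)
    lfc = m2 - m1
    ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
    ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    dfree = np.full(len(vals), float(n1 + n2 - 2))
    s2 = np.where(dfree > 0, (ss1 + ss2) / np.maximum(dfree, 1), np.nan)

    if d0 is None or s02 is None:
        d0_est, s02_est = estimate_prior(s2[usable], dfree[usable])
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        t = lfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_post = (d0 * s02 + dfree * s2) / (d0 + dfree)
        t = lfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), d0 + dfree)

    p = np.where(usable, p, np.nan)
    padj = np.full_like(p, np.nan)
    padj[usable] = bh_adjust(p[usable])
    table = pd.DataFrame(
        dict(lfc=lfc, s2=s2, df=dfree, s2_post=s2_post, t=t, p=p, padj=padj,
             flag=np.where(usable, "", "too_few_replicates")),
        index=vals.index,
    )
    return DiffResult(table=table, d0=float(d0), s02=float(s02), n1=n1, n2=n2)


# ----------------------------------------------------------------------
# group classification
# ----------------------------------------------------------------------
REQUIRED_CONTRASTS = ("rrp6_vs_WT", "rtt109_rrp6_vs_rrp6", "swr1_rrp6_vs_rrp6")


def classify_groups(
    diff: dict[str, DiffResult],
    biotypes: pd.Series,
    fdr: float = 0.1,
    lfc_threshold: float = 0.59,
) -> pd.DataFrame:
    """Assign each transcript to one differential group.

    Groups (strict inequalities at both thresholds):

    * A: ORFs significantly up in rrp6 vs WT (padj < fdr and LFC > thr) and
      reduced (LFC < -thr) in rtt109_rrp6 vs rrp6.
    * B: ORFs significantly down in rrp6 vs WT and increased (LFC > thr) in
      rtt109_rrp6 vs rrp6.
    * C: as A but for CUTs.
    * D: group-C criteria plus reduction (LFC < -thr) in swr1_rrp6 vs rrp6.
    * up_ncRNA: ncRNAs significantly up (padj < fdr, LFC > thr) in
      swr1_rrp6 vs rrp6.
    * unchanged_ncRNA: SRTs failing the up_ncRNA test.

    Precedence gives exactly one label per transcript: D before C for CUTs,
    A/B for ORFs, then up_ncRNA, then unchanged_ncRNA (SRTs), else none.
    """
    for c in REQUIRED_CONTRASTS:
        if c not in diff:
            raise KeyError(f"missing required contrast: {c}")
    rr = diff["rrp6_vs_WT"].table
    rt = diff["rtt109_rrp6_vs_rrp6"].table
    sw = diff["swr1_rrp6_vs_rrp6"].table
    ids = rr.index
    bio = biotypes.reindex(ids)

    def col(tbl, name):
        return tbl[name].reindex(ids).to_numpy()

    up_rr = (col(rr, "padj") < fdr) & (col(rr, "lfc") > lfc_threshold)
    dn_rr = (col(rr, "padj") < fdr) & (col(rr, "lfc") < -lfc_threshold)
    dn_rt = col(rt, "lfc") < -lfc_threshold
    up_rt = col(rt, "lfc") > lfc_threshold
    dn_sw = col(sw, "lfc") < -lfc_threshold
    up_sw = (col(sw, "padj") < fdr) & (col(sw, "lfc") > lfc_threshold)

    is_orf = (bio == "ORF").to_numpy()
    is_cut = (bio == "CUT").to_numpy()
    is_srt = (bio == "SRT").to_numpy()
    is_nc = bio.isin(NCRNA_BIOTYPES).to_numpy()

    labels = np.full(len(ids), "none", dtype=object)
    labels[is_orf & up_rr & dn_rt] = "A"
    labels[is_orf & dn_rr & up_rt] = "B"
    cut_c = is_cut & up_rr & dn_rt
    labels[cut_c] = "C"
    labels[cut_c & dn_sw] = "D"
    labels[is_nc & up_sw & (labels == "none")] = "up_ncRNA"
    labels[is_srt & (labels == "none")] = "unchanged_ncRNA"

    return pd.DataFrame(
        dict(label=labels, biotype=bio.to_numpy(),
             lfc_rrp6_vs_WT=col(rr, "lfc"), padj_rrp6_vs_WT=col(rr, "padj"),
             lfc_rtt109_rrp6_vs_rrp6=col(rt, "lfc"),
             lfc_swr1_rrp6_vs_rrp6=col(sw, "lfc"),
             padj_swr1_rrp6_vs_rrp6=col(sw, "padj")),
        index=ids,
    )


# ----------------------------------------------------------------------
# upstream/downstream interference correlation
# ----------------------------------------------------------------------
def interference_correlation(
    probes_norm: ProbeTable,
    orfs: pd.DataFrame,
    window_bp: int = 100,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Rank correlation of promoter-upstream vs gene-downstream signal.

    Per ORF (strand aware: for a - strand ORF the upstream window lies at
    larger coordinates), upstream = shorth midpoint of same-strand probes in
    the ``window_bp`` window before the TSS and downstream in the window
    after it.  Returns Spearman rho across ORFs with a two-sided permutation
    p-value.
    """
    data = probes_norm.data if probes_norm.normalized else None
    if data is None:
        raise ValueError("expects normalized probes")
    ups, downs, used, skipped = [], [], [], []
    grouped = {k: g for k, g in data.groupby(["chrom", "strand"])}
    for row in orfs.itertuples():
        g = grouped.get((row.chrom, row.strand))
        if g is None:
            skipped.append((row.feature_id, "no_probes"))
            continue
        pos = g["pos"].to_numpy()
        val = g["value"].to_numpy()
        if row.strand == "+":
            up_lo, up_hi = row.start - window_bp, row.start
            dn_lo, dn_hi = row.start, row.start + window_bp
        else:
            up_lo, up_hi = row.end, row.end + window_bp
            dn_lo, dn_hi = row.end - window_bp, row.end
        u = val[(pos >= up_lo) & (pos < up_hi)]
        d = val[(pos >= dn_lo) & (pos < dn_hi)]
        if u.size == 0 or d.size == 0:
            skipped.append((row.feature_id, "empty_window"))
            continue
        ups.append(shorth_midpoint(u))
        downs.append(shorth_midpoint(d))
        used.append(row.feature_id)
    ups_arr, downs_arr = np.asarray(ups), np.asarray(downs)
    if len(used) < 3:
        raise ValueError("fewer than 3 ORFs with usable windows")
    rho = stats.spearmanr(ups_arr, downs_arr).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = stats.spearmanr(ups_arr, rng.permutation(downs_arr)).statistic
        if abs(perm) >= abs(rho):
            hits += 1
    pval = (1 + hits) / (n_permutations + 1)
    return dict(rho=float(rho), p_value=float(pval), n_orfs=len(used),
                skipped=skipped,
                table=pd.DataFrame(dict(feature_id=used, upstream=ups,
                                        downstream=downs)))
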