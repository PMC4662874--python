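"""Contact-matrix analytics: decay, insulation, CIDs, compaction, 3C.

Distance-decay curves use log2 of the per-distance mean count (self and
adjacent-bin pairs excluded by default, d_min = 2, since those are
dominated by self-ligation artifacts at nucleosome resolution).  Boundaries
are local minima of an insulation-square profile; chromosome interaction
domains (CIDs) tile the intervals between consecutive boundaries; a
domain's compaction score is the log2 ratio of its observed intra-domain
contact sum to the sum expected under the matrix's own genome-wide
per-distance mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from chromexo.synthetic import ContactMatrix, ThreeCProfile

D_MIN_DEFAULT = 2
PSEUDOCOUNT_DEFAULT = 0.5


# ----------------------------------------------------------------------
# distance decay
# ----------------------------------------------------------------------
def distance_means(m: ContactMatrix, max_dist: int | None = None) -> np.ndarray:
    """Linear-scale mean count per distance d = 0..max_dist (expected model)."""
    n = m.n_bins
    if n == 0:
        raise ValueError("empty contact matrix")
    if max_dist is None:
        max_dist = n - 1
    out = np.empty(max_dist + 1)
    for d in range(max_dist + 1):
        out[d] = np.diagonal(m.counts, offset=d).mean()
    return out


def decay_curve(
    m: ContactMatrix,
    max_dist: int,
    d_min: int = D_MIN_DEFAULT,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
    aggregate: str = "log_of_mean",
) -> pd.DataFrame:
    """log2 mean interaction count of a bin with its d-th neighbour.

    ``aggregate`` switches between log2(mean + pc) (default) and
    mean(log2(c + pc)).
    """
    if max_dist >= m.n_bins:
        raise ValueError("max_dist must be < n_bins")
    rows = []
    for d in range(d_min, max_dist + 1):
        diag = np.diagonal(m.counts, offset=d)
        if aggregate == "log_of_mean":
            v = np.log2(diag.mean() + pseudocount)
        elif aggregate == "mean_of_log":
            v = np.mean(np.log2(diag + pseudocount))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        rows.append(dict(dist=d, dist_bp=d * m.bin_size_bp, log2_count=v))
    return pd.DataFrame(rows)


def fit_decay_exponent(curve: pd.DataFrame) -> float:
    """Slope of log2 count vs log2 distance (a pure power law gives -alpha)."""
    x = np.log2(curve["dist"].to_numpy(dtype=float))
    y = curve["log2_count"].to_numpy()
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


# ----------------------------------------------------------------------
# insulation and boundaries
# ----------------------------------------------------------------------
@dataclass
class InsulationProfile:
    window: int
    score: np.ndarray  # NaN outside the defined interior

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.score)


def insulation_profile(
    m: ContactMatrix,
    w: int = 4,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
) -> InsulationProfile:
    """Insulation-square score, centered to genome-wide mean 0.

    I(i) = log2(mean of c(a, b) over a in [i-w, i), b in [i, i+w)) + pc',
    defined for w <= i < n_bins - w, minus the mean over defined bins.
    The pseudocount is calibrated to the genome-mean square (pc' =
    pseudocount * mean square), so scaling all counts by a constant scales
    every term equally and the centered profile is exactly scale invariant.
    """
    n = m.n_bins
    if not (1 <= w < n / 2):
        raise ValueError(f"window w={w} out of range for {n} bins")
    sq = np.full(n, np.nan)
    for i in range(w, n - w):
        sq[i] = m.counts[i - w:i, i:i + w].mean()
    pc = pseudocount * np.nanmean(sq)
    score = np.log2(sq + pc)
    score -= np.nanmean(score)
    return InsulationProfile(window=w, score=score)


def call_boundaries(
    profile: InsulationProfile,
    min_prominence: float = 0.5,
) -> pd.DataFrame:
    """Local minima of the insulation score with prominence >= min_prominence.

    Boundary strength = mean of the flanking local maxima of the profile
    minus the minimum's score (one-sided where a flank has no maximum).
    Returns a bin-sorted table; may be empty.
    """
    s = profile.score
    ok = np.isfinite(s)
    interior = s[ok]
    offset = int(np.argmax(ok))
    minima, props = signal.find_peaks(-interior, prominence=min_prominence)
    maxima, _ = signal.find_peaks(interior)
    rows = []
    for k, mn in enumerate(minima):
        left = maxima[maxima < mn]
        right = maxima[maxima > mn]
        flank = [interior[left[-1]]] if left.size else []
        flank += [interior[right[0]]] if right.size else []
        strength = (np.mean(flank) - interior[mn]) if flank else \
            float(props["prominences"][k])
        rows.append(dict(bin=int(mn + offset), strength=float(strength),
                         score=float(interior[mn])))
    return pd.DataFrame(rows, columns=["bin", "strength", "score"]) \
        .sort_values("bin").reset_index(drop=True)


# ----------------------------------------------------------------------
# CIDs and compaction
# ----------------------------------------------------------------------
@dataclass
class CID:
    start_bin: int
    end_bin: int
    compaction: float = float("nan")
    left_strength: float = float("nan")
    right_strength: float = float("nan")
    flag: str = ""


def call_cids(
    boundaries: pd.DataFrame,
    n_bins: int,
    min_domain_bins: int = 5,
) -> list[CID]:
    """Domains between consecutive boundaries (chromosome ends close the
    first and last); domains shorter than min_domain_bins are discarded."""
    bins = sorted(boundaries["bin"].tolist()) if len(boundaries) else []
    strengths = dict(zip(boundaries["bin"], boundaries["strength"])) \
        if len(boundaries) else {}
    edges = [0] + bins + [n_bins]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < min_domain_bins:
            continue
        out.append(CID(start_bin=a, end_bin=b,
                       left_strength=strengths.get(a, float("nan")),
                       right_strength=strengths.get(b, float("nan"))))
    return out


def compaction_score(
    m: ContactMatrix,
    domain: CID,
    expected: np.ndarray,
    d_min: int = D_MIN_DEFAULT,
) -> CID:
    """CS = log2(sum of intra-domain counts / sum of expected counts),
    over pairs i < j in the domain with j - i >= d_min.

    ``expected`` is the per-distance linear-scale mean from
    :func:`distance_means` of the same matrix.  Domains with no eligible
    pair are flagged "too_short".
    """
    a, b = domain.start_bin, domain.end_bin
    obs = exp = 0.0
    npairs = 0
    for i in range(a, b):
        for j in range(max(i + d_min, i + 1), b):
            obs += m.counts[i, j]
            exp += expected[j - i]
            npairs += 1
    if npairs == 0 or exp <= 0:
        return CID(a, b, float("nan"), domain.left_strength,
                   domain.right_strength, "too_short")
    with np.errstate(divide="ignore"):
        cs = float(np.log2(obs / exp)) if obs > 0 else float("-inf")
    return CID(a, b, cs, domain.left_strength, domain.right_strength, "")


def score_domains(
    m: ContactMatrix,
    domains: list[CID],
    d_min: int = D_MIN_DEFAULT,
) -> pd.DataFrame:
    """Compaction scores for a set of domains against the matrix's own
    genome-wide expected model."""
    expected = distance_means(m)
    scored = [compaction_score(m, d, expected, d_min=d_min) for d in domains]
    return pd.DataFrame(
        dict(start_bin=[d.start_bin for d in scored],
             end_bin=[d.end_bin for d in scored],
             compaction=[d.compaction for d in scored],
             left_strength=[d.left_strength for d in scored],
             right_strength=[d.right_strength for d in scored],
             flag=[d.flag for d in scored]))


def compare_compaction(
    scores_wt,
    scores_mut,
    paired: bool = True,
) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of compaction-score
    distributions (asymptotic p), plus per-domain deltas when paired."""
    a = np.asarray(scores_wt, dtype=float)
    b = np.asarray(scores_mut, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("compaction score lists must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    out = dict(ks_D=float(res.statistic), p_value=float(res.pvalue))
    if paired and a.size == b.size:
        out["delta"] = b - a
        out["median_delta"] = float(np.median(b - a))
    return out


# ----------------------------------------------------------------------
# 3C normalization
# ----------------------------------------------------------------------
def normalize_3c(profile: ThreeCProfile) -> ThreeCProfile:
    """Divide every fragment's raw frequency (and replicate SD) by the
    control region's raw frequency, so the control reads exactly 1."""
    if profile.control_raw <= 0:
        raise ValueError("control fragment frequency must be > 0")
    frags = profile.fragments.copy()
    frags["normalized"] = frags["raw"] / profile.control_raw
    frags["normalized_sd"] = frags["raw_sd"] / profile.control_raw
    return ThreeCProfile(anchor_id=profile.anchor_id, fragments=frags,
                         control_raw=profile.control_raw,
                         n_replicates=profile.n_replicates)
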