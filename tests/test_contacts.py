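"""Contact-matrix analytics: decay, insulation, boundaries, CIDs,
compaction scores, KS comparison and 3C normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromexo import contacts as ct
from chromexo import synthetic
from chromexo.config import SimulationConfig, compaction_scenario, decay_scenario
from oracles import ks_statistic_bruteforce


def _matrix(counts, chrom="chr1", bin_size=200):
    return synthetic.ContactMatrix(chrom=chrom, bin_size_bp=bin_size,
                                   counts=np.asarray(counts, dtype=float))


def _power_law(n=80, base=2.0):
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.abs(i - j).astype(float)
    m = np.where(d > 0, base ** -d, 0.0)
    return _matrix(m)


# ----------------------------------------------------------------------
# decay
# ----------------------------------------------------------------------
def test_decay_closed_form_exponential():
    m = _power_law()
    curve = ct.decay_curve(m, max_dist=20, pseudocount=0.0)
    np.testing.assert_allclose(curve["log2_count"],
                               -curve["dist"].to_numpy(float), atol=1e-12)


def test_decay_diagonal_only_matrix_is_flat_at_pseudocount():
    m = _matrix(np.diag(np.full(50, 100.0)))
    curve = ct.decay_curve(m, max_dist=10, pseudocount=0.5)
    np.testing.assert_allclose(curve["log2_count"], np.log2(0.5))


def test_decay_max_dist_validated():
    with pytest.raises(ValueError):
        ct.decay_curve(_power_law(10), max_dist=10)


def test_decay_slope_recovers_planted_exponent_noiseless():
    for alpha in (0.8, 1.0, 1.5):
        cfg = decay_scenario(seed=1).with_(decay_exponent=alpha)
        m = synthetic.simulate_contacts(cfg, "WT", noiseless=True)
        curve = ct.decay_curve(m, max_dist=60, pseudocount=0.0)
        assert ct.fit_decay_exponent(curve) == pytest.approx(-alpha,
                                                             abs=0.1)


# ----------------------------------------------------------------------
# insulation
# ----------------------------------------------------------------------
def test_insulation_uniform_matrix_is_zero_everywhere():
    m = _matrix(np.full((40, 40), 7.0))
    prof = ct.insulation_profile(m, w=4)
    interior = prof.score[np.isfinite(prof.score)]
    np.testing.assert_allclose(interior, 0.0, atol=1e-12)


def test_insulation_two_block_matrix_dips_at_junction():
    n = 40
    counts = np.zeros((n, n))
    counts[:20, :20] = 5.0
    counts[20:, 20:] = 5.0
    prof = ct.insulation_profile(m := _matrix(counts), w=4)
    interior = np.flatnonzero(np.isfinite(prof.score))
    argmin = interior[np.argmin(prof.score[interior])]
    assert argmin == 20


def test_insulation_scale_invariant():
    rng = np.random.default_rng(2)
    upper = np.triu(rng.poisson(5, (30, 30)).astype(float))
    counts = upper + np.triu(upper, 1).T
    p1 = ct.insulation_profile(_matrix(counts), w=3)
    p2 = ct.insulation_profile(_matrix(counts * 11.0), w=3)
    np.testing.assert_allclose(p1.score, p2.score, atol=1e-9, equal_nan=True)


def test_insulation_window_validation():
    with pytest.raises(ValueError):
        ct.insulation_profile(_power_law(10), w=6)


def test_monotone_profile_has_no_boundaries():
    prof = ct.InsulationProfile(window=2,
                                score=np.linspace(-1, 1, 50))
    assert len(ct.call_boundaries(prof)) == 0


def test_planted_boundaries_recovered_exactly(sim_config):
    m = synthetic.simulate_contacts(sim_config, "WT")
    bounds = ct.call_boundaries(ct.insulation_profile(m, w=4))
    truth = np.asarray(sim_config.domain_boundaries())
    called = bounds["bin"].to_numpy()
    assert len(called) == len(truth)
    assert np.max(np.abs(called - truth)) <= 1


def test_boundary_strength_largely_intact_when_compaction_drops(sim_config):
    """Reducing intra-domain intensity (2.0 -> 1.4) moves boundary positions
    nowhere and changes mean strength by < 20%."""
    mw = synthetic.simulate_contacts(sim_config, "WT")
    mm = synthetic.simulate_contacts(sim_config, "swr1")
    bw = ct.call_boundaries(ct.insulation_profile(mw, w=4))
    bm = ct.call_boundaries(ct.insulation_profile(mm, w=4))
    assert bw["bin"].tolist() == bm["bin"].tolist()
    rel = abs(bm["strength"].mean() - bw["strength"].mean()) \
        / bw["strength"].mean()
    assert rel < 0.2


# ----------------------------------------------------------------------
# CIDs
# ----------------------------------------------------------------------
def test_cids_tile_between_boundaries():
    bounds = pd.DataFrame(dict(bin=[10, 20], strength=[1.0, 2.0],
                               score=[-1.0, -1.0]))
    doms = ct.call_cids(bounds, 30, min_domain_bins=2)
    assert [(d.start_bin, d.end_bin) for d in doms] == \
        [(0, 10), (10, 20), (20, 30)]
    assert doms[0].right_strength == 1.0 and doms[1].left_strength == 1.0


def test_empty_boundaries_give_whole_chromosome_domain():
    doms = ct.call_cids(pd.DataFrame(columns=["bin", "strength"]), 30)
    assert [(d.start_bin, d.end_bin) for d in doms] == [(0, 30)]


def test_short_domains_discarded():
    bounds = pd.DataFrame(dict(bin=[3, 20], strength=[1.0, 1.0],
                               score=[0.0, 0.0]))
    doms = ct.call_cids(bounds, 30, min_domain_bins=5)
    assert [(d.start_bin, d.end_bin) for d in doms] == [(3, 20), (20, 30)]


def test_planted_domain_lengths_recovered(sim_config):
    m = synthetic.simulate_contacts(sim_config, "WT")
    bounds = ct.call_boundaries(ct.insulation_profile(m, w=4))
    doms = ct.call_cids(bounds, m.n_bins)
    lengths = np.array([d.end_bin - d.start_bin for d in doms])
    assert np.all(np.abs(lengths - sim_config.domain_size_bins) <= 1)


# ----------------------------------------------------------------------
# compaction
# ----------------------------------------------------------------------
def test_compaction_zero_on_expectation_equal_matrix():
    m = _power_law(60)
    expected = ct.distance_means(m)
    cid = ct.compaction_score(m, ct.CID(10, 30), expected)
    assert cid.compaction == 0.0


def test_compaction_one_on_doubled_domain():
    m = _power_law(60)
    expected = ct.distance_means(m)  # from the undoubled expectation
    doubled = m.counts.copy()
    doubled[10:30, 10:30] *= 2.0
    cid = ct.compaction_score(_matrix(doubled), ct.CID(10, 30), expected)
    assert cid.compaction == 1.0


def test_compaction_too_short_domain_flagged():
    m = _power_law(20)
    cid = ct.compaction_score(m, ct.CID(5, 7), ct.distance_means(m))
    assert cid.flag == "too_short"
    assert np.isnan(cid.compaction)


def test_compaction_monotone_in_planted_intensity():
    """Noiseless: CS strictly increases with the planted multiplier."""
    scores = []
    for intensity in (0.5, 0.8, 1.0, 1.5, 2.0):
        cfg = compaction_scenario(seed=1).with_(
            domain_intensity={"WT": intensity})
        m = synthetic.simulate_contacts(cfg, "WT", noiseless=True)
        tab = ct.score_domains(m, [ct.CID(s, e) for s, e in cfg.domains()])
        scores.append(tab["compaction"].mean())
    assert all(a < b for a, b in zip(scores, scores[1:]))


def test_median_delta_cs_tracks_planted_seventyfold():
    deltas = []
    for seed in range(3):
        cfg = compaction_scenario(seed=seed)
        doms = [ct.CID(s, e) for s, e in cfg.domains()]
        sw = ct.score_domains(synthetic.simulate_contacts(cfg, "WT"),
                              doms)["compaction"]
        sm = ct.score_domains(synthetic.simulate_contacts(cfg, "swr1"),
                              doms)["compaction"]
        deltas.extend((sm - sw).tolist())
    assert np.median(deltas) == pytest.approx(np.log2(0.7), abs=0.1)


# ----------------------------------------------------------------------
# KS comparison
# ----------------------------------------------------------------------
def test_ks_identical_samples():
    x = np.arange(10.0)
    out = ct.compare_compaction(x, x)
    assert out["ks_D"] == 0.0
    assert out["p_value"] == pytest.approx(1.0)
    assert out["median_delta"] == 0.0


def test_ks_disjoint_supports():
    out = ct.compare_compaction(np.arange(10.0), np.arange(10.0) + 100)
    assert out["ks_D"] == 1.0


def test_ks_matches_ecdf_oracle():
    rng = np.random.default_rng(8)
    for _ in range(200):
        a = rng.normal(0, 1, rng.integers(3, 40))
        b = rng.normal(rng.normal(), 1, rng.integers(3, 40))
        out = ct.compare_compaction(a, b, paired=False)
        assert out["ks_D"] == ks_statistic_bruteforce(a, b)


def test_ks_detects_location_shift():
    rng = np.random.default_rng(3)
    out = ct.compare_compaction(rng.normal(0, 1, 200),
                                rng.normal(-0.5, 1, 200))
    assert out["p_value"] < 0.01


def test_ks_empty_input_rejected():
    with pytest.raises(ValueError):
        ct.compare_compaction([], [1.0])


# ----------------------------------------------------------------------
# sparse-triplet round trip / order invariance
# ----------------------------------------------------------------------
def test_contact_io_roundtrip_and_order_invariance(tmp_path, sim_config):
    from chromexo import io
    m = synthetic.simulate_contacts(sim_config, "WT")
    p = tmp_path / "c.tsv"
    io.write_contacts(m, p)
    lines = p.read_text().splitlines()
    header, body = lines[0], lines[1:]
    rng = np.random.default_rng(0)
    shuffled, swapped = list(body), []
    rng.shuffle(shuffled)
    for line in shuffled:  # also swap i/j on input
        i, j, v = line.split("\t")
        swapped.append(f"{j}\t{i}\t{v}")
    q = tmp_path / "c2.tsv"
    q.write_text("\n".join([header] + swapped) + "\n")
    m2 = io.read_contacts(q)
    np.testing.assert_allclose(m2.counts, io.read_contacts(p).counts)


# ----------------------------------------------------------------------
# 3C normalization
# ----------------------------------------------------------------------
def test_3c_control_fragment_normalizes_to_one(sim_config):
    prof = synthetic.simulate_3c(sim_config, loop_strength=4.0)
    norm = ct.normalize_3c(prof)
    assert norm.fragments["normalized"].equals(
        prof.fragments["raw"] / prof.control_raw)
    # a fragment with raw equal to the control would read exactly 1
    assert (prof.control_raw / prof.control_raw) == 1.0


def test_3c_simple_arithmetic():
    frags = pd.DataFrame(dict(fragment_id=["F2"], start=[0], end=[400],
                              dist=[1], raw=[0.06], raw_sd=[0.01]))
    prof = synthetic.ThreeCProfile(anchor_id="F1", fragments=frags,
                                   control_raw=0.02)
    norm = ct.normalize_3c(prof)
    assert norm.fragments.loc[0, "normalized"] == pytest.approx(3.0)
    assert norm.fragments.loc[0, "normalized_sd"] == pytest.approx(0.5)


def test_3c_nonpositive_control_rejected():
    frags = pd.DataFrame(dict(fragment_id=["F2"], start=[0], end=[400],
                              dist=[1], raw=[0.06], raw_sd=[0.0]))
    prof = synthetic.ThreeCProfile(anchor_id="F1", fragments=frags,
                                   control_raw=0.0)
    with pytest.raises(ValueError, match="control"):
        ct.normalize_3c(prof)


def test_3c_loop_pattern_only_in_looped_genotype(sim_config):
    looped = ct.normalize_3c(synthetic.simulate_3c(sim_config, 4.0))
    unlooped = ct.normalize_3c(synthetic.simulate_3c(sim_config, 1.0))
    lv = looped.fragments["normalized"].to_numpy()
    uv = unlooped.fragments["normalized"].to_numpy()
    # terminal fragment dominates every intervening fragment when looped
    assert lv[-1] > lv[1:-1].max()
    assert uv[-1] < uv[1:-1].max()
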