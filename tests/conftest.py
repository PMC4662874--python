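"""Shared fixtures: one fully simulated study (seed 1) reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromexo import differential, expression, synthetic
from chromexo.config import SimulationConfig


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def world(sim_config):
    """Annotation, truth, probes, normalized signal and expression matrix."""
    annotation, truth = synthetic.generate_annotation(sim_config)
    probes = synthetic.simulate_probes(annotation, truth, sim_config)
    norm = expression.normalize_probes(probes)
    expr = expression.quantify(norm, annotation)
    threshold = expression.estimate_background_threshold(norm, annotation)
    expr = expression.background_filter(expr, threshold,
                                        sim_config.sample_genotypes)
    return dict(config=sim_config, annotation=annotation, truth=truth,
                probes=probes, norm=norm, expr=expr, threshold=threshold)


@pytest.fixture(scope="session")
def samples_by_genotype(sim_config):
    by: dict[str, list[str]] = {}
    for s, g in sim_config.sample_genotypes.items():
        by.setdefault(g, []).append(s)
    return by


@pytest.fixture(scope="session")
def contrasts(world, samples_by_genotype):
    by = samples_by_genotype
    expr = world["expr"]
    return {
        "rrp6_vs_WT": differential.fit_contrast(expr, by["WT"], by["rrp6"]),
        "rtt109_rrp6_vs_rrp6": differential.fit_contrast(
            expr, by["rrp6"], by["rtt109_rrp6"]),
        "swr1_rrp6_vs_rrp6": differential.fit_contrast(
            expr, by["rrp6"], by["swr1_rrp6"]),
    }


def make_probe_table(records, reference_value=1.0):
    """Small ProbeTable from (chrom, pos, strand, sample, value) tuples,
    already on the normalized (log2) scale."""
    data = pd.DataFrame(records,
                        columns=["chrom", "pos", "strand", "sample", "value"])
    ref = data[["chrom", "pos"]].drop_duplicates()
    ref["ref"] = reference_value
    return synthetic.ProbeTable(data=data, reference=ref, normalized=True)


def box_probe_table(samples, level_by_sample, start=1000, end=1400,
                    spacing=8, chrom_len=8000, noise_sd=0.0, seed=0,
                    strand="+", chrom="chrX"):
    """Probe table with one rectangular signal box over background 0."""
    rng = np.random.default_rng(seed)
    pos = np.arange(0, chrom_len, spacing)
    frames = []
    for s in samples:
        lv = np.zeros(pos.size)
        lv[(pos >= start) & (pos < end)] = level_by_sample[s]
        noise = rng.normal(0, noise_sd, pos.size) if noise_sd else 0.0
        for st in ("+", "-") if strand == "both" else (strand,):
            frames.append(pd.DataFrame(dict(chrom=chrom, pos=pos, strand=st,
                                            sample=s, value=lv + noise)))
    data = pd.concat(frames, ignore_index=True)
    ref = pd.DataFrame(dict(chrom=chrom, pos=pos, ref=1.0))
    return synthetic.ProbeTable(data=data, reference=ref, normalized=True)
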