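"""Pipeline orchestration: validated config, staged execution, summary report.

Stages run in dependency order (simulate -> quantify -> diff -> classify ->
segment -> occupancy -> contacts -> report); every stage reads its inputs
from and writes its outputs to the run directory, so stages are idempotent
given unchanged inputs and any stage can be re-run standalone.  A resolved
copy of the configuration is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chromexo import contacts as ct
from chromexo import differential, expression, io, occupancy, segmentation
from chromexo import synthetic
from chromexo.config import SimulationConfig, compaction_scenario

log = logging.getLogger("chromexo")

STAGES = ("simulate", "quantify", "diff", "classify", "segment",
          "occupancy", "contacts", "report")

# schema: section -> field -> (type, validator or None)
_SCHEMA: dict[str, dict[str, tuple]] = {
    "simulation": {
        "genome_length_bp": (int, lambda v: v > 0),
        "n_chromosomes": (int, lambda v: v >= 1),
        "probe_spacing_bp": (int, lambda v: v >= 1),
        "n_replicates": (int, lambda v: v >= 2),
        "noise_sd": ((int, float), lambda v: v >= 0),
        "coverage_depth": ((int, float), lambda v: v > 0),
        "bin_size_bp": (int, lambda v: v >= 1),
        "decay_exponent": ((int, float), lambda v: v > 0),
        "domain_size_bins": (int, lambda v: v >= 2),
        "boundary_depletion": ((int, float), lambda v: 0 < v <= 1),
    },
    "expression": {
        "min_probes": (int, lambda v: v >= 1),
        "background_n_sd": ((int, float), lambda v: v >= 0),
        "median_center": (bool, None),
    },
    "differential": {
        "fdr": ((int, float), lambda v: 0 < v < 1),
        "lfc_threshold": ((int, float), lambda v: v >= 0),
    },
    "segmentation": {
        "level_threshold": ((int, float), None),
        "max_gap_bp": (int, lambda v: v > 0),
        "min_len_bp": (int, lambda v: v > 0),
        "min_seg_probes": (int, lambda v: v > 0),
        "link_gap_bp": (int, lambda v: v > 0),
        "overlap_frac": ((int, float), lambda v: 0 < v <= 1),
    },
    "occupancy": {
        "fold": ((int, float), lambda v: v >= 1),
    },
    "contacts": {
        "window": (int, lambda v: v >= 1),
        "min_prominence": ((int, float), lambda v: v >= 0),
        "min_domain_bins": (int, lambda v: v >= 1),
        "max_dist": (int, lambda v: v >= 2),
        "loop_strength_wt": ((int, float), lambda v: v > 0),
        "loop_strength_mut": ((int, float), lambda v: v > 0),
    },
}

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 1,
    "simulation": {},
    "expression": {"min_probes": 5, "background_n_sd": 2.0,
                   "median_center": True},
    "differential": {"fdr": 0.1, "lfc_threshold": 0.59},
    "segmentation": {"level_threshold": 0.61, "max_gap_bp": 100,
                     "min_len_bp": 150, "min_seg_probes": 5,
                     "link_gap_bp": 100, "overlap_frac": 0.5},
    "occupancy": {"fold": 1.3},
    "contacts": {"window": 4, "min_prominence": 0.5, "min_domain_bins": 5,
                 "max_dist": 60, "loop_strength_wt": 4.0,
                 "loop_strength_mut": 1.0},
}


def demo_config(seed: int = 1) -> dict:
    """The bundled demo configuration: a 60 kb single-chromosome genome
    exercising every stage in well under a minute."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["seed"] = seed
    cfg["simulation"] = {"genome_length_bp": 60_000, "n_chromosomes": 1}
    return cfg


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Validate against the schema; raises ConfigError naming the field path."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, fields in cfg.items():
        if section in ("schema_version", "seed"):
            if not isinstance(fields, int):
                raise ConfigError(f"{section}: expected integer")
            merged[section] = fields
            continue
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section: {section}")
        if not isinstance(fields, dict):
            raise ConfigError(f"{section}: expected a mapping")
        for key, value in fields.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown config field: {section}.{key}")
            typ, check = _SCHEMA[section][key]
            if isinstance(value, bool) and typ is not bool:
                raise ConfigError(f"{section}.{key}: wrong type")
            if not isinstance(value, typ):
                raise ConfigError(f"{section}.{key}: expected {typ}")
            if check is not None and not check(value):
                raise ConfigError(f"{section}.{key}: invalid value {value!r}")
            merged[section][key] = value
    # cross-checks delegated to SimulationConfig
    try:
        _sim_config(merged)
    except ValueError as err:
        raise ConfigError(f"simulation: {err}") from err
    return merged


def _sim_config(cfg: dict) -> SimulationConfig:
    allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {k: v for k, v in cfg["simulation"].items() if k in allowed}
    return SimulationConfig(seed=cfg["seed"], **kwargs)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


# ----------------------------------------------------------------------
class Pipeline:
    """Staged pipeline bound to one run directory."""

    def __init__(self, cfg: dict, outdir: str | Path):
        self.cfg = validate_config(cfg)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.sim = _sim_config(self.cfg)

    # -- helpers -------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str, producer: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing {name}: run the '{producer}' stage first")
        return p

    def _log(self, stage: str, **info) -> None:
        msg = " ".join(f"{k}={v}" for k, v in info.items())
        log.info("stage=%s %s", stage, msg)
        with open(self.path("run.log"), "a") as fh:
            fh.write(f"stage={stage} {msg}\n")

    def write_resolved_config(self) -> None:
        with open(self.path("config_resolved.yaml"), "w") as fh:
            yaml.safe_dump(self.cfg, fh, sort_keys=True)

    # -- stages --------------------------------------------------------
    def stage_simulate(self) -> None:
        sim = self.sim
        annotation, truth = synthetic.generate_annotation(sim)
        io.write_gff3(annotation, self.path("annotation.gff3"))
        io.write_bed6(annotation, self.path("annotation.bed"),
                      extra_columns=["biotype"])
        io.write_table(truth.features, self.path("truth.tsv"), index=False)
        probes = synthetic.simulate_probes(annotation, truth, sim)
        io.write_probes(probes, self.path("probes.tsv"),
                        self.path("reference.bedgraph"))
        for g in ("WT", "rtt109"):
            ip, inp = synthetic.simulate_coverage(annotation, truth, sim, g)
            io.write_bedgraph(ip, self.path(f"ip_{g}.bedgraph"))
            io.write_bedgraph(inp, self.path(f"input_{g}.bedgraph"))
        for g in ("WT", "swr1"):
            m = synthetic.simulate_contacts(sim, g)
            io.write_contacts(m, self.path(f"contacts_{g}.tsv"))
            cs_cfg = compaction_scenario(seed=sim.seed)
            io.write_contacts(synthetic.simulate_contacts(cs_cfg, g),
                              self.path(f"contacts_compaction_{g}.tsv"))
        io.write_3c(synthetic.simulate_3c(
            sim, self.cfg["contacts"]["loop_strength_wt"]),
            self.path("3c_WT.tsv"))
        io.write_3c(synthetic.simulate_3c(
            sim, self.cfg["contacts"]["loop_strength_mut"]),
            self.path("3c_swr1.tsv"))
        self._log("simulate", features=len(truth.features),
                  probes=len(probes.data))

    def stage_quantify(self) -> None:
        probes = io.read_probes(self._require("probes.tsv", "simulate"),
                                self._require("reference.bedgraph", "simulate"))
        annotation = io.read_gff3(self._require("annotation.gff3", "simulate"))
        norm = expression.normalize_probes(
            probes, median_center=self.cfg["expression"]["median_center"])
        io.write_probes(norm, self.path("probes_norm.tsv"))
        expr = expression.quantify(norm, annotation,
                                   min_probes=self.cfg["expression"]["min_probes"])
        threshold = expression.estimate_background_threshold(
            norm, annotation, n_sd=self.cfg["expression"]["background_n_sd"])
        sg = {s: s.rsplit("_", 1)[0] for s in expr.values.columns}
        expr = expression.background_filter(expr, threshold, sg)
        io.write_table(expr.values, self.path("expression.tsv"))
        io.write_table(pd.DataFrame(dict(flag=expr.flags,
                                         retained=expr.retained)),
                       self.path("expression_flags.tsv"))
        with open(self.path("background.json"), "w") as fh:
            json.dump({"threshold": threshold,
                       "retained": int(expr.retained.sum()),
                       "total": int(len(expr.retained))}, fh, sort_keys=True)
        self._log("quantify", transcripts=len(expr.values),
                  retained=int(expr.retained.sum()),
                  threshold=f"{threshold:.4f}")

    def _load_expression(self) -> expression.ExpressionMatrix:
        vals = io.read_table(self._require("expression.tsv", "quantify"))
        flags = io.read_table(self._require("expression_flags.tsv", "quantify"))
        with open(self._require("background.json", "quantify")) as fh:
            bg = json.load(fh)
        expr = expression.ExpressionMatrix(
            values=vals, flags=flags["flag"].fillna(""))
        sg = {s: s.rsplit("_", 1)[0] for s in vals.columns}
        return expression.background_filter(expr, bg["threshold"], sg)

    def stage_diff(self) -> None:
        expr = self._load_expression()
        by_geno: dict[str, list[str]] = {}
        for s in expr.values.columns:
            by_geno.setdefault(s.rsplit("_", 1)[0], []).append(s)
        contrasts = {
            "rrp6_vs_WT": ("WT", "rrp6"),
            "rtt109_rrp6_vs_rrp6": ("rrp6", "rtt109_rrp6"),
            "swr1_rrp6_vs_rrp6": ("rrp6", "swr1_rrp6"),
        }
        priors = {}
        for name, (g1, g2) in contrasts.items():
            res = differential.fit_contrast(expr, by_geno[g1], by_geno[g2])
            io.write_table(res.table, self.path(f"diff_{name}.tsv"))
            priors[name] = {"d0": res.d0, "s02": res.s02}
        with open(self.path("diff_priors.json"), "w") as fh:
            json.dump(priors, fh, sort_keys=True)
        self._log("diff", contrasts=len(contrasts))

    def stage_classify(self) -> None:
        annotation = io.read_gff3(self._require("annotation.gff3", "simulate"))
        diff = {}
        for name in differential.REQUIRED_CONTRASTS:
            tab = io.read_table(self._require(f"diff_{name}.tsv", "diff"))
            tab["flag"] = tab["flag"].fillna("")
            diff[name] = differential.DiffResult(table=tab, d0=np.nan,
                                                 s02=np.nan, n1=0, n2=0)
        biotypes = annotation.set_index("feature_id")["biotype"]
        groups = differential.classify_groups(
            diff, biotypes, fdr=self.cfg["differential"]["fdr"],
            lfc_threshold=self.cfg["differential"]["lfc_threshold"])
        io.write_table(groups, self.path("groups.tsv"))
        self._log("classify",
                  **groups["label"].value_counts().to_dict())

    def stage_segment(self) -> None:
        probes = io.read_probes(self._require("probes_norm.tsv", "quantify"))
        annotation = io.read_gff3(self._require("annotation.gff3", "simulate"))
        with open(self._require("background.json", "quantify")) as fh:
            bg = json.load(fh)
        seg_cfg = self.cfg["segmentation"]
        params = segmentation.SegmentationParams(
            level_threshold=seg_cfg["level_threshold"],
            max_gap_bp=seg_cfg["max_gap_bp"], min_len_bp=seg_cfg["min_len_bp"],
            min_seg_probes=seg_cfg["min_seg_probes"],
            link_gap_bp=seg_cfg["link_gap_bp"],
            overlap_frac=seg_cfg["overlap_frac"])
        sg = {s: s.rsplit("_", 1)[0] for s in probes.data["sample"].unique()}
        disc = [s for s, g in sg.items() if g == "swr1_rrp6"]
        ctrl = [s for s, g in sg.items() if g == "rrp6"]
        segs = segmentation.segment_signal(probes, disc, params,
                                           baseline_samples=ctrl)
        segs = segmentation.annotate_segments(segs, annotation, params)
        report = segmentation.differential_segments(
            segs, probes, sg, background_threshold=bg["threshold"],
            fdr=self.cfg["differential"]["fdr"],
            lfc_threshold=self.cfg["differential"]["lfc_threshold"],
            min_probes=self.cfg["expression"]["min_probes"])
        io.write_table(report, self.path("novel_report.tsv"), index=False)
        io.write_bed6(
            report.rename(columns={"segment_id": "feature_id"}),
            self.path("segments.bed"), extra_columns=["category", "parent_id"])
        counts = segmentation.category_counts(report)
        self._log("segment", segments=len(segs), novel=int(counts.sum()),
                  **counts.to_dict())

    def stage_occupancy(self) -> None:
        annotation = io.read_gff3(self._require("annotation.gff3", "simulate"))
        results = {}
        for g in ("WT", "rtt109"):
            ip = io.read_bedgraph(self._require(f"ip_{g}.bedgraph", "simulate"), g)
            inp = io.read_bedgraph(
                self._require(f"input_{g}.bedgraph", "simulate"), g)
            results[g] = occupancy.feature_occupancy(ip, inp, annotation)
            io.write_table(results[g], self.path(f"occupancy_{g}.tsv"))
        changed = occupancy.count_changed(results["WT"], results["rtt109"],
                                          fold=self.cfg["occupancy"]["fold"])
        io.write_table(changed["counts"].rename("n").reset_index(),
                       self.path("occupancy_counts.tsv"), index=False)
        self._log("occupancy", decreased=len(changed["decreased_ids"]),
                  increased=len(changed["increased_ids"]))

    def stage_contacts(self) -> None:
        cc = self.cfg["contacts"]
        domains_by_geno = {}
        for g in ("WT", "swr1"):
            m = io.read_contacts(self._require(f"contacts_{g}.tsv", "simulate"))
            curve = ct.decay_curve(m, max_dist=min(cc["max_dist"], m.n_bins - 1))
            io.write_table(curve, self.path(f"decay_{g}.tsv"), index=False)
            prof = ct.insulation_profile(m, w=cc["window"])
            bounds = ct.call_boundaries(prof, min_prominence=cc["min_prominence"])
            io.write_table(bounds, self.path(f"boundaries_{g}.tsv"), index=False)
            doms = ct.call_cids(bounds, m.n_bins,
                                min_domain_bins=cc["min_domain_bins"])
            domains_by_geno[g] = ct.score_domains(m, doms)
            io.write_table(domains_by_geno[g], self.path(f"domains_{g}.tsv"),
                           index=False)
        # compaction comparison on the dedicated sparse-domain experiment
        cs_cfg = compaction_scenario(seed=self.sim.seed)
        truth_doms = [ct.CID(s, e) for s, e in cs_cfg.domains()]
        cs = {}
        for g in ("WT", "swr1"):
            m = io.read_contacts(
                self._require(f"contacts_compaction_{g}.tsv", "simulate"))
            cs[g] = ct.score_domains(m, truth_doms)["compaction"].to_numpy()
        comp = ct.compare_compaction(cs["WT"], cs["swr1"])
        with open(self.path("compaction_comparison.json"), "w") as fh:
            json.dump({"ks_D": comp["ks_D"], "p_value": comp["p_value"],
                       "median_delta": comp.get("median_delta")},
                      fh, sort_keys=True)
        for g in ("WT", "swr1"):
            prof3c = io.read_3c(self._require(f"3c_{g}.tsv", "simulate"))
            io.write_3c(ct.normalize_3c(prof3c),
                        self.path(f"3c_normalized_{g}.tsv"))
        self._log("contacts",
                  wt_domains=len(domains_by_geno["WT"]),
                  ks_D=f"{comp['ks_D']:.3f}")

    def stage_report(self) -> None:
        groups = io.read_table(self._require("groups.tsv", "classify"))
        novel = pd.read_csv(self._require("novel_report.tsv", "segment"),
                            sep="\t")
        occ_counts = pd.read_csv(
            self._require("occupancy_counts.tsv", "occupancy"), sep="\t")
        bounds = pd.read_csv(self._require("boundaries_WT.tsv", "contacts"),
                             sep="\t")
        doms = pd.read_csv(self._require("domains_WT.tsv", "contacts"),
                           sep="\t")
        with open(self._require("compaction_comparison.json",
                                "contacts")) as fh:
            comp = json.load(fh)
        novel_pass = novel[novel["passed"]
                           & (novel["category"] != "overlaps_known")]
        report = {
            "groups": {k: int(v) for k, v in
                       groups["label"].value_counts().sort_index().items()},
            "novel_segments": {k: int(v) for k, v in novel_pass[
                "category"].value_counts().sort_index().items()},
            "occupancy_changed": {
                f"{r.biotype}_{r.direction}": int(r.n)
                for r in occ_counts.itertuples()},
            "n_boundaries_WT": int(len(bounds)),
            "n_domains_WT": int(len(doms)),
            "compaction_ks": comp,
        }
        with open(self.path("report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        lines = ["chromexo pipeline report", "========================"]
        for key, val in report.items():
            lines.append(f"{key}: {json.dumps(val, sort_keys=True)}")
        self.path("report.txt").write_text("\n".join(lines) + "\n")
        self._log("report", path="report.json")

    # -- driver --------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        wanted = list(STAGES) if stages is None else list(stages)
        unknown = [s for s in wanted if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        self.write_resolved_config()
        ordered = [s for s in STAGES if s in wanted]
        for s in ordered:
            getattr(self, f"stage_{s}")()
        report_path = self.path("report.json")
        if report_path.exists():
            with open(report_path) as fh:
                return json.load(fh)
        return {}


def run(cfg: dict, outdir: str | Path, stages: list[str] | None = None) -> dict:
    """Validate the config, execute the requested stages, return the report."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    return Pipeline(cfg, outdir).run(stages)
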