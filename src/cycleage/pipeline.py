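"""Umbrella pipeline: simulate -> detect -> annotate -> score -> cohort.

All randomness flows from one top-level seed through named substreams
(one per stage), so a run directory is exactly reproducible from its
manifest alone.  Outputs are plain text and carry no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cell_annot, cohort as cohort_mod, cyclic_detect, io as cio, signature, synthgen
from .exceptions import ConfigError

__all__ = ["PipelineConfig", "run_pipeline", "rerun_manifest", "load_config"]

# fixed substream indices per stage
_STREAMS = {"timecourse": 0, "proteome": 1, "cells": 2, "cohort": 3, "dip": 4}


def _substream_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclasses.dataclass
class PipelineConfig:
    """Validated stage parameters for a full demo run."""

    seed: int = 0
    timecourse: synthgen.TimecourseConfig = dataclasses.field(
        default_factory=synthgen.TimecourseConfig
    )
    proteome: synthgen.ProteomeConfig = dataclasses.field(
        default_factory=lambda: synthgen.ProteomeConfig(missing_rate=0.1)
    )
    cells: synthgen.SingleCellConfig = dataclasses.field(
        default_factory=lambda: synthgen.SingleCellConfig(n_cells_per_sample=400)
    )
    cohort: synthgen.CohortConfig = dataclasses.field(default_factory=synthgen.CohortConfig)
    tau: float = 1.0
    q_max: float = 0.05
    orientations: tuple[str, ...] = ("UDU", "DUD")
    floor: float = 0.0
    min_detect: int | None = None
    min_score: float | None = None
    margin: float = 0.25
    alpha: float = 0.25
    n_boot: int = 499
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if not (0 < self.q_max <= 1):
            raise ConfigError("q_max must lie in (0, 1]")
        if not (0 <= self.margin <= 1):
            raise ConfigError("margin must lie in [0, 1]")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        if self.floor < 0:
            raise ConfigError("floor must be >= 0")
        bad = set(self.orientations) - {"UDU", "DUD"}
        if bad:
            raise ConfigError(f"unknown orientations {sorted(bad)}")
        self.timecourse.validate()
        self.proteome.validate()
        self.cells.validate()
        self.cohort.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _plain(d)


def _plain(obj):
    """JSON/YAML-safe deep conversion."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _build_section(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            if f.name == "composition":
                pass
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in kwargs[f.name]
            )
    if "composition" in kwargs and isinstance(kwargs["composition"], dict):
        kwargs["composition"] = {int(k): dict(v) for k, v in kwargs["composition"].items()}
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config (fails at load, not mid-run)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {
        "timecourse": synthgen.TimecourseConfig,
        "proteome": synthgen.ProteomeConfig,
        "cells": synthgen.SingleCellConfig,
        "cohort": synthgen.CohortConfig,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in sections:
            kwargs[key] = _build_section(sections[key], val or {})
        elif key == "orientations":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    cfg = _build_section_top(kwargs)
    cfg.validate()
    return cfg


def _build_section_top(kwargs: dict) -> PipelineConfig:
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(kwargs) - fields
    if unknown:
        raise ConfigError(f"pipeline config: unknown keys {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute every stage on synthetic inputs and write a run directory.

    Writes the simulated inputs, the cyclic gene/protein calls, the
    timepoint partition and dendrogram, the cell annotation and
    composition ratios, the signature scores and groups, the cohort
    statistics JSON, and a manifest sufficient to reproduce the run.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage seeds derive from the single top-level seed
    tc_cfg = dataclasses.replace(cfg.timecourse, seed=_substream_seed(cfg.seed, "timecourse"))
    pr_cfg = dataclasses.replace(cfg.proteome, seed=_substream_seed(cfg.seed, "proteome"))
    sc_cfg = dataclasses.replace(cfg.cells, seed=_substream_seed(cfg.seed, "cells"))
    co_cfg = dataclasses.replace(cfg.cohort, seed=_substream_seed(cfg.seed, "cohort"))

    # -- simulate + detect: timecourse ---------------------------------
    tc, tc_truth = synthgen.gen_timecourse(tc_cfg)
    cio.write_expression_csv(tc, out / "expression.csv")
    tc_truth.to_csv(out / "expression_truth.tsv", sep="\t")
    stats = cyclic_detect.transition_stats(tc)
    calls = cyclic_detect.call_cyclic_genes(
        stats, tau=cfg.tau, q_max=cfg.q_max, orientations=cfg.orientations
    )
    cio.write_calls_tsv(calls, out / "cyclic_genes.tsv")
    clus = cyclic_detect.cluster_timepoints(
        tc.replicate_means().rename(columns=lambda t: f"{t}m")
    )
    cio.write_partition_json(clus, out / "timepoint_partition.json")
    cio.write_newick(clus, out / "timepoint_dendrogram.nwk")

    # -- proteome ------------------------------------------------------
    pt, pt_truth = synthgen.gen_proteome(pr_cfg)
    pt.floor = cfg.floor
    if cfg.min_detect is not None:
        pt.min_detect = cfg.min_detect
    cio.write_proteome_csv(pt, out / "proteome.csv")
    pt_truth.to_csv(out / "proteome_truth.tsv", sep="\t")
    cyc_prot = cyclic_detect.call_cyclic_proteins(pt, pr_cfg.cyclic_genotype)
    (out / "cyclic_proteins.txt").write_text("\n".join(cyc_prot) + "\n")

    # -- single cell ---------------------------------------------------
    adata, panel = synthgen.gen_single_cell(sc_cfg)
    cio.write_mtx_dir(adata, out / "cells")
    ann = cell_annot.annotate_cells(
        adata, panel=panel, min_score=cfg.min_score, margin=cfg.margin
    )
    ann.insert(0, "sample", adata.obs["sample"].to_numpy())
    ann.to_csv(out / "cell_annotation.tsv", sep="\t")
    ratios = cell_annot.composition_ratios(ann, sample="sample")
    ratios.to_csv(out / "composition_ratios.tsv", sep="\t", float_format="%.10g")

    # -- signature scoring on the simulated cohort ---------------------
    co_table, expr, sig_genes = synthgen.gen_cohort(co_cfg)
    gs = signature.GeneSet(name="cyclic_signature", genes=tuple(sig_genes))
    cio.write_gmt([gs], out / "signature.gmt")
    cio.write_cohort_tsv(co_table, out / "cohort.tsv")
    expr.to_csv(out / "cohort_expression.csv", float_format="%.10g")
    scores = signature.score_samples(expr, gs, alpha=cfg.alpha)
    groups = signature.tertile_stratify(scores)
    score_table = scores.to_frame()
    score_table["group"] = groups
    score_table.to_csv(out / "signature_scores.tsv", sep="\t", float_format="%.10g")

    # -- cohort statistics ---------------------------------------------
    merged = co_table.copy()
    merged["score_group"] = groups.reindex(merged.index)
    hi = merged[merged["score_group"] == "high"]
    lo = merged[merged["score_group"] == "low"]
    dip_seed = _substream_seed(cfg.seed, "dip")
    dip_hi = cohort_mod.dip_test(hi["age_years"], n_boot=cfg.n_boot, seed=dip_seed)
    dip_lo = cohort_mod.dip_test(lo["age_years"], n_boot=cfg.n_boot, seed=dip_seed + 1)
    lr = cohort_mod.logrank_test(
        hi["os_time"], hi["os_event"], lo["os_time"], lo["os_event"]
    )
    km_hi = cohort_mod.km_estimate(hi["os_time"], hi["os_event"])
    km_lo = cohort_mod.km_estimate(lo["os_time"], lo["os_event"])
    young = merged["age_years"] <= 43
    table = [
        [int((young & (merged["score_group"] == "high")).sum()),
         int((~young & (merged["score_group"] == "high")).sum())],
        [int((young & (merged["score_group"] == "low")).sum()),
         int((~young & (merged["score_group"] == "low")).sum())],
    ]
    fisher_p = cohort_mod.fisher_exact(np.array(table))

    results = {
        "n_cyclic_genes_called": int(len(calls)),
        "n_cyclic_proteins_called": len(cyc_prot),
        "timepoint_partition": [sorted(clus.partition[0]), sorted(clus.partition[1])],
        "dip": {
            "high": {"dip": dip_hi.dip, "p": dip_hi.p, "n": int(len(hi))},
            "low": {"dip": dip_lo.dip, "p": dip_lo.p, "n": int(len(lo))},
            "n_boot": cfg.n_boot,
        },
        "logrank": {"chi_square": lr.chi_square, "p": lr.p},
        "km_curves": {
            "high": {"times": km_hi.times.tolist(), "survival": km_hi.survival.tolist()},
            "low": {"times": km_lo.times.tolist(), "survival": km_lo.survival.tolist()},
        },
        "fisher_tables": {"age_le_43_vs_group": {"table": table, "p": fisher_p}},
    }
    with open(out / "cohort_results.json", "w") as fh:
        json.dump(_plain(results), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "package": "cycleage",
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {k: _substream_seed(cfg.seed, k) for k in _STREAMS},
        "config": cfg.to_dict(),
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def rerun_manifest(manifest_path, out_dir) -> Path:
    """Re-execute a run from its manifest alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    raw = manifest["config"]
    sections = {
        "timecourse": synthgen.TimecourseConfig,
        "proteome": synthgen.ProteomeConfig,
        "cells": synthgen.SingleCellConfig,
        "cohort": synthgen.CohortConfig,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in sections:
            kwargs[key] = _build_section(sections[key], val)
        elif key == "orientations":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    cfg = _build_section_top(kwargs)
    return run_pipeline(cfg, out_dir)
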