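"""End-to-end orchestration: simulate/ingest -> callpeaks -> kofilter ->
replicate overlap -> classify -> colocalize -> express -> report.

A single TOML config drives every stage; every stated analysis parameter
(window 50, gap 50, FDR 1e-3 with a 1e-10 strict preset, 2.5-fold cutoffs,
top 3000) defaults to its standard value and is echoed in the report so
deviations are auditable. Reruns with the same config and inputs are
byte-identical; per-stage wall times go to the log, not the report body.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .coloc import top_n_by_score, venn_counts
from .elements import (
    ClassificationRules,
    classify_regions,
    define_adipogenic_enhancers,
    genomic_distribution,
)
from .expression import (
    ExpressionTable,
    classify_dependency,
    classify_regulation,
    regulation_summary,
)
from .genomic import IntervalSet, fraction_percent
from .io import read_bed, read_chrom_sizes, read_tss_table, write_bed
from .islands import (
    IslandParams,
    call_islands,
    differential_ko_filter,
    islands_to_frame,
    islands_to_interval_set,
    read_tag_bed,
    replicate_high_confidence,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset, truth_compare

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

# the stricter differential FDR used for the Mll3/Mll4-knockout contrast
FDR_PRESETS = {"default": 1e-3, "mll34_ko": 1e-10}


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, with standard defaults."""

    schema_version: int = SCHEMA_VERSION
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    island: IslandParams = field(default_factory=IslandParams)
    fdr: float = FDR_PRESETS["default"]
    fdr_preset: str = "default"
    replicate_mode: str = "union"
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    regulation_cutoff: float = 2.5
    dependency_cutoff: float = 2.5
    dependency_mode: str = "ratio"
    expression_floor: float = 0.0
    top_n: int = 3000
    flank_bp: int = 2000
    bins: int = 100

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        cfg.schema_version = raw.get("schema_version", SCHEMA_VERSION)
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            for key in ("chrom_lengths", "island_width_bp"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimulationConfig(**sim)
        cfg.inputs = dict(raw.get("inputs", {}))
        if "island" in raw:
            cfg.island = IslandParams(**raw["island"])
        kof = raw.get("kofilter", {})
        cfg.fdr_preset = kof.get("preset", "default")
        cfg.fdr = kof.get("fdr", FDR_PRESETS.get(cfg.fdr_preset, FDR_PRESETS["default"]))
        cfg.replicate_mode = kof.get("replicate_mode", "union")
        if "classify" in raw:
            rules = dict(raw["classify"])
            for key in ("enhancer_marks", "priority"):
                if key in rules:
                    rules[key] = tuple(rules[key])
            cfg.rules = ClassificationRules(**rules)
        exp = raw.get("express", {})
        cfg.regulation_cutoff = exp.get("cutoff", 2.5)
        cfg.dependency_cutoff = exp.get("dependency_cutoff", 2.5)
        cfg.dependency_mode = exp.get("mode", "ratio")
        cfg.expression_floor = exp.get("floor", 0.0)
        col = raw.get("colocalize", {})
        cfg.top_n = col.get("top_n", 3000)
        cfg.flank_bp = col.get("flank_bp", 2000)
        cfg.bins = col.get("bins", 100)
        return cfg


REQUIRED_INPUTS = (
    "chrom_sizes", "control_rep1", "control_rep2", "ko",
    "H3K4me1", "H3K4me2", "H3K27ac", "CEBPA", "CEBPB", "PPARG",
    "tss", "expression",
)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Empty list iff the config is runnable; messages name the offending key."""
    problems: list[str] = []
    if cfg.schema_version != SCHEMA_VERSION:
        problems.append(f"schema_version: expected {SCHEMA_VERSION}, got {cfg.schema_version}")
    if not (0 < cfg.fdr < 1):
        problems.append("kofilter.fdr: must lie in (0, 1)")
    for key, val in (("express.cutoff", cfg.regulation_cutoff),
                     ("express.dependency_cutoff", cfg.dependency_cutoff)):
        if val <= 1:
            problems.append(f"{key}: cutoff must exceed 1")
    if cfg.top_n <= 0:
        problems.append("colocalize.top_n: must be positive")
    if cfg.bins <= 0 or (2 * cfg.flank_bp) % cfg.bins != 0:
        problems.append("colocalize.bins: must be positive and divide 2*flank_bp")
    if cfg.replicate_mode not in ("union", "intersection"):
        problems.append("kofilter.replicate_mode: must be 'union' or 'intersection'")
    if cfg.dependency_mode not in ("ratio", "induction"):
        problems.append("express.mode: must be 'ratio' or 'induction'")
    if cfg.simulate is None:
        for key in REQUIRED_INPUTS:
            if key not in cfg.inputs:
                problems.append(f"inputs.{key}: missing (required when [simulate] absent)")
            elif not Path(cfg.inputs[key]).exists():
                problems.append(f"inputs.{key}: file not found: {cfg.inputs[key]}")
    return problems


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        ds = simulate_dataset(cfg.simulate)
        ds.write(outdir / "data")
        return ds
    genome = read_chrom_sizes(cfg.inputs["chrom_sizes"])
    frag = cfg.simulate.fragment_size if cfg.simulate else 250
    libraries = {
        name: read_tag_bed(cfg.inputs[name], genome, fragment_size=frag)
        for name in ("control_rep1", "control_rep2", "ko")
    }
    marks = {m: read_bed(cfg.inputs[m], genome) for m in ("H3K4me1", "H3K4me2", "H3K27ac")}
    tfs = {t: read_bed(cfg.inputs[t], genome) for t in ("CEBPA", "CEBPB", "PPARG")}
    tss = read_tss_table(cfg.inputs["tss"], genome)
    expression = ExpressionTable.read_tsv(cfg.inputs["expression"])
    return SyntheticDataset(
        config=cfg.simulate, genome=genome, tss=tss, mark_sets=marks, tf_sets=tfs,
        libraries=libraries, expression=expression, truth=None,
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, write per-stage outputs under `outdir`, and return the
    summary report (also written as report.json / report.tsv)."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "enhancerstate", "version": __version__},
        "schema_version": cfg.schema_version,
        "seed": cfg.island.seed if cfg.simulate is None else cfg.simulate.seed,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.monotonic()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise StageError(name, exc) from exc
            logger.info("stage %-12s done in %.1f s", name, time.monotonic() - t0)
        return deco

    state: dict = {}

    @stage("ingest")
    def _ingest():
        state["ds"] = _load_inputs(cfg, outdir)

    ds: SyntheticDataset = state["ds"]

    @stage("callpeaks")
    def _callpeaks():
        # one threshold, calibrated on the pooled control depth, shared by
        # both replicates so replicate islands are comparable
        state["rep_islands"] = {}
        for rep in ("control_rep1", "control_rep2"):
            calls = call_islands(ds.libraries[rep], cfg.island)
            state["rep_islands"][rep] = calls
            iset = islands_to_interval_set(calls, ds.genome)
            write_bed(iset, outdir / f"islands_{rep}.bed",
                      scores=[round(c.score * 10) for c in calls])
        report["stages"]["callpeaks"] = {
            rep: {"n_islands": len(calls)} for rep, calls in state["rep_islands"].items()
        }

    @stage("kofilter")
    def _kofilter():
        state["filtered"] = {}
        controls = [ds.libraries["control_rep1"], ds.libraries["control_rep2"]]
        for rep, calls in state["rep_islands"].items():
            kept = differential_ko_filter(
                calls, controls, ds.libraries["ko"], fdr=cfg.fdr, params=cfg.island
            )
            state["filtered"][rep] = kept
            islands_to_frame(kept).to_csv(outdir / f"islands_{rep}_kofiltered.tsv",
                                          sep="\t", index=False)
        report["stages"]["kofilter"] = {
            "fdr": cfg.fdr,
            **{rep: {"n_kept": len(k)} for rep, k in state["filtered"].items()},
        }

    @stage("high_confidence")
    def _highconf():
        hc = replicate_high_confidence(
            islands_to_interval_set(state["filtered"]["control_rep1"], ds.genome),
            islands_to_interval_set(state["filtered"]["control_rep2"], ds.genome),
            mode=cfg.replicate_mode,
        )
        state["high_confidence"] = hc
        write_bed(hc, outdir / "high_confidence.bed")
        entry = {"n_regions": len(hc)}
        if ds.truth is not None:
            recall, precision = truth_compare(hc, ds.truth.true_islands)
            art_recall, _ = truth_compare(hc, ds.truth.artifact_islands)
            entry.update(
                recall_true=round(recall, 4),
                precision=round(precision, 4),
                artifact_retained=round(art_recall, 4),
            )
        report["stages"]["high_confidence"] = entry

    @stage("classify")
    def _classify():
        hc: IntervalSet = state["high_confidence"]
        dist = genomic_distribution(hc, ds.mark_sets, ds.tss, cfg.rules)
        report["stages"]["classify"] = {
            cls: {"count": c, "fraction": round(f, 4)} for cls, (c, f) in dist.items()
        }
        df = classify_regions(hc, ds.mark_sets, ds.tss, cfg.rules)
        ae = IntervalSet(
            [hc[i] for i in range(len(hc)) if df["element_class"].iloc[i] == "active_enhancer"],
            genome=ds.genome,
        )
        state["active_enhancers"] = ae
        adipo = define_adipogenic_enhancers(ae, ds.tf_sets) if len(ae) else None
        state["adipogenic"] = adipo
        df.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        if adipo is not None:
            adipo.to_csv(outdir / "adipogenic_enhancers.tsv", sep="\t", index=False)
            n_ad = int(adipo["adipogenic"].sum())
            report["stages"]["classify"]["adipogenic"] = {
                "count": n_ad,
                "of_active_enhancers": len(ae),
                "percent": fraction_percent(n_ad, len(ae)) if len(ae) else None,
            }

    @stage("colocalize")
    def _colocalize():
        entry = {}
        ae: IntervalSet = state.get("active_enhancers")
        if ae is not None and len(ae) >= 1:
            venn = venn_counts(
                {"CEBP": IntervalSet(
                    list(ds.tf_sets["CEBPA"]) + list(ds.tf_sets["CEBPB"]), genome=ds.genome),
                 "PPARG": ds.tf_sets["PPARG"]},
                universe=ae,
            )
            entry["venn_on_active_enhancers"] = {
                "+".join(sorted(k)): v for k, v in venn.cells.items()
            }
        top = top_n_by_score(
            state["rep_islands"]["control_rep1"], min(cfg.top_n, max(1, len(state["rep_islands"]["control_rep1"])))
        )
        write_bed(top, outdir / "top_regions.bed")
        entry["top_n_written"] = len(top)
        report["stages"]["colocalize"] = entry

    @stage("express")
    def _express():
        expr = ds.expression
        from .expression import expressed_gene_filter

        universe = expressed_gene_filter(expr, cfg.expression_floor)
        reg = classify_regulation(expr, cutoff=cfg.regulation_cutoff, genes=universe)
        calls = classify_dependency(
            expr, reg, cutoff=cfg.dependency_cutoff, mode=cfg.dependency_mode
        )
        calls.to_csv(outdir / "expression_calls.tsv", sep="\t", index_label="gene_id")
        summary = regulation_summary(calls)
        summary["dependency_mode"] = cfg.dependency_mode
        if ds.truth is not None:
            truth = ds.truth.gene_truth.set_index("gene_id")
            merged = calls.join(truth, rsuffix="_truth")
            summary["regulation_accuracy"] = round(
                float((merged["regulation"] == merged["regulation_truth"]).mean()), 4
            )
            up = merged[merged["regulation_truth"] == "up"]
            if len(up):
                summary["dependency_accuracy"] = round(
                    float((up["dependency"] == up["dependency_truth"]).mean()), 4
                )
        report["stages"]["express"] = summary
        state["calls"] = calls

    @stage("report")
    def _report():
        report["config"] = _config_echo(cfg)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        rows = _flatten(report)
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(
            outdir / "report.tsv", sep="\t", index=False
        )

    return report


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = {
        "island": asdict(cfg.island),
        "kofilter": {"fdr": cfg.fdr, "preset": cfg.fdr_preset,
                     "replicate_mode": cfg.replicate_mode},
        "classify": asdict(cfg.rules),
        "express": {"cutoff": cfg.regulation_cutoff,
                    "dependency_cutoff": cfg.dependency_cutoff,
                    "mode": cfg.dependency_mode, "floor": cfg.expression_floor},
        "colocalize": {"top_n": cfg.top_n, "flank_bp": cfg.flank_bp, "bins": cfg.bins},
    }
    if cfg.simulate is not None:
        echo["simulate"] = asdict(cfg.simulate)
    else:
        echo["inputs"] = dict(cfg.inputs)
    return echo


def _flatten(obj, prefix: str = "") -> list[tuple[str, object]]:
    rows: list[tuple[str, object]] = []
    if isinstance(obj, dict):
        for k in sorted(obj, key=str):
            rows.extend(_flatten(obj[k], f"{prefix}{k}."))
    else:
        rows.append((prefix.rstrip("."), obj))
    return rows
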