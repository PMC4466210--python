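"""End-to-end orchestration: simulate -> lineage -> normalize -> cluster ->
de -> enrich -> qpcr, driven by one validated configuration.

Each analysis group (deceased, live) is processed separately from the
normalization stage on, mirroring the study design (per-group informative
filtering, clustering and DE).  Every stage appends to a manifest with the
parameters used and SHA-256 digests of its outputs; ``report.json``
aggregates the scientific results and is byte-identical across runs with
the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import array_processing as ap
from . import coordination as co
from . import diffexpr as de
from . import lineage as li
from . import qpcr as qp
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

STAGES = ("simulate", "lineage", "normalize", "cluster", "de", "enrich", "qpcr")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Single source of truth for paths, stage toggles and every threshold."""

    outdir: str = "run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    present_pixel_fraction: float = 0.70
    presence_rate: float = 0.90
    raw_intensity: float = 100.0
    ratio_sd: float = 1.4
    fc_threshold: float = 1.5
    alpha: float = 0.05
    heteroplasmy_threshold: float = 0.25
    lowess_span: float = 0.3
    lowess_iterations: int = 3
    purity_margin: float = 0.2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = [
            ("present_pixel_fraction", 0.0 < self.present_pixel_fraction <= 1.0),
            ("presence_rate", 0.0 < self.presence_rate < 1.0),
            ("raw_intensity", self.raw_intensity >= 0),
            ("ratio_sd", self.ratio_sd > 0),
            ("fc_threshold", self.fc_threshold >= 1.0),
            ("alpha", 0.0 < self.alpha < 1.0),
            ("heteroplasmy_threshold", 0.0 < self.heteroplasmy_threshold < 1.0),
            ("lowess_span", 0.0 < self.lowess_span <= 1.0),
            ("lowess_iterations", self.lowess_iterations >= 0),
            ("purity_margin", 0.0 <= self.purity_margin <= 1.0),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise PipelineError(f"invalid threshold(s): {bad}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage toggle(s): {sorted(unknown)}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    records = []
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages in dependency order; returns the report."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simdir = outdir / "sim"
    report: dict = {"seed": config.seed}
    manifest: list[dict] = []
    current = "?"
    try:
        sim_config = sd.SimulationConfig(**{**config.simulation, "seed": config.seed})

        if config.enabled("simulate"):
            current = "simulate"
            paths = sd.simulate_dataset(sim_config, simdir)
            manifest.append(_stage_entry(current, {"seed": config.seed}, simdir))
            report["simulate"] = {"n_slides": paths["n_slides"]}

        design = pd.read_csv(simdir / "design.tsv", sep="\t")
        animal_design = design.drop_duplicates("animal_id")[
            ["animal_id", "group", "role", "breed"]
        ].reset_index(drop=True)
        gdesign = co.GroupDesign.from_frame(animal_design)

        if config.enabled("lineage"):
            current = "lineage"
            report["lineage"] = _run_lineage(simdir, outdir, animal_design)
            manifest.append(_stage_entry(current, {}, outdir, ("lineage_",)))

        matrices: dict[str, ap.ExpressionMatrix] = {}
        annotation = pd.read_csv(simdir / "annotation.tsv", sep="\t",
                                 keep_default_na=False)
        if config.enabled("normalize"):
            current = "normalize"
            report["normalize"] = {}
            slides = [
                ap.read_slide_tsv(p)
                for p in sorted((simdir / "slides").glob("*.tsv"))
            ]
            for group in sorted(animal_design["group"].unique()):
                members = set(
                    animal_design.loc[animal_design["group"] == group, "animal_id"]
                )
                group_slides = [s for s in slides if s.sample_id in members]
                matrix, _ = ap.process_slides(
                    group_slides,
                    span=config.lowess_span,
                    iterations=config.lowess_iterations,
                    present_threshold=config.present_pixel_fraction,
                    presence_rate=config.presence_rate,
                    raw_intensity=config.raw_intensity,
                    ratio_sd=config.ratio_sd,
                )
                matrices[group] = matrix
                matrix.values.to_csv(
                    outdir / f"expression_matrix_{group}.tsv", sep="\t",
                    float_format="%.6g",
                )
                flags = pd.DataFrame({
                    "probe_id": matrix.values.index,
                    "informative": matrix.informative.to_numpy(),
                    "excluded_for": [
                        ";".join(matrix.reasons.get(str(p), []))
                        for p in matrix.values.index
                    ],
                })
                flags.to_csv(outdir / f"probe_flags_{group}.tsv", sep="\t", index=False)
                report["normalize"][group] = {
                    "n_probes": int(matrix.values.shape[0]),
                    "n_informative": matrix.n_informative,
                    "informative_percent": ap.informative_percentage(
                        matrix.n_informative, matrix.values.shape[0]
                    ),
                }
            manifest.append(_stage_entry(
                current,
                {"span": config.lowess_span, "presence_rate": config.presence_rate},
                outdir, ("expression_matrix_", "probe_flags_"),
            ))

        if config.enabled("cluster"):
            current = "cluster"
            report["cluster"] = {}
            coherence_rows = []
            for group, matrix in matrices.items():
                results = {}
                for subset in ("global", "nuclear_mito", "mtdna"):
                    sub = ap.subset_by_origin(matrix, annotation, subset)
                    res = co.cluster_subset(sub, gdesign, subset)
                    results[subset] = res
                    with open(outdir / f"cluster_{group}_{subset}.json", "w") as fh:
                        json.dump(_jsonable(res.to_dict()), fh, indent=1)
                    for treatment, r in res.r_per_treatment.items():
                        coherence_rows.append({
                            "group": group, "subset": subset,
                            "treatment": treatment, "r": r,
                        })
                contrast = co.coordination_contrast(
                    results["nuclear_mito"], results["mtdna"],
                    margin=config.purity_margin,
                )
                report["cluster"][group] = {
                    "purity": {
                        s: results[s].separation_purity
                        for s in ("global", "nuclear_mito", "mtdna")
                    },
                    "coordination": contrast,
                }
            pd.DataFrame(coherence_rows).to_csv(
                outdir / "coherence.tsv", sep="\t", index=False, float_format="%.6g"
            )
            with open(outdir / "coordination_report.json", "w") as fh:
                json.dump(_jsonable({g: report["cluster"][g]["coordination"]
                                     for g in report["cluster"]}), fh, indent=1)
            manifest.append(_stage_entry(
                current, {"margin": config.purity_margin}, outdir,
                ("cluster_", "coherence", "coordination_report"),
            ))

        de_results: dict[str, pd.DataFrame] = {}
        if config.enabled("de"):
            current = "de"
            report["de"] = {}
            for group, matrix in matrices.items():
                res = de.call_de(
                    matrix, gdesign, annotation,
                    fc_threshold=config.fc_threshold, alpha=config.alpha,
                )
                de_results[group] = res
                ann = ap.validate_annotation(annotation)
                out = res.copy()
                out.insert(1, "gene_symbol",
                           ann["gene_symbol"].reindex(res.index).to_numpy())
                out.to_csv(outdir / f"de_results_{group}.tsv", sep="\t",
                           index=False, float_format="%.6g")
                report["de"][group] = {
                    "n_tested": int(res["tested"].sum()),
                    "n_de": int((res["direction"] != "none").sum()),
                    "by_origin": de.partition_by_origin(res),
                }
            manifest.append(_stage_entry(
                current, {"fc": config.fc_threshold, "alpha": config.alpha},
                outdir, ("de_results_",),
            ))

        if config.enabled("enrich"):
            current = "enrich"
            gene_sets = de.read_gmt(simdir / "gene_sets.gmt")
            ann = ap.validate_annotation(annotation)
            report["enrich"] = {}
            frames = []
            for group, res in de_results.items():
                symbols = ann["gene_symbol"].reindex(res.index)
                universe = set(symbols)
                de_set = set(symbols[res["direction"] != "none"])
                results = de.enrich(de_set, gene_sets, universe)
                frame = de.enrichment_frame(results)
                frame.insert(0, "group", group)
                frames.append(frame)
                report["enrich"][group] = [
                    {"gene_set": r.gene_set, "fisher_p": r.fisher_p, "p_adj": r.p_adj}
                    for r in results
                ]
            if frames:
                pd.concat(frames).to_csv(outdir / "enrichment.tsv", sep="\t",
                                         index=False, float_format="%.6g")
            manifest.append(_stage_entry(current, {}, outdir, ("enrichment",)))

        if config.enabled("qpcr"):
            current = "qpcr"
            report["qpcr"] = _run_qpcr(
                simdir, outdir, gdesign, de_results, annotation, config,
            )
            manifest.append(_stage_entry(
                current, {"alpha": config.alpha}, outdir,
                ("rq", "qpcr_tests", "concordance"),
            ))

    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return report


def _stage_entry(stage: str, params: dict, outdir: Path,
                 prefixes: tuple[str, ...] = ()) -> dict:
    outputs = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and (not prefixes or p.name.startswith(prefixes)):
            outputs[str(p.relative_to(outdir))] = _digest(p)
    return {"stage": stage, "params": _jsonable(params), "outputs": outputs}


def _run_lineage(simdir: Path, outdir: Path, animal_design: pd.DataFrame) -> dict:
    refs = li.read_panel_tsv(simdir / "panel.tsv")
    genotypes = []
    for header, seq in _read_fasta(simdir / "animals.fasta"):
        fields = dict(
            kv.split("=") for kv in header.split()[1:] if "=" in kv
        )
        animal_id = header.split()[0]
        offset = int(fields.get("offset", 1))
        genotypes.append(li.extract_panel_genotype(
            seq, offset, list(refs[0].panel_calls),
            animal_id=animal_id,
            group=fields.get("group", "?"), role=fields.get("role", "?"),
        ))
    calls = [li.assign_lineage(g, refs) for g in genotypes]
    li.calls_to_frame(calls).to_csv(outdir / "lineage_calls.tsv", sep="\t",
                                    index=False)
    summary = li.lineage_report(calls, animal_design)
    with open(outdir / "lineage_summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1)
    return summary


def _run_qpcr(
    simdir: Path,
    outdir: Path,
    gdesign: co.GroupDesign,
    de_results: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    config: RunConfig,
) -> dict:
    records = pd.read_csv(simdir / "qpcr.tsv", sep="\t")
    rq = qp.comparative_ct(records, sd.QPCR_CONTROL_GENE, "REF")
    rq.to_csv(outdir / "rq.tsv", sep="\t", index=False, float_format="%.6g")

    # Microarray fold changes per gene symbol, pooled over analysis groups
    # (first group carrying the gene wins).
    ann = ap.validate_annotation(annotation)
    fold: dict[str, float] = {}
    for group in sorted(de_results):
        res = de_results[group]
        symbols = ann["gene_symbol"].reindex(res.index)
        for sym, fc in zip(symbols, res["fold_change"]):
            if np.isfinite(fc):
                fold.setdefault(sym, float(fc))

    genes = sorted(set(rq["gene"]) - {sd.QPCR_CONTROL_GENE})
    tests = []
    for gene in genes:
        direction = None
        if gene in fold:
            direction = "up" if fold[gene] >= 1.0 else "down"
        sub = rq[rq["sample_id"].isin(gdesign.treatment) & (rq["gene"] == gene)]
        t = sub["sample_id"].map(gdesign.treatment)
        clones = sub.loc[t == "clone", "rq"]
        controls = sub.loc[t == "control", "rq"]
        if direction is None or len(clones) < 2 or len(controls) < 2:
            continue
        cmp = qp.compare_groups(clones, controls, direction, alpha=config.alpha)
        tests.append({
            "gene": gene, "direction": direction, "f_p": cmp.f_p,
            "t_p": cmp.t_p, "branch": cmp.branch,
            "significant": cmp.significant,
        })
    pd.DataFrame(tests).to_csv(outdir / "qpcr_tests.tsv", sep="\t", index=False,
                               float_format="%.6g")

    table, fraction = qp.concordance(rq, gdesign, fold, genes)
    table.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    return {
        "n_genes": len(genes),
        "tests": tests,
        "concordance_fraction": None if np.isnan(fraction) else fraction,
    }
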