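"""End-to-end orchestration: simulate -> build-ref -> quant -> de ->
intersect -> enrich -> curate, driven by one YAML config.

Every stochastic stage must carry an explicit seed; the summary embeds
the fully resolved config so a run is reproducible from its report
alone. Identical config implies byte-identical summary output.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Any, Dict

import pandas as pd
import yaml

from tagdge import io as tio
from tagdge.curation import curate
from tagdge.diffexpr import common_degs, compare_libraries
from tagdge.enrichment import enrich_terms
from tagdge.quant import clean_tags, map_tags, tpm_normalize
from tagdge.reference import build_index
from tagdge.simulate import (
    SimulationConfig,
    generate_annotations,
    generate_family_fixtures,
    generate_unigenes,
    simulate_tag_library,
    spike_truth,
)

DEFAULT_THRESHOLDS = {
    "fdr_max": 0.001,
    "min_abs_log2": 1.0,
    "go_alpha": 0.05,
    "kegg_alpha": 0.05,
    "min_len": 400,
    "min_orf_aa": 100,
    "min_identity": 0.95,
    "min_coverage": 0.8,
}


class ConfigError(ValueError):
    pass


def _require_seed(section: Dict[str, Any], where: str) -> int:
    if "seed" not in section:
        raise ConfigError(f"config section {where!r} is missing an explicit seed")
    return int(section["seed"])


def validate_config(config: Dict[str, Any]) -> Dict[str, Any]:
    """Fill defaults and fail fast on missing seeds, before any stage runs."""
    resolved = dict(config)
    if "run_id" not in resolved:
        raise ConfigError("config is missing run_id")
    sim = dict(resolved.get("simulate", {}))
    _require_seed(sim, "simulate")
    treatments = sim.get("treatments")
    if not treatments:
        raise ConfigError("config must define at least one treatment under simulate.treatments")
    for name, spec in treatments.items():
        _require_seed(spec, f"simulate.treatments.{name}")
    ann = dict(resolved.get("annotations", {}))
    _require_seed(ann, "annotations")
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(resolved.get("thresholds", {}))
    resolved["simulate"] = sim
    resolved["annotations"] = ann
    resolved["thresholds"] = thresholds
    resolved.setdefault("quant", {"denominator": "clean"})
    resolved.setdefault("curation", {"seed": int(sim["seed"])})
    return resolved


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def run_pipeline(config: Dict[str, Any], out_dir: str | os.PathLike) -> Dict[str, Any]:
    """Execute all stages; write stage outputs and a deterministic summary."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, Any] = {"run_id": config["run_id"], "config": config, "stages": {}}

    def stage(name):
        summary["stages"][name] = {}
        return summary["stages"][name]

    # --- simulate -------------------------------------------------------
    sim_cfg = config["simulate"]
    treatments = sim_cfg["treatments"]
    base = SimulationConfig(
        n_genes=int(sim_cfg.get("n_genes", 2000)),
        length_range=tuple(sim_cfg.get("length_range", (300, 1500))),
        catg_free_fraction=float(sim_cfg.get("catg_free_fraction", 0.0)),
        library_size=int(sim_cfg.get("library_size", 1_000_000)),
        error_rate=float(sim_cfg.get("error_rate", 0.0)),
        n_contaminant_reads=int(sim_cfg.get("n_contaminant_reads", 0)),
        seed=int(sim_cfg["seed"]),
    )
    try:
        unigenes, truth = generate_unigenes(base)
    except ValueError as exc:
        raise ConfigError(f"[simulate] {exc}") from exc
    tio.write_fasta(unigenes, out / "unigenes.fasta")

    truths = {}
    for name, spec in treatments.items():
        truths[name] = spike_truth(
            truth,
            n_up=int(spec.get("n_up", 0)),
            n_down=int(spec.get("n_down", 0)),
            fold=float(spec.get("fold", 8.0)),
            seed=int(spec["seed"]),
        )
        truths[name].to_csv(out / f"truth_{name}.tsv", sep="\t")

    control_lib = simulate_tag_library(unigenes, truth, treated=False, config=base, name="control")
    tio.write_tag_table(control_lib.tags, out / "tags_control.tsv")
    libs = {}
    for name, t in truths.items():
        libs[name] = simulate_tag_library(unigenes, t, treated=True, config=base, name=name)
        tio.write_tag_table(libs[name].tags, out / f"tags_{name}.tsv")
    stage("simulate").update(
        n_genes=base.n_genes,
        library_size=base.library_size,
        treatments=sorted(treatments),
        unigenes_sha256=_sha256(out / "unigenes.fasta"),
    )

    # --- build-ref ------------------------------------------------------
    index = build_index(unigenes, strand_mode=config.get("reference", {}).get("strand_mode", "sense_only"))
    index.write_tsv(out / "reference_tags.tsv")
    stage("build_ref").update(
        tag_count=index.tag_count,
        unquantifiable=len(index.unquantifiable),
        reference_sha256=_sha256(out / "reference_tags.tsv"),
    )

    # --- quant ----------------------------------------------------------
    denominator = config["quant"].get("denominator", "clean")
    tables = {}
    quant_stage = stage("quant")
    for name, lib in [("control", control_lib)] + sorted(libs.items()):
        table = tpm_normalize(map_tags(clean_tags(lib), index), denominator=denominator)
        table.write_tsv(out / f"expression_{name}.tsv")
        tables[name] = table
        quant_stage[name] = dict(table.totals)

    # --- de + intersect -------------------------------------------------
    thr = config["thresholds"]
    universe = sorted(g for g in unigenes if g not in set(index.unquantifiable))
    comparisons = {}
    de_stage = stage("de")
    for name in sorted(libs):
        df = compare_libraries(
            tables["control"],
            tables[name],
            gene_universe=universe,
            fdr_max=float(thr["fdr_max"]),
            min_abs_log2=float(thr["min_abs_log2"]),
        )
        df.to_csv(out / f"de_control_vs_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        comparisons[name] = df
        de_stage[name] = {
            "up": int((df["call"] == "up").sum()),
            "down": int((df["call"] == "down").sum()),
        }
    if len(comparisons) >= 2:
        names = sorted(comparisons)
        common = common_degs(comparisons[names[0]], comparisons[names[1]])
        stage("intersect").update(
            comparisons=[names[0], names[1]],
            common_up=len(common["common_up"]),
            common_down=len(common["common_down"]),
        )
        with open(out / "common_degs.json", "w") as handle:
            json.dump(
                {k: sorted(v) for k, v in common.items()}, handle, indent=2, sort_keys=True
            )

    # --- enrich ---------------------------------------------------------
    ann_cfg = config["annotations"]
    first_treatment = sorted(truths)[0]
    annotation = generate_annotations(
        truths[first_treatment],
        n_terms=int(ann_cfg.get("n_terms", 30)),
        enriched_rate=float(ann_cfg.get("enriched_rate", 0.6)),
        background_rate=float(ann_cfg.get("background_rate", 0.05)),
        seed=int(ann_cfg["seed"]),
    )
    tio.write_annotation_table(annotation, out / "annotations.tsv")
    enrich_stage = stage("enrich")
    for name, df in sorted(comparisons.items()):
        degs = sorted(df.loc[df["call"] != "ns", "gene_id"])
        go = enrich_terms(annotation, degs, correction="bonferroni", alpha=float(thr["go_alpha"]))
        kegg = enrich_terms(annotation, degs, correction="bh", alpha=float(thr["kegg_alpha"]))
        go.to_csv(out / f"enrichment_go_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        kegg.to_csv(out / f"enrichment_kegg_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        enrich_stage[name] = {
            "go_significant": int(go["significant"].sum()),
            "kegg_significant": int(kegg["significant"].sum()),
        }

    # --- curate ---------------------------------------------------------
    fixtures, _expected = generate_family_fixtures(seed=int(config["curation"]["seed"]))
    records = curate(
        fixtures,
        min_len=int(thr["min_len"]),
        min_orf_aa=int(thr["min_orf_aa"]),
        min_identity=float(thr["min_identity"]),
        min_coverage=float(thr["min_coverage"]),
    )
    pd.DataFrame(
        [
            (r.gene_id, r.length_bp, r.longest_orf_aa, r.disposition, r.cluster_id or "")
            for r in records
        ],
        columns=["gene_id", "length_bp", "longest_orf_aa", "disposition", "cluster_id"],
    ).to_csv(out / "curation.tsv", sep="\t", index=False)
    tally: Dict[str, int] = {}
    for r in records:
        tally[r.disposition] = tally.get(r.disposition, 0) + 1
    stage("curate").update(tally)

    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary


def load_config(path: str | os.PathLike) -> Dict[str, Any]:
    with open(path) as handle:
        return yaml.safe_load(handle)
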