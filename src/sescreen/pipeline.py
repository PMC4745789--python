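"""End-to-end orchestration of the screening stages from one config.

Stage order: simulate (optional) -> super-enhancer calling -> gene
assignment -> microsatellite scan and enrichment -> metagene profiles ->
GSEA -> screen integration. Each stage's output files are digested
(sha256) into a run manifest, so a rerun with the same config and seed
can be checked for byte-identical deterministic outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .enhancers import (
    DEFAULT_STITCH_DISTANCE_BP,
    DEFAULT_TSS_EXCLUSION_BP,
    call_super,
    define_candidates,
    quantify_and_rank,
    stitch,
    summarize_ranking,
)
from .genes import (
    DEFAULT_EXPRESSION_THRESHOLD,
    DEFAULT_WINDOW_BP,
    assign_genes,
    class_gene_sets,
)
from .gsea import (
    expression_by_class,
    gsea_permutation_p,
    rank_genes_by_enhancer_signal,
)
from .metagene import build_metagene
from .microsat import (
    region_overlap_enrichment,
    repeat_count_comparison,
    scan_microsatellites,
)
from .screens import (
    drug_sensitivity_test,
    integrate_hits,
    signal_to_noise_selectivity,
)
from .simulate import SyntheticConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class InputError(ValueError):
    """A named input file is missing or unreadable."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: List[dict] = field(default_factory=list)
    warnings: int = 0

    def record(self, name: str, outputs: Dict[str, Path], elapsed: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "elapsed_s": round(elapsed, 3),
                "outputs": {
                    str(Path(p).name): _sha256(p) for p in outputs.values()
                },
            }
        )

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_PARAMS = {
    "tss_exclusion_bp": DEFAULT_TSS_EXCLUSION_BP,
    "stitch_distance_bp": DEFAULT_STITCH_DISTANCE_BP,
    "k4me3_overlap_fraction": 0.5,
    "se_method": "tangent",
    "window_bp": DEFAULT_WINDOW_BP,
    "expression_threshold": DEFAULT_EXPRESSION_THRESHOLD,
    "msat_unit": "GGAA",
    "msat_min_repeats": 2,
    "gsea_weight": 1.0,
    "gsea_n_permutations": 1000,
    "snr_n_permutations": 1000,
    "dependency_p_threshold": 0.05,
    "drug_p_threshold": 0.05,
    "body_bins": 50,
    "flank_bp": 5000,
    "flank_bins": 25,
}


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    try:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def run_pipeline(config, out_dir) -> RunManifest:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 17))
    params = dict(DEFAULT_PARAMS)
    user_params = cfg.get("params", {})
    unknown = set(user_params) - set(params)
    if unknown:
        raise ConfigError(f"params: unknown keys {sorted(unknown)}")
    params.update(user_params)

    manifest = RunManifest(config=cfg, seed=seed)
    summary: dict = {"seed": seed}

    # ---- stage: simulate or load inputs
    t0 = time.time()
    truth = None
    if cfg.get("simulate", False):
        sim_overrides = dict(cfg.get("simulate_config", {}))
        sim_overrides["seed"] = seed
        try:
            sim_config = SyntheticConfig(**sim_overrides)
        except TypeError as exc:
            raise ConfigError(f"simulate_config: {exc}") from exc
        dataset = simulate_dataset(sim_config, with_sequence=True)
        data_dir = out / "data"
        paths = write_dataset(dataset, data_dir)
        manifest.record("simulate", paths, time.time() - t0)
        inputs = {k: str(v) for k, v in paths.items()}
        truth = dataset.truth
    else:
        inputs = cfg.get("inputs", {})

    required = ["k27ac_peaks", "k27ac_track", "k4me3_peaks", "genes"]
    for key in required:
        if key not in inputs:
            raise InputError(f"missing input: inputs.{key}")
    for key in required:
        if not Path(inputs[key]).exists():
            raise InputError(f"input file not found: inputs.{key} = {inputs[key]}")

    try:
        k27_peaks = sio.read_bed(inputs["k27ac_peaks"])
        k4_peaks = sio.read_bed(inputs["k4me3_peaks"])
        genes = sio.read_genes_tsv(inputs["genes"])
        track = sio.read_bedgraph(inputs["k27ac_track"])
        fli1_peaks = (
            sio.read_bed(inputs["fli1_peaks"]) if inputs.get("fli1_peaks") else []
        )
        control = (
            sio.read_bedgraph(inputs["control_track"])
            if inputs.get("control_track")
            else None
        )
    except ValueError as exc:
        raise InputError(str(exc)) from exc

    # ---- stage: super-enhancer calling
    t0 = time.time()
    try:
        candidates = define_candidates(
            k27_peaks,
            genes,
            k4_peaks,
            tss_exclusion_bp=params["tss_exclusion_bp"],
            k4me3_overlap_fraction=params["k4me3_overlap_fraction"],
        )
        enhancers = stitch(candidates, params["stitch_distance_bp"])
        ranking = quantify_and_rank(enhancers, track, control)
        ranking = call_super(
            ranking, method=params["se_method"], n=cfg.get("top_n")
        )
    except ValueError as exc:
        raise StageError(f"call-se: {exc}") from exc
    enh_bed = out / "enhancers.bed"
    sio.write_bed(
        [
            dataclasses.replace(
                e.constituents[0],
                interval=e.region,
                score=round(e.signal, 6),
                name=e.eid,
            )
            for e in ranking.enhancers
        ],
        enh_bed,
        extra_columns=[(e.rank, e.klass.value) for e in ranking.enhancers],
        header=f"seed={seed}",
    )
    ranking_summary = summarize_ranking(ranking)
    summary["ranking"] = ranking_summary
    with open(out / "ranking_summary.json", "w") as fh:
        json.dump(ranking_summary, fh, indent=1, sort_keys=True)
    manifest.record(
        "call-se",
        {"enhancers": enh_bed, "summary": out / "ranking_summary.json"},
        time.time() - t0,
    )

    # ---- stage: gene assignment
    t0 = time.time()
    assignment = assign_genes(
        ranking,
        genes,
        window_bp=params["window_bp"],
        expression_threshold=params["expression_threshold"],
    )
    gene_sets = class_gene_sets(assignment)
    links_df = pd.DataFrame(
        [
            {
                "enhancer_id": l.enhancer_id,
                "gene_id": l.gene_id,
                "distance": l.distance,
                "klass": l.enhancer_klass.value,
            }
            for l in assignment.links
        ]
    )
    if len(links_df):
        links_df = links_df.sort_values(["gene_id", "enhancer_id"])
    links_path = out / "assignment_links.tsv"
    links_df.to_csv(links_path, sep="\t", index=False)
    se_genes_path = out / "se_genes.tsv"
    best: Dict[str, tuple] = {}
    for l in assignment.links:
        if l.gene_id not in best or l.enhancer_signal > best[l.gene_id][2]:
            best[l.gene_id] = (l.enhancer_id, l.distance, l.enhancer_signal, l.enhancer_klass.value)
    pd.DataFrame(
        [
            {
                "gene_id": g,
                "best_enhancer": best[g][0],
                "distance": best[g][1],
                "class": "SUPER" if g in gene_sets["super_genes"] else "TYPICAL",
            }
            for g in sorted(set(gene_sets["super_genes"]) | set(gene_sets["typical_genes"]))
        ]
    ).to_csv(se_genes_path, sep="\t", index=False)
    summary["gene_assignment"] = {
        "n_super_genes": gene_sets["n_super_genes"],
        "n_typical_genes": gene_sets["n_typical_genes"],
    }
    manifest.record(
        "assign", {"links": links_path, "se_genes": se_genes_path}, time.time() - t0
    )

    # ---- stage: microsatellites and enrichment
    t0 = time.time()
    super_regions = [e.region for e in ranking.super_enhancers]
    typical_regions = [e.region for e in ranking.typical_enhancers]
    enrich_rows = []
    msat_path = None
    msats = []
    if inputs.get("genome"):
        fasta = sio.FastaSource(inputs["genome"])
        msats = scan_microsatellites(
            fasta, unit=params["msat_unit"], min_repeats=params["msat_min_repeats"]
        )
        msat_path = out / "microsatellites.bed"
        sio.write_bed(
            [
                sio.Peak(m.region, score=m.repeat_count, name=m.unit)
                for m in msats
            ],
            msat_path,
            header=f"seed={seed}",
        )
    if super_regions and typical_regions:
        if fli1_peaks:
            enr = region_overlap_enrichment(
                super_regions, typical_regions, [p.interval for p in fli1_peaks]
            )
            enrich_rows.append(_enrich_row("fli1_peak_overlap", enr))
            summary["fli1_enrichment"] = enrich_rows[-1]
        if msats:
            enr = region_overlap_enrichment(
                super_regions, typical_regions, [m.region for m in msats]
            )
            enrich_rows.append(_enrich_row("ggaa_microsat_overlap", enr))
            summary["msat_enrichment"] = enrich_rows[-1]
    if msats and fli1_peaks:
        rep = repeat_count_comparison(msats, fli1_peaks)
        row = {
            "test": "repeat_count_in_vs_out_fli1",
            "statistic": rep.statistic,
            "p_value": rep.p_value,
            **rep.details,
        }
        enrich_rows.append(row)
        summary["repeat_counts"] = row
    enrich_path = out / "enrichment_results.tsv"
    pd.DataFrame(enrich_rows).to_csv(enrich_path, sep="\t", index=False)
    outputs = {"enrichment": enrich_path}
    if msat_path:
        outputs["microsatellites"] = msat_path
    manifest.record("msat-enrich", outputs, time.time() - t0)

    # ---- stage: metagene
    t0 = time.time()
    meta_outputs = {}
    for label, regions in (("super", super_regions), ("typical", typical_regions)):
        if not regions:
            continue
        profile = build_metagene(
            regions,
            track,
            body_bins=params["body_bins"],
            flank_bp=params["flank_bp"],
            flank_bins=params["flank_bins"],
        )
        path = out / f"metagene_{label}.tsv"
        pd.DataFrame(
            {"bin": np.arange(len(profile.mean_signal)), "mean_signal": profile.mean_signal}
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")
        meta_outputs[label] = path
        summary.setdefault("metagene", {})[label] = {
            "n_regions": profile.n_regions,
            "mean_body_density": float(
                profile.mean_signal[
                    profile.flank_bins : profile.flank_bins + profile.body_bins
                ].mean()
            ),
            "median_region_length": profile.median_region_length,
        }
    manifest.record("metagene", meta_outputs, time.time() - t0)

    # ---- stage: GSEA and expression by class
    t0 = time.time()
    gsea_outputs = {}
    try:
        ranked = rank_genes_by_enhancer_signal(assignment, ranking)
    except Exception as exc:  # no links at all
        raise StageError(f"gsea: {exc}") from exc
    query_sets: Dict[str, set] = {}
    if inputs.get("gene_sets"):
        query_sets.update(sio.read_gmt(inputs["gene_sets"]))
    if fli1_peaks:
        # genes whose linked enhancers carry a FLI1 peak: the ChIP-defined
        # EWS/FLI1 target surrogate set
        from .microsat import _overlap_flags

        enh_regions = [e.region for e in ranking.enhancers]
        flags = _overlap_flags(enh_regions, [p.interval for p in fli1_peaks])
        fli1_eids = {
            e.eid for e, f in zip(ranking.enhancers, flags) if f
        }
        fli1_target_genes = {
            l.gene_id for l in assignment.links if l.enhancer_id in fli1_eids
        }
        if fli1_target_genes:
            query_sets["fli1_target_genes"] = fli1_target_genes
    gsea_rows = []
    for name, gene_set in sorted(query_sets.items()):
        overlap = set(gene_set) & set(ranked.ids)
        if not overlap or len(overlap) >= len(ranked):
            logger.warning("gene set %s skipped (overlap %d)", name, len(overlap))
            continue
        res = gsea_permutation_p(
            ranked,
            gene_set,
            weight_exponent=params["gsea_weight"],
            n_permutations=params["gsea_n_permutations"],
            seed=seed,
        )
        gsea_rows.append(
            {
                "set": name,
                "n_genes": len(overlap),
                "es": res.es,
                "nes": res.nes,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "seed": res.seed,
            }
        )
    gsea_path = out / "gsea_results.tsv"
    pd.DataFrame(gsea_rows).to_csv(gsea_path, sep="\t", index=False, float_format="%.6g")
    gsea_outputs["gsea"] = gsea_path
    summary["gsea"] = gsea_rows
    if assignment.super_genes and assignment.typical_genes:
        expr = expression_by_class(genes, assignment)
        expr_path = out / "expression_by_class.tsv"
        pd.DataFrame(
            [
                {"class": "SUPER", **expr["super"]},
                {"class": "TYPICAL", **expr["typical"]},
            ]
        ).to_csv(expr_path, sep="\t", index=False, float_format="%.6g")
        gsea_outputs["expression_by_class"] = expr_path
        summary["expression_by_class"] = {
            "super_median": expr["super"]["median"],
            "typical_median": expr["typical"]["median"],
            "p_value": expr["test"].p_value if expr["test"] else None,
        }
    manifest.record("gsea", gsea_outputs, time.time() - t0)

    # ---- stage: screen integration
    t0 = time.time()
    int_outputs = {}
    if inputs.get("dependency") and inputs.get("labels"):
        matrix = sio.read_dependency_tsv(inputs["dependency"], inputs["labels"])
        target_lineage = cfg.get("target_lineage", "EWING")
        selectivity = signal_to_noise_selectivity(
            matrix,
            target_lineage,
            n_permutations=params["snr_n_permutations"],
            seed=seed,
        )
        sel_path = out / "selectivity.tsv"
        selectivity.table.sort_values("rank").to_csv(
            sel_path, sep="\t", index_label="gene_id", float_format="%.6g"
        )
        int_outputs["selectivity"] = sel_path
        dep_hits = set(
            selectivity.table.index[
                (selectivity.table["p_value"] < params["dependency_p_threshold"])
                & (selectivity.table["snr"] < 0)
            ]
        )
        drug_validated: set = set(cfg.get("drug_target_genes", []) or [])
        drug_p = None
        if inputs.get("ic50"):
            drug_table = sio.read_ic50_tsv(inputs["ic50"])
            drug = drug_sensitivity_test(drug_table, target_lineage)
            drug_p = drug.p_value
            drug_path = out / "drug_test.tsv"
            pd.DataFrame(
                [{"test": drug.name, "U": drug.statistic, "p_value": drug.p_value, **{k: v for k, v in drug.details.items() if not isinstance(v, (list, dict))}}]
            ).to_csv(drug_path, sep="\t", index=False, float_format="%.6g")
            int_outputs["drug_test"] = drug_path
            if not drug_validated and truth is not None:
                # in simulate mode the profiled compound targets the planted
                # driver genes; they validate if the lineage shift is detected
                drug_validated = (
                    set(truth.driver_genes)
                    if drug.p_value < params["drug_p_threshold"]
                    else set()
                )
        venn = integrate_hits(gene_sets["super_genes"], dep_hits, drug_validated)
        venn_path = out / "venn_regions.json"
        with open(venn_path, "w") as fh:
            json.dump(venn, fh, indent=1, sort_keys=True)
        int_outputs["venn"] = venn_path
        summary["integration"] = {
            "n_dependency_hits": len(dep_hits),
            "drug_p_value": drug_p,
            "triple_intersection": venn["se_dependency_drug"],
            "top_selective_genes": selectivity.top_genes(10),
        }
    manifest.record("integrate", int_outputs, time.time() - t0)

    # ---- finalize
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True, default=str)
    return manifest


def _enrich_row(name: str, enr: dict) -> dict:
    table = enr["table"]
    result = enr["result"]
    return {
        "test": name,
        "odds_ratio": result.odds_ratio,
        "p_value": result.p_value,
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
    }
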