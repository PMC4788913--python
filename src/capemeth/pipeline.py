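"""Pipeline orchestration: simulate → call → diff → annotate → ASM.

A single JSON config drives every stage; all thresholds default to the
study's values (coverage window [2,30], min coverage 5, 25% difference,
p <= 0.05, 4+ sites per top gene).  The run writes stage TSV/JSON outputs
plus a machine-readable ``report.json`` whose bytes are identical for
identical config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import pandas as pd

from . import annotation as ann
from . import calling, differential, haplotyping, simulate

__all__ = ["run_pipeline", "DEFAULT_THRESHOLDS", "PipelineConfigError"]

logger = logging.getLogger("capemeth")

DEFAULT_THRESHOLDS = {
    "alpha": 0.05,
    "window": [2, 30],
    "min_cov": 5,
    "diff_threshold": 25.0,
    "min_sites": 4,
    "asm_alpha": 0.05,
    "asm_min_calls": 30,
    "asm_min_informative": 1,
}


class PipelineConfigError(ValueError):
    """Schema violation in the pipeline config, with a field path."""


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise PipelineConfigError(f"config field '{path}': {msg}")


def _validate_config(config: Dict[str, Any]) -> Dict[str, Any]:
    _require(isinstance(config, dict), "<root>", "must be a JSON object")
    known = {"simulation", "inputs", "thresholds", "asm_regions", "seed"}
    for k in config:
        _require(k in known, k, f"unknown key (expected one of {sorted(known)})")
    _require("simulation" in config or "inputs" in config, "<root>",
             "needs a 'simulation' block or an 'inputs' block")
    thresholds = dict(DEFAULT_THRESHOLDS)
    user_thr = config.get("thresholds", {})
    _require(isinstance(user_thr, dict), "thresholds", "must be an object")
    for k, v in user_thr.items():
        _require(k in DEFAULT_THRESHOLDS, f"thresholds.{k}", "unknown threshold")
        thresholds[k] = v
    _require(0 < thresholds["alpha"] < 1, "thresholds.alpha", "must be in (0,1)")
    _require(thresholds["min_cov"] >= 1, "thresholds.min_cov", "must be >= 1")
    lo, hi = thresholds["window"]
    _require(1 <= lo <= hi, "thresholds.window", "must satisfy 1 <= lo <= hi")
    if "simulation" in config:
        sim = config["simulation"]
        _require(isinstance(sim, dict), "simulation", "must be an object")
        valid = {f.name for f in simulate.SimulationConfig.__dataclass_fields__.values()}
        for k in sim:
            _require(k in valid, f"simulation.{k}", "unknown simulation field")
    if "asm_regions" in config:
        _require(isinstance(config["asm_regions"], list), "asm_regions",
                 "must be a list of {start, end} objects")
        for i, r in enumerate(config["asm_regions"]):
            _require(isinstance(r, dict) and {"start", "end"} <= set(r),
                     f"asm_regions[{i}]", "needs integer 'start' and 'end'")
    return thresholds


def _config_hash(config: Dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _summary_dict(s: calling.MethylomeSummary) -> Dict[str, Any]:
    out = {}
    for c in (*s.contexts, s.all_cytosines):
        out[c.context] = {
            "genome_total": c.genome_total,
            "total_covered": c.total_covered,
            "pct_of_genome_covered": round(c.pct_of_genome_covered, 4),
            "total_methylated": c.total_methylated,
            "pct_methylation": round(c.pct_methylation, 4),
        }
    return out


def run_pipeline(
    config: Dict[str, Any] | str | Path,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> Tuple[Dict[str, Any], Path]:
    """Run every applicable stage; return (report, output directory).

    ``config`` is a dict or a path to a JSON file.  ``seed`` overrides
    config['seed'] (and simulation.seed) when given.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    config = json.loads(json.dumps(config))  # deep copy, JSON-clean
    thresholds = _validate_config(config)
    if seed is not None:
        config["seed"] = int(seed)
        if "simulation" in config:
            config["simulation"]["seed"] = int(seed)
    run_seed = int(config.get("seed", config.get("simulation", {}).get("seed", 0)))

    if out_dir is None:
        out_dir = Path(f"run_{_config_hash(config)[:10]}_s{run_seed}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds in effect: %s", thresholds)

    report: Dict[str, Any] = {
        "config": config,
        "seed": run_seed,
        "thresholds": thresholds,
    }

    # ----- inputs: simulate or load -------------------------------------
    world = None
    if "simulation" in config:
        sim_cfg = simulate.SimulationConfig(**{**config["simulation"],
                                               "seed": run_seed})
        world = simulate.build_world(sim_cfg)
        simulate.write_world(world, out_dir / "sim_inputs")
        tables = {}
        for mode in simulate.MODES:
            counts, control = simulate.simulate_count_table(world, mode)
            calling.write_count_table(counts, out_dir / f"counts_{mode}.tsv")
            calling.write_count_table(control, out_dir / f"control_{mode}.tsv")
            tables[mode] = (counts, control)
        counts_a, control_a = tables[simulate.FERTILIZED]
        counts_b, control_b = tables[simulate.THELYTOKOUS]
        genome_totals = calling.genome_context_totals(world.reference)
        annotation = ann.annotation_from_genes(world.genes)
        logger.info("simulated world: %d bp, %d genes, %d CpG dyads",
                    sim_cfg.genome_length, len(world.genes), world.dyad_pos.size)
    else:
        inp = config["inputs"]
        counts_a = calling.read_count_table(inp["counts_fertilized"])
        counts_b = calling.read_count_table(inp["counts_thelytokous"])
        control_a = calling.read_count_table(inp["control_fertilized"])
        control_b = calling.read_count_table(inp["control_thelytokous"])
        from Bio import SeqIO
        ref = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(inp["reference"], "fasta")}
        genome_totals = calling.genome_context_totals(ref)
        annotation = ann.load_models(inp["genes"])

    # ----- methylation calling ------------------------------------------
    window = tuple(thresholds["window"])
    alpha = thresholds["alpha"]
    est_a = calling.estimate_conversion_rate(control_a)
    est_b = calling.estimate_conversion_rate(control_b)
    calls_a = calling.call_sites(counts_a, est_a, alpha=alpha, window=window)
    calls_b = calling.call_sites(counts_b, est_b, alpha=alpha, window=window)
    calling.write_call_table(calls_a, out_dir / "calls_fertilized.tsv")
    calling.write_call_table(calls_b, out_dir / "calls_thelytokous.tsv")
    summary_a = calling.summarize_methylome(calls_a, genome_totals, window)
    summary_b = calling.summarize_methylome(calls_b, genome_totals, window)
    overlap = calling.overlap_calls(calls_a, calls_b)
    report["conversion"] = {
        "fertilized": round(est_a.rate, 6),
        "thelytokous": round(est_b.rate, 6),
    }
    report["methylome_summary"] = {
        "fertilized": _summary_dict(summary_a),
        "thelytokous": _summary_dict(summary_b),
    }
    ov = {k: (round(v, 6) if isinstance(v, float) else v)
          for k, v in vars(overlap).items()}
    report["overlap"] = json.loads(json.dumps(ov))  # NaN-safe via json round trip

    # ----- differential methylation -------------------------------------
    diff = differential.differential_sites(
        counts_a, counts_b, min_cov=thresholds["min_cov"],
        diff_threshold=thresholds["diff_threshold"], alpha=alpha, context="CG")
    diff_out = diff.copy()
    diff_out["significant"] = diff_out["significant"].astype(int)
    diff_out.to_csv(out_dir / "differential_sites.tsv", sep="\t", index=False,
                    float_format="%.6g")
    n_a, n_b, bias = differential.hyper_counts_and_bias(diff)
    report["differential"] = {
        "n_tested": int(len(diff)),
        "n_significant": int(diff["significant"].sum()) if len(diff) else 0,
        "hyper_fertilized": n_a,
        "hyper_thelytokous": n_b,
        "bias_chi2": None if bias is None else round(bias.statistic, 4),
        "bias_p": None if bias is None else float(f"{bias.p_value:.4g}"),
    }

    # ----- gene annotation ----------------------------------------------
    partition = ann.context_partition(diff, annotation)
    top, (g_a, g_b, g_both) = ann.aggregate_gene_hypermethylation(
        diff, annotation, min_sites=thresholds["min_sites"])
    ann.write_gene_summary(top, out_dir / "gene_summary.tsv")
    report["genes"] = {
        "context_partition": partition,
        "genes_with_hyper_fertilized": g_a,
        "genes_with_hyper_thelytokous": g_b,
        "genes_with_both": g_both,
        "top_genes": [s.gene_id for s in top],
    }

    # ----- ASM haplotyping ----------------------------------------------
    if config.get("asm_regions"):
        if world is None:
            raise PipelineConfigError(
                "config field 'asm_regions': requires a simulation block "
                "(clone FASTA inputs go through the asm subcommand)")
        report["asm"] = {}
        for r in config["asm_regions"]:
            region = (int(r["start"]), int(r["end"]))
            verdict = _run_asm_region(world, region, thresholds, out_dir)
            report["asm"][f"{world.config.chrom_name}:{region[0]}-{region[1]}"] = verdict

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report, out_dir


def _run_asm_region(world, region, thresholds, out_dir) -> Dict[str, Any]:
    matrices = {}
    qc = {}
    n_clones = 20
    for mode in simulate.MODES:
        clone_set = simulate.simulate_clones(world, region, mode, n_clones)
        simulate.write_clone_fasta(
            clone_set, out_dir / f"clones_{mode}_{region[0]}_{region[1]}.fa")
        mat, stats = haplotype_clone_set(
            clone_set, min_informative=thresholds["asm_min_informative"])
        matrices[mode] = mat
        qc[mode] = stats
    verdict = haplotyping.classify_poe_vs_asm(
        matrices[simulate.FERTILIZED], matrices[simulate.THELYTOKOUS],
        alpha=thresholds["asm_alpha"], min_calls=thresholds["asm_min_calls"])
    out = {
        "verdict": verdict.verdict,
        "cross_mode_q": {a: float(f"{q:.4g}") for a, q in verdict.cross_mode_q.items()},
        "heterogeneity_p": {m: float(f"{p:.4g}")
                            for m, p in verdict.heterogeneity_p.items()},
        "delta_pct": {a: round(d, 3) for a, d in verdict.delta_pct.items()},
        "overall_pct": {
            mode: {a: round(p, 3) for a, p in matrices[mode].overall_pct().items()}
            for mode in simulate.MODES},
        "qc": qc,
        "alpha": verdict.alpha,
        "min_calls": verdict.min_calls,
    }
    return out


def haplotype_clone_set(clone_set, min_informative: int = 1):
    """Align, assign and tabulate one clone set; returns (matrix, QC dict)."""
    info = haplotyping.classify_snp_informativeness(
        clone_set.allele_definitions, region_start=clone_set.start,
        region_length=len(clone_set.reference))
    aligned, assignments = {}, {}
    n_unaligned = 0
    for clone in clone_set.clones:
        try:
            al = haplotyping.align_clone_bisulfite(clone.sequence,
                                                   clone_set.reference)
        except haplotyping.UnalignableCloneError:
            n_unaligned += 1
            continue
        aligned[clone.clone_id] = al
        assignments[clone.clone_id] = haplotyping.assign_clone_allele(
            al, info, min_informative=min_informative)
    mat = haplotyping.allele_methylation_matrix(
        aligned, assignments, clone_set.allele_definitions, clone_set.reference,
        region_start=clone_set.start, n_unaligned=n_unaligned)
    qc = {
        "n_clones": len(clone_set.clones),
        "n_unaligned": n_unaligned,
        "n_ambiguous": mat.n_ambiguous,
        "n_assigned": {a: int(n) for a, n in mat.n_clones.items()},
    }
    return mat, qc
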