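"""End-to-end orchestration over plain-text stage outputs.

Each stage reads only its predecessor's files from the run directory and
writes TSV/BED/JSON outputs plus a manifest (config hash, seed, package
version, output checksums), so any stage can be re-run in isolation.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    introns_of,
    read_bed,
    read_gtf,
    write_bed,
    write_gene_table,
    write_gtf,
)
from .conversions import ConversionTable, aggregate, build_snp_mask, mask_to_bed
from .diffkin import test_differential, test_differential_lrt
from .enrichment import CountMatrix, overlap_summary, test_enrichment
from .features import (
    fraction_overlapping,
    intronic_enrichment,
    nearest_peak_distance,
    signal_matrix,
    state_group_percentages,
)
from .kinetics import (
    KineticsError,
    RateParams,
    estimate_background,
    estimate_pc_global,
    fit_gene_kinetics,
)
from .simulate import (
    COMPARTMENTS,
    DEFAULT_CONSOLIDATION,
    ClassParams,
    CompartmentSimulation,
    SimulationConfig,
    default_classes,
    read_truth,
)


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message lists every violation."""


DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "simulate": {
        "reads_per_library": 50_000,
        "replicates": 3,
        "pulse_hours": 4.0,
        "p_e": 0.001,
        "p_c": 0.05,
        "n_genes": {"polycomb_adjacent": 40, "speckle": 40, "background": 120},
        "n_snps": 30,
        "n_T_per_read": 20,
        "read_length": 100,
    },
    "kinetics": {
        "min_reads": 50,
        "estimate_rates": True,
        "pool_replicates": True,
    },
    "diffkin": {
        "method": "lrt",  # "lrt" (histogram likelihood-ratio) or "wald"
        "ratio_threshold": 2.0,
        "alpha": 0.05,
        "strict_persistent": False,
        "log2_scale": False,
    },
    "enrichment": {
        "fold_threshold": 2.0,
        "alpha": 0.05,
        "base_mean_floor": 5.0,
        "log2_scale": False,
    },
    "features": {
        "bins": 10,
        "upstream_bp": 500,
        "intron_fold_threshold": 2.0,
        "intron_pseudocount": 1.0,
    },
}

_SIMULATE_PASSTHROUGH = {
    "reads_per_library", "replicates", "pulse_hours", "p_e", "p_c",
    "n_snps", "n_T_per_read", "read_length", "n_chromosomes",
    "peak_median_distance", "peak_overlap_fraction", "peak_width",
    "p_speckle_adjacent", "genome_size",
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys.

    All violations are collected and reported together.
    """
    errors: list[str] = []
    merged = {sec: dict(vals) for sec, vals in DEFAULT_CONFIG.items()}
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping of sections")
    for section, values in config.items():
        if section not in merged:
            errors.append(f"unknown section {section!r}")
            continue
        if not isinstance(values, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, val in values.items():
            if key not in merged[section]:
                errors.append(f"unknown key {section}.{key}")
            else:
                merged[section][key] = val
    sim = merged["simulate"]
    if not (0 <= sim["p_e"] < sim["p_c"] <= 1):
        errors.append(
            f"simulate.p_e ({sim['p_e']}) must be < simulate.p_c "
            f"({sim['p_c']}), both in [0, 1]"
        )
    if sim["pulse_hours"] <= 0:
        errors.append("simulate.pulse_hours must be > 0")
    if errors:
        raise ConfigError("; ".join(errors))
    return merged


def build_simulation_config(sim_section: dict, seed: int) -> SimulationConfig:
    classes = default_classes()
    for cls_name, n in sim_section.get("n_genes", {}).items():
        if cls_name not in classes:
            raise ConfigError(f"unknown gene class {cls_name!r} in simulate.n_genes")
        classes[cls_name].n_genes = int(n)
    kwargs = {
        k: v
        for k, v in sim_section.items()
        if k in _SIMULATE_PASSTHROUGH and v is not None
    }
    return SimulationConfig(classes=classes, seed=seed, **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(
    outdir: Path, stage: str, config: dict, seed: int, outputs: list[Path],
    extra: dict | None = None,
) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _libraries(replicates: int) -> list[tuple[str, int]]:
    libs = [(lib, r) for lib in ("igg", *COMPARTMENTS) for r in range(1, replicates + 1)]
    libs.append(("unlabeled", 1))
    return libs


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: dict, outdir: str | Path, seed: int) -> list[Path]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    (outdir / "sam").mkdir(parents=True, exist_ok=True)
    sim_cfg = build_simulation_config(cfg["simulate"], seed)
    sim = CompartmentSimulation(sim_cfg)

    outputs: list[Path] = []
    write_gtf(sim.genes, outdir / "genes.gtf")
    write_gene_table(sim.genes, outdir / "genes.tsv")
    write_bed(sim.peaks, outdir / "peaks.bed")
    write_bed(sim.states, outdir / "spin_states.bed")
    sim.write_truth(outdir / "truth.tsv")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in sim.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    outputs += [
        outdir / n
        for n in ("genes.gtf", "genes.tsv", "peaks.bed", "spin_states.bed",
                  "truth.tsv", "chrom_sizes.tsv")
    ]
    for lib, rep in _libraries(sim_cfg.replicates):
        path = outdir / "sam" / f"{lib}_rep{rep}.sam"
        sim.write_sam(lib, rep, path)
        outputs.append(path)
    _write_manifest(outdir, "simulate", cfg, seed, outputs)
    return outputs


def run_count(config: dict, outdir: str | Path, seed: int) -> list[Path]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    genes = read_gtf(outdir / "genes.gtf")
    sam_dir = outdir / "sam"
    sams = sorted(sam_dir.glob("*.sam"))
    if not sams:
        raise FileNotFoundError(f"no SAM files under {sam_dir}")

    control = sam_dir / "unlabeled_rep1.sam"
    mask = build_snp_mask(control) if control.exists() else set()
    write_bed(mask_to_bed(mask), outdir / "snp_mask.bed")

    obs_frames = []
    stats_by_lib = {}
    for path in sams:
        stem = path.stem  # e.g. igg_rep2
        lib, rep_s = stem.rsplit("_rep", maxsplit=1)
        obs, stats = aggregate(
            path, genes, sample=lib, replicate=int(rep_s), mask=mask,
            keep_positions=True,
        )
        obs_frames.append(obs)
        stats_by_lib[stem] = {
            "assigned": stats.assigned,
            "no_gene": stats.no_gene,
            "ambiguous": stats.ambiguous,
        }
    obs = pd.concat(obs_frames, ignore_index=True)
    table = ConversionTable.from_observations(
        obs[["gene_id", "sample", "replicate", "n_T", "k"]]
    )
    table.to_tsv(outdir / "conversions.tsv")
    obs[["gene_id", "sample", "replicate", "chrom", "pos5"]].to_csv(
        outdir / "read_loci.tsv", sep="\t", index=False
    )

    counts = (
        obs.groupby(["gene_id", "sample", "replicate"]).size().rename("n").reset_index()
    )
    counts["column"] = counts["sample"] + "_rep" + counts["replicate"].astype(str)
    wide = (
        counts.pivot_table(index="gene_id", columns="column", values="n", fill_value=0)
        .astype(int)
        .sort_index()
    )
    wide.to_csv(outdir / "gene_counts.tsv", sep="\t")

    outputs = [
        outdir / n
        for n in ("snp_mask.bed", "conversions.tsv", "read_loci.tsv", "gene_counts.tsv")
    ]
    _write_manifest(outdir, "count", cfg, seed, outputs, {"assignment": stats_by_lib})
    return outputs


def run_kinetics(config: dict, outdir: str | Path, seed: int) -> list[Path]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    kcfg = cfg["kinetics"]
    table = ConversionTable.read_tsv(outdir / "conversions.tsv")
    t_hours = float(cfg["simulate"]["pulse_hours"])

    p_e_cfg = float(cfg["simulate"]["p_e"])
    p_c_cfg = float(cfg["simulate"]["p_c"])
    if kcfg["estimate_rates"] and "unlabeled" in table.samples:
        p_e = estimate_background(table.subset("unlabeled"))
        p_e_source = "estimated_from_unlabeled"
    else:
        p_e = p_e_cfg
        p_e_source = "config"
    if kcfg["estimate_rates"]:
        try:
            p_c = estimate_pc_global(
                table.subset("igg"), p_e, min_reads=int(kcfg["min_reads"])
            )
            p_c_source = "em_pooled_igg"
        except KineticsError:
            p_c, p_c_source = p_c_cfg, "config_fallback"
    else:
        p_c, p_c_source = p_c_cfg, "config"
    params = RateParams(p_e, p_c, source=f"p_e:{p_e_source},p_c:{p_c_source}")
    with open(outdir / "rates.json", "w") as fh:
        json.dump(
            {"p_e": p_e, "p_c": p_c, "p_e_source": p_e_source, "p_c_source": p_c_source},
            fh, indent=2,
        )
        fh.write("\n")

    outputs = [outdir / "rates.json"]
    for lib in ("igg", *COMPARTMENTS):
        if lib not in table.samples:
            continue
        est = fit_gene_kinetics(
            table, lib, params, t_hours,
            min_reads=int(kcfg["min_reads"]),
            pool_replicates=bool(kcfg["pool_replicates"]),
        )
        path = outdir / f"kinetics_{lib}.tsv"
        est.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    _write_manifest(outdir, "kinetics", cfg, seed, outputs)
    return outputs


def run_diffkin(config: dict, outdir: str | Path, seed: int) -> list[Path]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    dcfg = cfg["diffkin"]
    if dcfg["method"] not in ("lrt", "wald"):
        raise ConfigError(f"diffkin.method must be 'lrt' or 'wald', got {dcfg['method']!r}")
    thresholds = dict(
        ratio_threshold=float(dcfg["ratio_threshold"]),
        alpha=float(dcfg["alpha"]),
        strict_persistent=bool(dcfg["strict_persistent"]),
        log2_scale=bool(dcfg["log2_scale"]),
    )
    glob = pd.read_csv(outdir / "kinetics_igg.tsv", sep="\t")
    if dcfg["method"] == "lrt":
        table = ConversionTable.read_tsv(outdir / "conversions.tsv")
        with open(outdir / "rates.json") as fh:
            rates = json.load(fh)
        params = RateParams(rates["p_e"], rates["p_c"])
        t_hours = float(cfg["simulate"]["pulse_hours"])
        min_reads = int(cfg["kinetics"]["min_reads"])
    outputs = []
    for comp in COMPARTMENTS:
        path = outdir / f"kinetics_{comp}.tsv"
        if not path.exists():
            continue
        if dcfg["method"] == "lrt":
            res = test_differential_lrt(
                table, comp, "igg", params, t_hours, min_reads=min_reads, **thresholds
            )
        else:
            loc = pd.read_csv(path, sep="\t")
            res = test_differential(loc, glob, **thresholds)
        out_path = outdir / f"diffkin_{comp}.tsv"
        res.to_csv(out_path, sep="\t", index=False)
        outputs.append(out_path)
    _write_manifest(outdir, "diffkin", cfg, seed, outputs)
    return outputs


def run_enrich(config: dict, outdir: str | Path, seed: int) -> list[Path]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    ecfg = cfg["enrichment"]
    wide = pd.read_csv(outdir / "gene_counts.tsv", sep="\t", index_col="gene_id")
    outputs = []
    enriched_sets: dict[str, set[str]] = {}
    for comp in COMPARTMENTS:
        t_cols = [c for c in wide.columns if c.startswith(f"{comp}_rep")]
        c_cols = [c for c in wide.columns if c.startswith("igg_rep")]
        if len(t_cols) < 2 or len(c_cols) < 2:
            continue
        matrix = CountMatrix(
            wide[t_cols + c_cols],
            {**{c: "target" for c in t_cols}, **{c: "control" for c in c_cols}},
        )
        res = test_enrichment(
            matrix,
            fold_threshold=float(ecfg["fold_threshold"]),
            alpha=float(ecfg["alpha"]),
            base_mean_floor=float(ecfg["base_mean_floor"]),
            log2_scale=bool(ecfg["log2_scale"]),
        )
        path = outdir / f"enrichment_{comp}.tsv"
        res.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        enriched_sets[comp] = set(res.loc[res["enriched"], "gene_id"])
    if len(enriched_sets) == 2:
        a, b = (enriched_sets[c] for c in COMPARTMENTS)
        shared, percent = overlap_summary(len(a), len(b), len(a & b))
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(
                {
                    "n_" + COMPARTMENTS[0]: len(a),
                    "n_" + COMPARTMENTS[1]: len(b),
                    "shared": shared,
                    "percent_of_union": percent,
                },
                fh, indent=2,
            )
            fh.write("\n")
        outputs.append(outdir / "overlap.json")
    _write_manifest(outdir, "enrich", cfg, seed, outputs)
    return outputs


def run_features(config: dict, outdir: str | Path, seed: int) -> list[Path]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    fcfg = cfg["features"]
    genes = {g.gene_id: g for g in read_gtf(outdir / "genes.gtf")}
    peaks = read_bed(outdir / "peaks.bed")
    states = read_bed(outdir / "spin_states.bed")
    loci = pd.read_csv(outdir / "read_loci.tsv", sep="\t")

    summary: dict[str, Any] = {}
    outputs: list[Path] = []

    enr_path = outdir / f"enrichment_{COMPARTMENTS[0]}.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        sel = [genes[g] for g in enr.loc[enr["enriched"], "gene_id"] if g in genes]
        dists = [nearest_peak_distance(g, peaks) for g in sel]
        dists = [d for d in dists if not np.isnan(d)]
        summary["polycomb_enriched_genes"] = len(sel)
        summary["median_peak_distance_bp"] = float(np.median(dists)) if dists else None
        summary["percent_overlapping_peak"] = fraction_overlapping(sel, peaks)

    enr_path = outdir / f"enrichment_{COMPARTMENTS[1]}.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        sel = [genes[g] for g in enr.loc[enr["enriched"], "gene_id"] if g in genes]
        summary["speckle_enriched_genes"] = len(sel)
        pct = state_group_percentages(sel, states, DEFAULT_CONSOLIDATION)
        summary["state_group_percent"] = {k: round(v, 1) for k, v in pct.items()}

        introns, intron_ids, tes_ivs, tes_ids = [], [], [], []
        for g in sel:
            for j, iv in enumerate(introns_of(g)):
                introns.append(iv)
                intron_ids.append(f"{g.gene_id}.intron{j + 1}")
            tes_ivs.append(g.span)
            tes_ids.append(g.gene_id)
        target_reads = loci[loci["sample"] == COMPARTMENTS[1]].rename(columns={"pos5": "pos5"})
        control_reads = loci[loci["sample"] == "igg"]
        bins = int(fcfg["bins"])
        if introns:
            t_mat, _ = signal_matrix(
                target_reads, introns, "scaled_body", bins=bins, feature_ids=intron_ids
            )
            c_mat, _ = signal_matrix(
                control_reads, introns, "scaled_body", bins=bins, feature_ids=intron_ids
            )
            res, frac = intronic_enrichment(
                t_mat, c_mat,
                fold_threshold=float(fcfg["intron_fold_threshold"]),
                pseudocount=float(fcfg["intron_pseudocount"]),
            )
            res.insert(0, "gene_id", [i.rsplit(".intron", 1)[0] for i in res.index])
            res.to_csv(outdir / "intron_enrichment_sc35.tsv", sep="\t", index_label="intron_id")
            outputs.append(outdir / "intron_enrichment_sc35.tsv")
            summary["percent_introns_enriched"] = round(frac, 1)
        if tes_ivs:
            t_tes, _ = signal_matrix(
                target_reads, tes_ivs, "fixed_upstream",
                bins=bins, upstream_bp=int(fcfg["upstream_bp"]), feature_ids=tes_ids,
            )
            t_tes.to_csv(outdir / "tes_signal_sc35.tsv", sep="\t", index_label="gene_id")
            outputs.append(outdir / "tes_signal_sc35.tsv")

    with open(outdir / "features_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append(outdir / "features_summary.json")
    _write_manifest(outdir, "features", cfg, seed, outputs)
    return outputs


def evaluate_against_truth(outdir: str | Path) -> dict:
    """Compare pipeline calls with the simulator's truth table.

    Reports, per compartment, the dynamics-label accuracy over truly
    enriched genes that were tested, and the enrichment-call sensitivity.
    """
    outdir = Path(outdir)
    truth = read_truth(outdir / "truth.tsv")
    report: dict[str, Any] = {}
    accs = []
    for comp in COMPARTMENTS:
        dk_path = outdir / f"diffkin_{comp}.tsv"
        if not dk_path.exists():
            continue
        calls = pd.read_csv(dk_path, sep="\t")
        sub = truth[truth[f"enriched_{comp}"]].merge(calls, on="gene_id", how="left")
        tested = sub[sub["label"].notna() & (sub["label"] != "not_tested")]
        if len(tested):
            acc = float((tested["label"] == tested[f"label_{comp}"]).mean())
            report[f"label_accuracy_{comp}"] = acc
            report[f"n_labeled_{comp}"] = int(len(tested))
            accs.append((acc, len(tested)))
        en_path = outdir / f"enrichment_{comp}.tsv"
        if en_path.exists():
            enr = pd.read_csv(en_path, sep="\t")
            merged = truth.merge(enr, on="gene_id", how="left")
            truly = merged[f"enriched_{comp}"].astype(bool)
            called = merged["enriched"].fillna(False).astype(bool)
            sens = float(called[truly].mean()) if truly.any() else float("nan")
            fpr = float(called[~truly].mean())
            report[f"enrichment_sensitivity_{comp}"] = sens
            report[f"enrichment_fpr_{comp}"] = fpr
    if accs:
        total = sum(n for _, n in accs)
        report["label_accuracy_overall"] = sum(a * n for a, n in accs) / total
        report["n_labeled_overall"] = total
    return report


def run_all(config: dict, outdir: str | Path, seed: int) -> dict:
    """simulate -> count -> kinetics -> diffkin -> enrich -> features."""
    outdir = Path(outdir)
    run_simulate(config, outdir, seed)
    run_count(config, outdir, seed)
    run_kinetics(config, outdir, seed)
    run_diffkin(config, outdir, seed)
    run_enrich(config, outdir, seed)
    run_features(config, outdir, seed)
    report = evaluate_against_truth(outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
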