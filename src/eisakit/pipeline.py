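"""Config-driven orchestration of the analysis stages.

A YAML config selects stages and parameters; ``run_pipeline`` executes the
stages in dependency order (simulate -> count -> de -> eisa -> enrich, plus
the independent metabolites and patients stages), writes every cross-stage
artifact to disk as TSV/GTF/BED/JSON, and records a JSON manifest with the
config hash, per-stage outputs and SHA-256 checksums.  Reruns with an
identical config are bit-identical for all deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import de, eisa, enrichment, metabolites, simulate
from .counting import (
    build_region_index,
    count_samples,
    read_counts_table,
    write_count_report,
    write_counts_table,
)
from .genome import GeneModelSet, read_bed, write_bed

logger = logging.getLogger("eisakit.pipeline")

__version__ = "0.1.0"


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


class StageError(RuntimeError):
    pass


STAGES = ["simulate", "count", "de", "eisa", "enrich", "metabolites", "patients"]

_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {
        "n_genes": 300,
        "n_replicates": 3,
        "n_txn_up": 20,
        "n_txn_down": 20,
        "n_pt": 15,
        "effect_size": 1.0,
        "dispersion": 0.01,
        "base_mean_median": 200.0,
        "intron_fraction": 0.1,
        "read_length": 50,
        "emit_reads": True,
    },
    "count": {"strandedness": "unstranded"},
    "de": {"alpha": 0.01, "lfc_min": 0.25},
    "eisa": {"fdr": 0.05, "lfc": 0.25, "min_intron_mean": 8.0, "pseudocount": 0.5},
    "enrich": {"gmt": None, "min_size": 5, "n_random_sets": 20, "set_size": 25},
    "metabolites": {"n_features": 40, "n_per_group": 5, "n_interaction": 8,
                    "interaction_size": 1.0, "sigma": 0.2, "transform": "log2"},
    "patients": {"n_patients": 5, "n_metabolites": 8, "beta_treatment": 0.5,
                 "sigma_b": 0.5, "sigma_e": 0.25},
}

_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("de", "alpha"): (0.0, 1.0),
    ("de", "lfc_min"): (0.0, np.inf),
    ("eisa", "fdr"): (0.0, 1.0),
    ("eisa", "lfc"): (0.0, np.inf),
    ("eisa", "min_intron_mean"): (0.0, np.inf),
    ("eisa", "pseudocount"): (0.0, np.inf),
    ("simulate", "n_genes"): (1, np.inf),
    ("simulate", "dispersion"): (0.0, np.inf),
    ("simulate", "intron_fraction"): (0.0, 1.0),
    ("metabolites", "sigma"): (0.0, np.inf),
    ("patients", "n_patients"): (2, np.inf),
}


def default_config(out_dir: str, seed: int = 11) -> dict:
    cfg: dict[str, Any] = {"out_dir": str(out_dir), "seed": int(seed),
                           "stages": list(STAGES), "log_level": "INFO"}
    for stage, params in _DEFAULTS.items():
        cfg[stage] = dict(params)
    return cfg


def validate_config(cfg: dict | str | Path) -> dict:
    """Normalize a config mapping or YAML path; all violations at once."""
    if isinstance(cfg, (str, Path)):
        with open(cfg) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    errors: list[str] = []
    known_top = {"out_dir", "seed", "stages", "log_level", "counts_dir", *STAGES}
    for key in cfg:
        if key not in known_top:
            errors.append(f"unknown key {key!r}")
    if "out_dir" not in cfg:
        errors.append("missing required key 'out_dir'")
    norm = default_config(cfg.get("out_dir", "."), int(cfg.get("seed", 11)))
    if "counts_dir" in cfg:
        norm["counts_dir"] = str(cfg["counts_dir"])
    stages = cfg.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        errors.append(f"unknown stage(s) {bad}")
    norm["stages"] = [s for s in stages if s in STAGES]
    if "log_level" in cfg:
        norm["log_level"] = str(cfg["log_level"])
    for stage in STAGES:
        user = cfg.get(stage, {})
        if user is None:
            user = {}
        if not isinstance(user, dict):
            errors.append(f"section {stage!r} must be a mapping")
            continue
        for key, value in user.items():
            if key not in _DEFAULTS[stage]:
                errors.append(f"unknown key {stage}.{key}")
                continue
            norm[stage][key] = value
        for (st, key), (lo, hi) in _RANGES.items():
            if st != stage:
                continue
            v = norm[stage][key]
            if v is not None and not (lo <= float(v) <= hi):
                errors.append(f"{stage}.{key}={v} outside [{lo}, {hi}]")
    gmt = norm["enrich"].get("gmt")
    if gmt is not None and not Path(gmt).exists():
        errors.append(f"enrich.gmt path does not exist: {gmt}")
    if errors:
        raise ConfigError("invalid config: " + "; ".join(errors))
    return norm


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label)


# ---------------------------------------------------------------------------
# stages (each reads its declared inputs from disk and writes its outputs)


def _stage_simulate(cfg: dict, out: Path) -> list[Path]:
    p = cfg["simulate"]
    seed = cfg["seed"]
    models = simulate.generate_genome(p["n_genes"], seed)
    design = simulate.make_rnaseq_design(p["n_replicates"])
    truth = simulate.make_gene_truth(
        models.gene_ids,
        seed,
        base_mean_median=p["base_mean_median"],
        dispersion=p["dispersion"],
        intron_fraction=p["intron_fraction"],
        n_txn_up=p["n_txn_up"],
        n_txn_down=p["n_txn_down"],
        n_pt=p["n_pt"],
        effect_size=p["effect_size"],
    )
    counts, _ = simulate.simulate_counts(models, design, truth, seed)
    outputs = []
    models.to_gtf(out / "annotation.gtf")
    outputs.append(out / "annotation.gtf")
    _write_tsv(design, out / "design.tsv")
    outputs.append(out / "design.tsv")
    _write_tsv(truth, out / "truth_genes.tsv")
    outputs.append(out / "truth_genes.tsv")
    write_counts_table(counts.exonic, out / "counts_exonic_true.tsv")
    write_counts_table(counts.intronic, out / "counts_intronic_true.tsv")
    outputs += [out / "counts_exonic_true.tsv", out / "counts_intronic_true.tsv"]
    if p["emit_reads"]:
        reads, skipped = simulate.simulate_reads(
            counts, models, p["read_length"], seed
        )
        for sample, df in reads.items():
            path = out / f"reads_{sample}.bed"
            write_bed(df, path)
            outputs.append(path)
        (out / "reads_skipped.json").write_text(
            json.dumps(sorted(skipped), indent=0) + "\n"
        )
        outputs.append(out / "reads_skipped.json")
    return outputs


def _stage_count(cfg: dict, out: Path) -> list[Path]:
    models = GeneModelSet.from_gtf(out / "annotation.gtf")
    design = pd.read_csv(out / "design.tsv", sep="\t")
    index = build_region_index(models)
    reads = {}
    for sample in design["sample_id"]:
        path = out / f"reads_{sample}.bed"
        if not path.exists():
            raise DataError(f"missing reads file {path}")
        reads[sample] = read_bed(path)
    matrix = count_samples(reads, index, cfg["count"]["strandedness"])
    write_counts_table(matrix.exonic, out / "counts_exonic.tsv")
    write_counts_table(matrix.intronic, out / "counts_intronic.tsv")
    write_count_report(matrix, out / "count_report.json")
    return [out / "counts_exonic.tsv", out / "counts_intronic.tsv",
            out / "count_report.json"]


def _counts_for_analysis(cfg: dict, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    src = Path(cfg.get("counts_dir", out))
    for stem in ("counts_exonic", "counts_intronic"):
        if not (src / f"{stem}.tsv").exists() and not (
            src / f"{stem}_true.tsv"
        ).exists():
            raise DataError(f"no count tables found under {src}")
    ex = src / "counts_exonic.tsv"
    ex = ex if ex.exists() else src / "counts_exonic_true.tsv"
    inn = src / "counts_intronic.tsv"
    inn = inn if inn.exists() else src / "counts_intronic_true.tsv"
    return read_counts_table(ex), read_counts_table(inn)


def _stage_de(cfg: dict, out: Path) -> list[Path]:
    exonic, _ = _counts_for_analysis(cfg, out)
    design = pd.read_csv(Path(cfg.get("counts_dir", out)) / "design.tsv", sep="\t")
    spec = de.ModelSpec(
        terms=("genotype",), references=(("genotype", "wild_type"),)
    )
    res = de.de_table(exonic, design, spec, test="wald", coef="genotype[mutant]")
    calls = de.call_de(res, cfg["de"]["alpha"], cfg["de"]["lfc_min"])
    _write_tsv(res, out / "de_results.tsv", index_label="gene_id")
    (out / "de_calls.json").write_text(json.dumps(calls, indent=2) + "\n")
    return [out / "de_results.tsv", out / "de_calls.json"]


def _stage_eisa(cfg: dict, out: Path) -> list[Path]:
    exonic, intronic = _counts_for_analysis(cfg, out)
    design = pd.read_csv(Path(cfg.get("counts_dir", out)) / "design.tsv", sep="\t")
    p = cfg["eisa"]
    res = eisa.eisa_fit(
        exonic, intronic, design,
        min_intron_mean=p["min_intron_mean"], pseudocount=p["pseudocount"],
    )
    res["class"] = eisa.classify_regulation(res, p["fdr"], p["lfc"])
    _write_tsv(res, out / "eisa_results.tsv", index_label="gene_id")
    _write_tsv(
        eisa.scatter_data(res, p["fdr"], p["lfc"]),
        out / "eisa_scatter.tsv",
        index_label="gene_id",
    )
    return [out / "eisa_results.tsv", out / "eisa_scatter.tsv"]


def _stage_enrich(cfg: dict, out: Path) -> list[Path]:
    de_path = out / "de_results.tsv"
    if not de_path.exists():
        raise DataError("enrich stage needs de_results.tsv; run the de stage first")
    res = pd.read_csv(de_path, sep="\t", index_col="gene_id")
    statistic = res["stat"].dropna()
    p = cfg["enrich"]
    if p["gmt"]:
        sets = enrichment.read_gmt(p["gmt"])
    else:
        rng = simulate.stage_rng(cfg["seed"], "enrich_sets")
        genes = list(statistic.index)
        sets = {}
        # one set enriched in the strongest signals, the rest random
        top = statistic.abs().sort_values(ascending=False).index[: p["set_size"]]
        sets["top_signal"] = list(top)
        for i in range(p["n_random_sets"]):
            sets[f"random_{i + 1:02d}"] = list(
                rng.choice(genes, size=min(p["set_size"], len(genes)), replace=False)
            )
        enrichment.write_gmt(sets, out / "gene_sets.gmt")
    cam = enrichment.camera_test(statistic, sets, min_size=p["min_size"])
    _write_tsv(cam, out / "enrichment.tsv", index_label="set")
    barcodes = {
        name: enrichment.barcode_data(statistic, members)
        for name, members in sets.items()
        if len([g for g in members if g in statistic.index]) >= p["min_size"]
    }
    (out / "barcodes.json").write_text(
        json.dumps(barcodes, indent=None, sort_keys=True) + "\n"
    )
    outputs = [out / "enrichment.tsv", out / "barcodes.json"]
    if not p["gmt"]:
        outputs.append(out / "gene_sets.gmt")
    return outputs


def _stage_metabolites(cfg: dict, out: Path) -> list[Path]:
    p = cfg["metabolites"]
    design = simulate.make_metabolite_design(p["n_per_group"])
    truth = simulate.make_metabolite_truth(
        [f"met_{i + 1:03d}" for i in range(p["n_features"])],
        cfg["seed"],
        sigma=p["sigma"],
        n_interaction=p["n_interaction"],
        interaction_size=p["interaction_size"],
    )
    panel = simulate.simulate_metabolites(design, truth, cfg["seed"])
    transformed = metabolites.transform_panel(panel, p["transform"])
    fits = metabolites.fit_interaction_lm(
        transformed, design["genotype"], design["treatment"]
    )
    pca = metabolites.pca_scores(transformed)
    _write_tsv(truth, out / "truth_metabolites.tsv")
    _write_tsv(panel, out / "metabolite_panel.tsv", index_label="feature")
    _write_tsv(fits, out / "metabolite_fits.tsv", index_label="feature")
    _write_tsv(pca["scores"], out / "pca_scores.tsv", index_label="sample_id")
    _write_tsv(pca["loadings"], out / "pca_loadings.tsv", index_label="feature")
    return [out / "truth_metabolites.tsv", out / "metabolite_panel.tsv",
            out / "metabolite_fits.tsv", out / "pca_scores.tsv",
            out / "pca_loadings.tsv"]


def _stage_patients(cfg: dict, out: Path) -> list[Path]:
    p = cfg["patients"]
    truth = simulate.make_patient_truth(
        [f"aa_{i + 1:02d}" for i in range(p["n_metabolites"])],
        cfg["seed"],
        beta_treatment=p["beta_treatment"],
        sigma_b=p["sigma_b"],
        sigma_e=p["sigma_e"],
    )
    panel = simulate.simulate_patients(p["n_patients"], truth, cfg["seed"])
    fits = metabolites.patient_panel_lmm(panel, value_col="value")
    _write_tsv(truth, out / "truth_patients.tsv")
    _write_tsv(panel, out / "patient_panel.tsv")
    _write_tsv(fits, out / "patient_lmm.tsv", index_label="metabolite")
    return [out / "truth_patients.tsv", out / "patient_panel.tsv",
            out / "patient_lmm.tsv"]


# inputs each stage needs on disk, keyed by the stage that produces them;
# only checked when the producer is not scheduled earlier in the same run
_REQUIRES: dict[str, tuple[str, list[str]]] = {
    "count": ("simulate", ["annotation.gtf", "design.tsv"]),
    "de": ("count", ["design.tsv"]),
    "eisa": ("count", ["design.tsv"]),
    "enrich": ("de", ["de_results.tsv"]),
}


def _preflight(cfg: dict, out: Path, todo: list[str]) -> None:
    missing: list[str] = []
    for i, stage in enumerate(todo):
        if stage not in _REQUIRES:
            continue
        producer, files = _REQUIRES[stage]
        if producer in todo[:i] or (producer == "count" and "simulate" in todo[:i]):
            continue
        src = Path(cfg.get("counts_dir", out)) if stage in {"de", "eisa"} else out
        for f in files:
            if not (src / f).exists():
                missing.append(f"{stage}: {src / f}")
        if stage == "count":
            design_path = out / "design.tsv"
            if design_path.exists():
                for sample in pd.read_csv(design_path, sep="\t")["sample_id"]:
                    if not (out / f"reads_{sample}.bed").exists():
                        missing.append(f"count: {out / f'reads_{sample}.bed'}")
    if missing:
        raise DataError(
            "missing input file(s) before any stage ran: " + "; ".join(missing)
        )


_STAGE_FUNCS: dict[str, Callable[[dict, Path], list[Path]]] = {
    "simulate": _stage_simulate,
    "count": _stage_count,
    "de": _stage_de,
    "eisa": _stage_eisa,
    "enrich": _stage_enrich,
    "metabolites": _stage_metabolites,
    "patients": _stage_patients,
}


def run_pipeline(cfg: dict, stages: list[str] | None = None) -> dict:
    """Run the configured stages in order; returns and writes the manifest."""
    cfg = validate_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    todo = stages if stages is not None else cfg["stages"]
    bad = [s for s in todo if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s) {bad}")
    todo = [s for s in STAGES if s in todo]
    _preflight(cfg, out, todo)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
    }
    try:
        for stage in todo:
            t0 = time.perf_counter()
            logger.info("stage %s: starting", stage)
            try:
                outputs = _STAGE_FUNCS[stage](cfg, out)
            except (ConfigError, DataError):
                raise
            except Exception as exc:  # halt, keep partial manifest
                raise StageError(f"stage {stage!r} failed: {exc}") from exc
            manifest["stages"][stage] = {
                "outputs": {
                    str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
                },
                "wall_seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info(
                "stage %s: done in %.2fs", stage,
                manifest["stages"][stage]["wall_seconds"],
            )
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
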