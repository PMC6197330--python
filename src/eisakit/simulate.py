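"""Synthetic data with known ground truth for every downstream analysis.

The generators emulate the statistical structure the pipeline assumes:

* gene loci with exon/intron structure on a small synthetic genome;
* negative-binomial exonic and intronic counts where a *transcriptional*
  effect (``delta_txn``, log2) shifts both regions and a *post-transcriptional*
  effect (``delta_pt``, log2) shifts exonic counts only — the planted signal
  an exon-intron split analysis is meant to recover;
* uniformly placed fixed-length single-end reads inside exonic or intronic
  regions, so the counting stage can be tested end to end;
* log-normal metabolite panels with genotype x treatment interaction effects
  (2x2 design);
* paired patient panels (each patient sampled on and off treatment) with a
  per-patient random baseline shift.

Every generator returns or consumes an explicit truth table so recovery can
be scored without reaching into generator internals.  All randomness flows
from one integer seed through named child streams (:func:`stage_rng`), so a
stage can be regenerated independently and byte-identically.

Default study conditions: 3 biological replicates per genotype for RNA-seq,
2x2 genotype x treatment with 5 samples per cell for metabolites, and
5 patients sampled in both treatment states for the clinical panel.
Gene-level defaults are a log-normal base mean with median 200 counts,
intronic/exonic coverage ratio 0.1, and NB dispersion alpha = 0.01 (pooled
whole-larvae libraries are highly reproducible, which is what makes small
fold-changes detectable at n = 3).
"""

from __future__ import annotations

import logging
import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GeneModelSet

logger = logging.getLogger(__name__)

GENE_TRUTH_COLUMNS = [
    "gene_id",
    "base_mean",
    "intron_fraction",
    "dispersion",
    "delta_txn",
    "delta_pt",
]


class ParameterError(ValueError):
    """Invalid generator parameters."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child stream for a named stage of the pipeline."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# design tables


def make_rnaseq_design(
    n_replicates: int = 3,
    mutated_gene: str = "fdx1b",
    time: str = "ZT1",
) -> pd.DataFrame:
    """Wild-type vs mutant design, ``n_replicates`` per genotype."""
    rows = []
    for genotype in ("wild_type", "mutant"):
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{mutated_gene}_{genotype}_{time}_r{r}",
                    "genotype": genotype,
                    "treatment": "CTR",
                    "mutated_gene": mutated_gene,
                    "time": time,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows)


def make_cross_model_design(
    n_replicates: int = 3,
    times: Sequence[str] = ("ZT1", "ZT13"),
    lines: Sequence[str] = ("fdx1b", "rx3"),
) -> pd.DataFrame:
    """Two mutant lines x phenotype x time design for the interaction model."""
    frames = []
    for line in lines:
        for t in times:
            frames.append(make_rnaseq_design(n_replicates, mutated_gene=line, time=t))
    return pd.concat(frames, ignore_index=True)


def make_metabolite_design(n_per_group: int = 5) -> pd.DataFrame:
    rows = []
    for genotype in ("wild_type", "mutant"):
        for treatment in ("CTR", "DEX"):
            for r in range(1, n_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{treatment}_r{r}",
                        "genotype": genotype,
                        "treatment": treatment,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame) -> None:
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParameterError(f"duplicate sample_id {dup!r} in design")


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(
    n_genes: int,
    seed: int,
    n_chroms: int = 4,
    exon_count_range: tuple[int, int] = (1, 6),
    exon_length_range: tuple[int, int] = (100, 400),
    intron_length_range: tuple[int, int] = (200, 1500),
    intergenic_range: tuple[int, int] = (500, 2000),
) -> GeneModelSet:
    """Lay out ``n_genes`` non-overlapping loci across ``n_chroms`` chromosomes.

    Genes are tiled left to right with random intergenic gaps, so genes never
    overlap; each gene has between ``exon_count_range[0]`` and
    ``exon_count_range[1]`` exons separated by introns.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    for name, (lo, hi) in (
        ("exon_count_range", exon_count_range),
        ("exon_length_range", exon_length_range),
        ("intron_length_range", intron_length_range),
        ("intergenic_range", intergenic_range),
    ):
        if lo < 1 or hi < lo:
            raise ParameterError(f"invalid {name}: ({lo}, {hi})")
    rng = stage_rng(seed, "genome")
    cursors = {f"chr{i + 1}": 0 for i in range(n_chroms)}
    chrom_names = list(cursors)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        chrom = chrom_names[i % n_chroms]
        start = cursors[chrom] + int(rng.integers(*intergenic_range, endpoint=True))
        n_exons = int(rng.integers(*exon_count_range, endpoint=True))
        pos = start
        exons = []
        for j in range(n_exons):
            if j > 0:
                pos += int(rng.integers(*intron_length_range, endpoint=True))
            length = int(rng.integers(*exon_length_range, endpoint=True))
            exons.append((pos, pos + length))
            pos = pos + length
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=exons[-1][1],
                exons=tuple(exons),
            )
        )
        cursors[chrom] = exons[-1][1]
    return GeneModelSet(genes=genes)


# ---------------------------------------------------------------------------
# gene-level truth and counts


def make_gene_truth(
    gene_ids: Sequence[str],
    seed: int,
    base_mean_median: float = 200.0,
    base_mean_sigma: float = 1.0,
    dispersion: float = 0.01,
    intron_fraction: float = 0.1,
    n_txn_up: int = 0,
    n_txn_down: int = 0,
    n_pt: int = 0,
    effect_size: float = 1.0,
) -> pd.DataFrame:
    """Per-gene ground truth with optional planted effects.

    ``n_txn_up``/``n_txn_down`` genes get ``delta_txn = +/-effect_size``
    (shared by both regions); the next ``n_pt`` genes get
    ``delta_pt = effect_size`` (exonic only).  Planted groups are disjoint.
    """
    if dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    if not 0 < intron_fraction <= 1:
        raise ParameterError("intron_fraction must be in (0, 1]")
    n = len(gene_ids)
    if n_txn_up + n_txn_down + n_pt > n:
        raise ParameterError("more planted effects than genes")
    rng = stage_rng(seed, "gene_truth")
    base_mean = np.exp(
        np.log(base_mean_median) + base_mean_sigma * rng.standard_normal(n)
    )
    delta_txn = np.zeros(n)
    delta_pt = np.zeros(n)
    order = rng.permutation(n)
    up = order[:n_txn_up]
    down = order[n_txn_up : n_txn_up + n_txn_down]
    pt = order[n_txn_up + n_txn_down : n_txn_up + n_txn_down + n_pt]
    delta_txn[up] = effect_size
    delta_txn[down] = -effect_size
    delta_pt[pt] = effect_size
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "base_mean": base_mean,
            "intron_fraction": intron_fraction,
            "dispersion": dispersion,
            "delta_txn": delta_txn,
            "delta_pt": delta_pt,
        }
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    models: GeneModelSet | Sequence[str],
    design: pd.DataFrame,
    truth: pd.DataFrame,
    seed: int,
    size_factors: Sequence[float] | None = None,
):
    """Simulate exonic and intronic count matrices from gene-level truth.

    Exonic mean for gene g, sample j:
        ``sf_j * base_mean_g * 2**((delta_txn_g + delta_pt_g) * x_j)``
    Intronic mean:
        ``sf_j * base_mean_g * intron_fraction_g * 2**(delta_txn_g * x_j)``
    with ``x_j = 1`` for mutant samples.  Single-exon genes have no intronic
    region and receive intronic count 0.

    Returns ``(RegionCountMatrix, truth)``.
    """
    from .counting import RegionCountMatrix

    validate_design(design)
    if isinstance(models, GeneModelSet):
        gene_ids = models.gene_ids
        single_exon = {g.gene_id for g in models if len(g.exonic_union) == 1
                       and not g.intron_intervals}
    else:
        gene_ids = list(models)
        single_exon = set()
    t = truth.set_index("gene_id")
    missing = [g for g in gene_ids if g not in t.index]
    if missing:
        raise ParameterError(f"truth table missing gene(s): {missing[:5]}")
    t = t.loc[gene_ids]
    samples = design["sample_id"].tolist()
    sf = (
        np.ones(len(samples))
        if size_factors is None
        else np.asarray(size_factors, dtype=float)
    )
    if (sf <= 0).any():
        raise ParameterError("size_factors must be positive")
    x = (design["genotype"].to_numpy() == "mutant").astype(float)

    base = t["base_mean"].to_numpy()[:, None]
    dtxn = t["delta_txn"].to_numpy()[:, None]
    dpt = t["delta_pt"].to_numpy()[:, None]
    ifrac = t["intron_fraction"].to_numpy()[:, None]
    alpha = np.broadcast_to(
        t["dispersion"].to_numpy()[:, None], (len(gene_ids), len(samples))
    )

    mu_ex = sf[None, :] * base * 2.0 ** ((dtxn + dpt) * x[None, :])
    mu_in = sf[None, :] * base * ifrac * 2.0 ** (dtxn * x[None, :])

    rng = stage_rng(seed, "counts")
    exonic = _nb_draw(rng, mu_ex, alpha)
    intronic = _nb_draw(rng, mu_in, alpha)
    if single_exon:
        mask = np.array([g in single_exon for g in gene_ids])
        intronic[mask, :] = 0

    exonic_df = pd.DataFrame(exonic, index=gene_ids, columns=samples)
    intronic_df = pd.DataFrame(intronic, index=gene_ids, columns=samples)
    return RegionCountMatrix(exonic=exonic_df, intronic=intronic_df), truth


# ---------------------------------------------------------------------------
# read placement


def _placeable(segments, read_length: int):
    """Segments that can fully contain a read, with position weights."""
    segs = [(s, e) for s, e in segments if e - s >= read_length]
    weights = np.array([e - s - read_length + 1 for s, e in segs], dtype=float)
    return segs, weights


def simulate_reads(
    counts,
    models: GeneModelSet,
    read_length: int,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Place ``count`` uniform reads fully inside each gene's regions.

    Exonic reads land entirely within one exon of the gene's exonic union
    (no junction-spanning by default); intronic reads land entirely within
    one intron.  Returns per-sample BED6 frames (read name carries the
    originating gene and region as a truth tag, score 255 marks uniquely
    mapped) plus the list of skipped ``gene:region`` targets whose every
    segment is shorter than the read.
    """
    rng = stage_rng(seed, "reads")
    skipped: list[str] = []
    per_sample: dict[str, pd.DataFrame] = {}
    gene_segments = {}
    for g in models:
        gene_segments[g.gene_id] = {
            "exonic": _placeable(g.exonic_union, read_length),
            "intronic": _placeable(g.intron_intervals, read_length),
        }
    skip_logged: set[str] = set()
    for sample in counts.exonic.columns:
        rows = []
        for kind, mat in (("exonic", counts.exonic), ("intronic", counts.intronic)):
            col = mat[sample]
            for g in models:
                n = int(col[g.gene_id])
                if n < 0:
                    raise ParameterError("counts must be nonnegative")
                if n == 0:
                    continue
                segs, weights = gene_segments[g.gene_id][kind]
                if not segs:
                    tag = f"{g.gene_id}:{kind}"
                    if tag not in skip_logged:
                        logger.warning(
                            "gene %s: no %s segment >= read length %d; skipped",
                            g.gene_id, kind, read_length,
                        )
                        skip_logged.add(tag)
                        skipped.append(tag)
                    continue
                seg_idx = rng.choice(len(segs), size=n, p=weights / weights.sum())
                for i, si in enumerate(seg_idx):
                    s0, e0 = segs[si]
                    start = s0 + int(rng.integers(0, e0 - s0 - read_length + 1))
                    rows.append(
                        (
                            g.chrom,
                            start,
                            start + read_length,
                            f"{g.gene_id}|{kind}|{sample}|{i}",
                            255,
                            g.strand,
                        )
                    )
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )
        per_sample[sample] = df.sort_values(
            ["chrom", "start", "end", "name"], kind="mergesort"
        ).reset_index(drop=True)
    return per_sample, skipped


# ---------------------------------------------------------------------------
# metabolite panels


def make_metabolite_truth(
    features: Sequence[str],
    seed: int,
    beta0_range: tuple[float, float] = (4.0, 10.0),
    sigma: float = 0.2,
    n_interaction: int = 0,
    interaction_size: float = 1.0,
    n_genotype: int = 0,
    genotype_size: float = 1.0,
) -> pd.DataFrame:
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    rng = stage_rng(seed, "metabolite_truth")
    n = len(features)
    beta0 = rng.uniform(*beta0_range, size=n)
    beta_g = np.zeros(n)
    beta_t = np.zeros(n)
    beta_i = np.zeros(n)
    order = rng.permutation(n)
    beta_i[order[:n_interaction]] = interaction_size
    beta_g[order[n_interaction : n_interaction + n_genotype]] = genotype_size
    return pd.DataFrame(
        {
            "feature": list(features),
            "beta0": beta0,
            "beta_genotype": beta_g,
            "beta_treatment": beta_t,
            "beta_interaction": beta_i,
            "sigma": sigma,
        }
    )


def simulate_metabolites(
    design: pd.DataFrame, truth: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Log-normal concentrations: log2 y = b0 + bg*g + bt*t + bi*g*t + noise.

    Returned on the natural (exponentiated) scale, features x samples.
    """
    validate_design(design)
    if (truth["sigma"] < 0).any():
        raise ParameterError("sigma must be >= 0")
    g = (design["genotype"].to_numpy() == "mutant").astype(float)
    t = (design["treatment"].to_numpy() == "DEX").astype(float)
    rng = stage_rng(seed, "metabolites")
    log2y = (
        truth["beta0"].to_numpy()[:, None]
        + truth["beta_genotype"].to_numpy()[:, None] * g[None, :]
        + truth["beta_treatment"].to_numpy()[:, None] * t[None, :]
        + truth["beta_interaction"].to_numpy()[:, None] * (g * t)[None, :]
        + truth["sigma"].to_numpy()[:, None]
        * rng.standard_normal((len(truth), len(design)))
    )
    return pd.DataFrame(
        2.0 ** log2y, index=truth["feature"].tolist(),
        columns=design["sample_id"].tolist(),
    )


# ---------------------------------------------------------------------------
# patient panels


def make_patient_truth(
    metabolites: Sequence[str],
    seed: int,
    beta0: float = 5.0,
    beta_age: float = 0.02,
    beta_treatment: float = 0.0,
    sigma_b: float = 0.5,
    sigma_e: float = 0.25,
) -> pd.DataFrame:
    if sigma_b < 0 or sigma_e < 0:
        raise ParameterError("sigma_b and sigma_e must be >= 0")
    return pd.DataFrame(
        {
            "metabolite": list(metabolites),
            "beta0": beta0,
            "beta_age": beta_age,
            "beta_treatment": beta_treatment,
            "sigma_b": sigma_b,
            "sigma_e": sigma_e,
        }
    )


def simulate_patients(
    n_patients: int,
    truth: pd.DataFrame,
    seed: int,
    ages: Sequence[float] | None = None,
    treatment_states: Sequence[str] = ("On", "Off"),
) -> pd.DataFrame:
    """Paired patient panel: each patient sampled in every treatment state.

    ``y = beta0 + beta_age*age + beta_treatment*[state == "Off"] + b_i + eps``
    with patient baseline ``b_i ~ N(0, sigma_b^2)`` and residual
    ``eps ~ N(0, sigma_e^2)``.  Long format: one row per
    patient x state x metabolite.
    """
    if n_patients < 2:
        raise ParameterError("n_patients must be >= 2")
    if len(set(treatment_states)) < 2:
        raise ParameterError(
            "need two treatment states per patient; the within-patient "
            "treatment effect is unidentifiable with one state"
        )
    rng = stage_rng(seed, "patients")
    if ages is None:
        ages = np.round(rng.uniform(6.0, 17.0, size=n_patients), 1)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != n_patients:
        raise ParameterError("ages must have one entry per patient")
    rows = []
    for _, m in truth.iterrows():
        b = rng.normal(0.0, m["sigma_b"], size=n_patients)
        for i in range(n_patients):
            for state in treatment_states:
                y = (
                    m["beta0"]
                    + m["beta_age"] * ages[i]
                    + m["beta_treatment"] * (state == "Off")
                    + b[i]
                    + rng.normal(0.0, m["sigma_e"])
                )
                rows.append(
                    {
                        "patient_id": f"P{i + 1:03d}",
                        "age": ages[i],
                        "treatment": state,
                        "metabolite": m["metabolite"],
                        "value": y,
                        "concentration": 2.0 ** y,
                    }
                )
    return pd.DataFrame(rows)
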