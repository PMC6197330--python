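"""Exon-intron split analysis (EISA).

Exonic reads track mature mRNA, intronic reads track pre-mRNA (nascent
transcription).  A gene whose mRNA changes more than its pre-mRNA between
conditions (``delta_exon != delta_intron``) is post-transcriptionally
regulated; equal shifts indicate purely transcriptional control.

Per gene, exonic and intronic counts are stacked into one joint NB GLM

    log mu = b0 + b_cond*x + b_region*r + b_int*(x*r)

with region-specific size-factor offsets (exonic and intronic libraries are
normalized separately), ``x`` the condition indicator and ``r = 1`` for the
exonic rows.  Then ``delta_intron = b_cond``, ``delta_exon = b_cond + b_int``
and the interaction coefficient ``b_int`` *is* ``delta_exon - delta_intron``;
its Wald test propagates the standard errors properly (a two-step
subtraction estimate is also reported for transparency).  The joint model's
dispersion is the maximum of the exon- and intron-level estimates
(conservative).  Genes with mean normalized intronic count below a filter
(default 8; intronic coverage is generally much lower than exonic) are
labelled ``low_intron`` and carry no p-values.

The log2 ratio of normalized exonic to intronic abundance is a proxy for
relative mRNA half-life: a positive mutant-minus-control shift means the
mutant's mRNA is relatively more stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import de
from .de import LN2


def _condition_indicator(
    design: pd.DataFrame, contrast: tuple[str, str, str]
) -> np.ndarray:
    factor, level, ref = contrast
    vals = design[factor].astype(str)
    keep = vals.isin([level, ref])
    if not keep.all():
        raise de.DesignError("samples outside the contrast levels are not supported")
    return (vals == level).to_numpy(dtype=float)


def eisa_fit(
    exonic: pd.DataFrame,
    intronic: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str] = ("genotype", "mutant", "wild_type"),
    min_intron_mean: float = 8.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Joint interaction model per gene; returns the EISA result table.

    Columns: ``delta_exon``, ``delta_intron``, ``delta_diff`` (log2, from the
    joint model), ``delta_diff_twostep``, ``diff_SE``, ``diff_pvalue``,
    ``diff_padj``, exon-level DE columns (``exon_log2FC``, ``exon_pvalue``,
    ``exon_padj``), half-life proxies per condition and their shift, and
    ``low_intron``.
    """
    common = [g for g in exonic.index if g in set(intronic.index)]
    dropped = [g for g in exonic.index if g not in set(intronic.index)]
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "%d gene(s) present only in the exonic matrix were excluded",
            len(dropped),
        )
    exonic = exonic.loc[common]
    intronic = intronic.loc[common]

    sf_ex = de.size_factors(exonic, pseudo_reference=True)
    sf_in = de.size_factors(intronic, pseudo_reference=True)
    x = _condition_indicator(design, contrast)

    norm_ex = exonic.to_numpy(float) / sf_ex.to_numpy()[None, :]
    norm_in = intronic.to_numpy(float) / sf_in.to_numpy()[None, :]
    low_intron = norm_in.mean(axis=1) < min_intron_mean

    cells = pd.Series(np.where(x == 1, "cond", "ref"), index=design.index)
    disp_ex = de.estimate_dispersions(exonic, cells, sf_ex)["alpha"]
    disp_in = de.estimate_dispersions(intronic, cells, sf_in)["alpha"]

    # stacked design: intronic rows first, then exonic
    xx = np.concatenate([x, x])
    rr = np.concatenate([np.zeros(len(x)), np.ones(len(x))])
    X = pd.DataFrame(
        {
            "Intercept": np.ones(2 * len(x)),
            "condition": xx,
            "region": rr,
            "condition:region": xx * rr,
        }
    )
    offset = np.log(np.concatenate([sf_in.to_numpy(), sf_ex.to_numpy()]))

    # exon-level DE (Wald on the condition effect) for classification
    exon_de = de.de_table(
        exonic,
        design.assign(_cond=np.where(x == 1, "cond", "ref")),
        de.ModelSpec(terms=("_cond",), references=(("_cond", "ref"),)),
        test="wald",
        coef="_cond[cond]",
        sf=sf_ex,
        dispersions=disp_ex,
    )

    mean_ex_ref = norm_ex[:, x == 0].mean(axis=1)
    mean_ex_cond = norm_ex[:, x == 1].mean(axis=1)
    mean_in_ref = norm_in[:, x == 0].mean(axis=1)
    mean_in_cond = norm_in[:, x == 1].mean(axis=1)
    c = pseudocount
    twostep = np.log2((mean_ex_cond + c) / (mean_ex_ref + c)) - np.log2(
        (mean_in_cond + c) / (mean_in_ref + c)
    )
    proxy_ref = np.log2((mean_ex_ref + c) / (mean_in_ref + c))
    proxy_cond = np.log2((mean_ex_cond + c) / (mean_in_cond + c))

    rows = []
    ex_arr = exonic.to_numpy(float)
    in_arr = intronic.to_numpy(float)
    for i, gene in enumerate(common):
        if low_intron[i]:
            rows.append((np.nan,) * 6)
            continue
        a = np.nanmax(
            [disp_ex.get(gene, np.nan), disp_in.get(gene, np.nan)]
        )
        if not np.isfinite(a):
            rows.append((np.nan,) * 6)
            continue
        y = np.concatenate([in_arr[i], ex_arr[i]])
        fit = de.fit_nb_glm(y, X, offset, float(a))
        if not fit.converged:
            rows.append((np.nan,) * 6)
            continue
        w = de.wald_test(fit, "condition:region")
        d_in = fit.coef[fit.names.index("condition")] / LN2
        d_diff = w["log2FC"]
        rows.append((d_in + d_diff, d_in, d_diff, w["SE"], w["stat"], w["pvalue"]))

    res = pd.DataFrame(
        rows,
        index=common,
        columns=[
            "delta_exon", "delta_intron", "delta_diff", "diff_SE", "diff_stat",
            "diff_pvalue",
        ],
    )
    res["diff_padj"] = de.adjust_bh(res["diff_pvalue"])
    res["delta_diff_twostep"] = twostep
    res["exon_log2FC"] = exon_de["log2FC"]
    res["exon_pvalue"] = exon_de["pvalue"]
    res["exon_padj"] = exon_de["padj"]
    res["half_life_proxy_ref"] = proxy_ref
    res["half_life_proxy_cond"] = proxy_cond
    res["half_life_shift"] = proxy_cond - proxy_ref
    res["low_intron"] = low_intron
    return res


def half_life_proxy(
    exonic: pd.DataFrame,
    intronic: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str] = ("genotype", "mutant", "wild_type"),
    min_intron_mean: float = 8.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene, per-condition exon/intron stability proxy and its shift.

    ``proxy = log2((normalized exonic mean + c)/(normalized intronic mean + c))``
    per condition; ``shift = condition - reference``; positive shift means
    increased relative mRNA stability.  Genes below the intronic filter are
    reported with NaN.
    """
    common = [g for g in exonic.index if g in set(intronic.index)]
    exonic, intronic = exonic.loc[common], intronic.loc[common]
    sf_ex = de.size_factors(exonic, pseudo_reference=True)
    sf_in = de.size_factors(intronic, pseudo_reference=True)
    x = _condition_indicator(design, contrast)
    norm_ex = exonic.to_numpy(float) / sf_ex.to_numpy()[None, :]
    norm_in = intronic.to_numpy(float) / sf_in.to_numpy()[None, :]
    c = pseudocount
    out = pd.DataFrame(index=common)
    out["proxy_ref"] = np.log2(
        (norm_ex[:, x == 0].mean(axis=1) + c) / (norm_in[:, x == 0].mean(axis=1) + c)
    )
    out["proxy_cond"] = np.log2(
        (norm_ex[:, x == 1].mean(axis=1) + c) / (norm_in[:, x == 1].mean(axis=1) + c)
    )
    out["shift"] = out["proxy_cond"] - out["proxy_ref"]
    out[norm_in.mean(axis=1) < min_intron_mean] = np.nan
    return out


def classify_regulation(
    res: pd.DataFrame, fdr: float = 0.05, lfc: float = 0.25
) -> pd.Series:
    """Label each gene's regulation mode from the EISA result table.

    ``post_transcriptional``: significant interaction only;
    ``transcriptional``: significant exon-level DE only;
    ``mixed``: both; ``none``: neither; ``low_intron``: filtered out.
    Labels are exhaustive and mutually exclusive.
    """
    diff_sig = (res["diff_padj"] <= fdr) & (res["delta_diff"].abs() >= lfc)
    exon_sig = (res["exon_padj"] <= fdr) & (res["exon_log2FC"].abs() >= lfc)
    labels = np.where(
        res["low_intron"],
        "low_intron",
        np.where(
            diff_sig & exon_sig,
            "mixed",
            np.where(
                diff_sig,
                "post_transcriptional",
                np.where(exon_sig, "transcriptional", "none"),
            ),
        ),
    )
    return pd.Series(labels, index=res.index, name="class")


def scatter_data(res: pd.DataFrame, fdr: float = 0.05, lfc: float = 0.25) -> pd.DataFrame:
    """Delta-exon vs delta-intron scatter table with significance flags,
    sufficient to draw the classic EISA panel."""
    out = res[["delta_exon", "delta_intron", "delta_diff", "diff_padj"]].copy()
    out["significant"] = (res["diff_padj"] <= fdr) & (res["delta_diff"].abs() >= lfc)
    out["post_transcriptional_up"] = out["significant"] & (res["delta_diff"] > 0)
    return out
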