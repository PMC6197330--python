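"""Competitive gene-set enrichment and overlap testing.

``camera_test`` asks whether the genes of a set carry systematically larger
or smaller statistics than the remaining genes, while accounting for
inter-gene correlation: correlated sets behave like fewer independent genes,
so the naive two-sample comparison is anti-conservative.  The comparison's
variance is inflated by ``VIF = 1 + (m - 1) * rho`` where ``rho`` is the mean
pairwise correlation of the set members' residuals (estimated from the
fitted model's residual matrix, not raw data; floored at 0.01 when it cannot
be estimated).

``barcode_data`` produces the ranked positions of set members plus a running
relative-enrichment curve (the "worm"), sufficient to draw barcode plots.

``hypergeom_overlap`` is the exact upper-tail hypergeometric test for the
overlap of two sets drawn from a common universe, computed with integer
arithmetic (rational-safe; no floating-point binomials).
"""

from __future__ import annotations

import os
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .de import adjust_bh


class GeneSetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GMT IO


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    sets: dict[str, list[str]], path: str | os.PathLike, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# camera-style competitive test


def _mean_pairwise_correlation(resid: np.ndarray) -> float:
    """Mean pairwise Pearson correlation between rows of ``resid``."""
    m = resid.shape[0]
    if m < 2 or resid.shape[1] < 3:
        return np.nan
    centered = resid - resid.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    if ok.sum() < 2:
        return np.nan
    unit = centered[ok] / norms[ok][:, None]
    s = unit.sum(axis=0)
    mm = ok.sum()
    return float((s @ s - mm) / (mm * (mm - 1)))


def camera_test(
    statistics: pd.Series,
    sets: dict[str, list[str]],
    residuals: pd.DataFrame | None = None,
    min_size: int = 5,
    inter_gene_cor: float | None = None,
    df: int | None = None,
) -> pd.DataFrame:
    """Competitive test of each set's statistics against the rest.

    ``statistics`` are per-gene (ideally z-like) scores over the universe;
    ``residuals`` is the genes x samples residual matrix used to estimate the
    within-set correlation (``inter_gene_cor`` overrides it, and 0.01 is
    used when neither yields an estimate).  For each retained set a
    two-sample t comparison with VIF-inflated variance gives a two-sided p;
    direction is the sign of the set-minus-rest mean difference.  Sets whose
    intersection with the universe falls below ``min_size`` are skipped.

    ``df`` is the degrees of freedom of the t reference.  When the
    correlation is estimated from a residual matrix the appropriate choice
    is the model's residual df (samples minus fitted parameters), which
    accounts for the uncertainty of the correlation estimate; the default
    uses the residual column count minus one, or ``N - 2`` when no residuals
    are supplied.
    """
    stats_v = statistics.dropna()
    universe = pd.Index(stats_v.index)
    values = stats_v.to_numpy(dtype=float)
    n_total = len(universe)
    if n_total < 3:
        raise GeneSetError("universe too small for a competitive test")
    overall_var = float(values.var(ddof=1))
    if df is None:
        df = residuals.shape[1] - 1 if residuals is not None else n_total - 2
    df = min(df, n_total - 2)
    rows = []
    for name, members in sets.items():
        idx = universe.get_indexer_for([g for g in set(members) if g in universe])
        m = len(idx)
        if m < min_size or n_total - m < 2:
            continue
        if inter_gene_cor is not None:
            rho = float(inter_gene_cor)
        elif residuals is not None:
            sub = residuals.reindex(universe[idx]).dropna().to_numpy(dtype=float)
            rho = _mean_pairwise_correlation(sub)
            if not np.isfinite(rho):
                rho = 0.01
        else:
            rho = 0.01
        vif = 1.0 + (m - 1) * rho
        vif = max(vif, 1e-6)
        mask = np.zeros(n_total, dtype=bool)
        mask[idx] = True
        mean_in = values[mask].mean()
        mean_out = values[~mask].mean()
        delta = mean_in - mean_out
        se = np.sqrt(overall_var * (vif / m + 1.0 / (n_total - m)))
        t = delta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "set": name,
                "n_genes": m,
                "direction": "Up" if delta > 0 else "Down",
                "correlation": rho,
                "VIF": vif,
                "stat": t,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["n_genes", "direction", "correlation", "VIF", "stat", "pvalue"]
    )
    if len(out):
        out["padj"] = adjust_bh(out["pvalue"])
    return out


# ---------------------------------------------------------------------------
# barcode data


def barcode_data(
    statistics: pd.Series, gene_set: list[str], n_bins: int = 64
) -> dict:
    """Ranked positions of set members and a running enrichment curve.

    Statistics are ranked from largest to smallest (ties broken by gene id,
    deterministically); positions are 1-based.  The curve is the set's
    relative density across ``n_bins`` equal-width rank bins, lightly
    smoothed with a triangular kernel and normalized so 1.0 is the density
    expected under uniform placement.
    """
    members = [g for g in set(gene_set) if g in statistics.index]
    if not members:
        raise GeneSetError("gene set is empty after intersection with the universe")
    order = statistics.sort_index().sort_values(ascending=False, kind="mergesort")
    n = len(order)
    rank = pd.Series(np.arange(1, n + 1), index=order.index)
    positions = np.sort(rank.loc[members].to_numpy())
    edges = np.linspace(0.5, n + 0.5, n_bins + 1)
    hist, _ = np.histogram(positions, bins=edges)
    smooth = np.convolve(hist, np.array([0.25, 0.5, 0.25]), mode="same")
    expected = len(members) / n_bins
    curve = smooth / expected
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {
        "n_universe": n,
        "positions": positions.tolist(),
        "curve_x": centers.tolist(),
        "curve_y": curve.tolist(),
    }


# ---------------------------------------------------------------------------
# hypergeometric overlap


def hypergeom_overlap(
    universe_size: int, set1_size: int, set2_size: int, overlap: int
) -> dict:
    """Exact upper-tail P(X >= overlap) for the overlap of two random sets.

    X ~ Hypergeometric(N=universe_size, K=set1_size, n=set2_size); computed
    by exact integer summation and symmetric in the two set sizes.
    """
    N, K, n, k = universe_size, set1_size, set2_size, overlap
    if K > N or n > N:
        raise GeneSetError("set sizes exceed the universe")
    if k < 0 or k > min(K, n):
        raise GeneSetError("overlap inconsistent with the set sizes")
    denom = comb(N, n)
    total = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    pvalue = Fraction(total, denom)
    return {
        "pvalue": float(pvalue),
        "expected_overlap": n * K / N,
        "observed": k,
    }


def hypergeom_pmf_exact(universe_size: int, set1_size: int, set2_size: int):
    """Exact PMF over the full support, as Fractions (sums to exactly 1)."""
    N, K, n = universe_size, set1_size, set2_size
    lo = max(0, n - (N - K))
    hi = min(K, n)
    denom = comb(N, n)
    return {
        x: Fraction(comb(K, x) * comb(N - K, n - x), denom) for x in range(lo, hi + 1)
    }
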