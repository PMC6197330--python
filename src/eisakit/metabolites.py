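"""Metabolite panel statistics.

Three workhorses for concentration/intensity panels:

* per-feature ``~ genotype * treatment`` linear models on log2 or
  variance-stabilized values, testing the interaction term — "does the
  genotype difference change under treatment?" (a glucocorticoid-rescue
  contrast);
* PCA score/loading decomposition for panel-level QC;
* a per-metabolite random-intercept linear mixed model for paired patient
  panels, ``y ~ age + treatment + (1|patient)``, fitted by maximum
  likelihood with the variance ratio profiled out, and a chi-square(1)
  likelihood-ratio test of the treatment effect against the reduced
  ``y ~ age + (1|patient)`` model.

ML (not REML) is used throughout the LMM because the LRT compares models
with different fixed effects; reported SEs are therefore large-sample ML
SEs without small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .de import adjust_bh


class PanelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transforms


def glog(x: np.ndarray, lam: float) -> np.ndarray:
    """Generalized log: log2((x + sqrt(x^2 + lam^2)) / 2); -> log2(x) as lam->0."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def estimate_glog_lambda(panel: pd.DataFrame) -> float:
    """Median SD of the lowest-intensity quartile of features."""
    means = panel.mean(axis=1)
    cut = means.quantile(0.25)
    low = panel.loc[means <= cut]
    lam = float(low.std(axis=1, ddof=1).median())
    return lam if lam > 0 else 1.0


def transform_panel(
    panel: pd.DataFrame, method: str = "log2", lam: float | None = None
) -> pd.DataFrame:
    """Elementwise log2 or variance-stabilizing glog transform."""
    if method == "log2":
        if (panel.to_numpy() <= 0).any():
            raise PanelError(
                "nonpositive values cannot be log2-transformed; use method='glog'"
            )
        return np.log2(panel)
    if method == "glog":
        if lam is None:
            lam = estimate_glog_lambda(panel)
        if lam <= 0:
            raise PanelError("glog lambda must be > 0")
        return pd.DataFrame(
            glog(panel.to_numpy(), lam), index=panel.index, columns=panel.columns
        )
    raise PanelError(f"unknown transform {method!r}")


# ---------------------------------------------------------------------------
# genotype x treatment interaction models


def fit_interaction_lm(
    panel: pd.DataFrame,
    genotype: pd.Series | np.ndarray,
    treatment: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """OLS ``y ~ genotype * treatment`` per feature (vectorized across rows).

    ``genotype``/``treatment`` are 0/1 indicators or factor labels
    ("mutant", "DEX" coded 1).  Returns per-feature coefficients, SEs, the
    interaction t-test p-value and its BH adjustment.  Requires at least one
    sample in each 2x2 cell and >= 1 residual degree of freedom.
    """
    g = np.asarray(
        [1.0 if v in (1, "mutant", True) else 0.0 for v in np.asarray(genotype)]
    )
    t = np.asarray(
        [1.0 if v in (1, "DEX", True) else 0.0 for v in np.asarray(treatment)]
    )
    cells = {(int(a), int(b)) for a, b in zip(g, t)}
    if len(cells) < 4:
        raise PanelError("need samples in every cell of the 2x2 design")
    X = np.column_stack([np.ones_like(g), g, t, g * t])
    n, p = X.shape
    if n - p < 1:
        raise PanelError("need >= 1 residual degree of freedom")
    Y = panel.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T  # features x 4
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / (n - p)
    se = np.sqrt(np.outer(s2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B / se
    pint = 2.0 * stats.t.sf(np.abs(tstat[:, 3]), n - p)
    out = pd.DataFrame(
        {
            "beta0": B[:, 0],
            "beta_genotype": B[:, 1],
            "beta_treatment": B[:, 2],
            "beta_interaction": B[:, 3],
            "SE_interaction": se[:, 3],
            "interaction_pvalue": pint,
        },
        index=panel.index,
    )
    out["interaction_padj"] = adjust_bh(out["interaction_pvalue"])
    return out


# ---------------------------------------------------------------------------
# PCA


def pca_scores(
    panel: pd.DataFrame, center: bool = True, scale: bool = False
) -> dict:
    """SVD-based PCA of a features x samples panel (samples are observations).

    Constant features are dropped when scaling.  Loadings' sign convention:
    the largest-magnitude loading of each component is positive.  Returns
    scores (samples x PCs), loadings (features x PCs) and the variance
    explained per component.
    """
    if panel.shape[0] < 2 or panel.shape[1] < 2:
        raise PanelError("need >= 2 features and >= 2 samples")
    X = panel.to_numpy(dtype=float).T  # samples x features
    features = list(panel.index)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            import logging

            logging.getLogger(__name__).info(
                "dropped %d constant feature(s) before scaling", int((~keep).sum())
            )
        X = X[:, keep]
        features = [f for f, k in zip(features, keep) if k]
        sd = sd[keep]
    mean = X.mean(axis=0)
    if center:
        X = X - mean
    if scale:
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for j in range(Vt.shape[0]):
        i = int(np.abs(Vt[j]).argmax())
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    var = S**2 / max(1, X.shape[0] - 1)
    pcs = [f"PC{j + 1}" for j in range(len(S))]
    return {
        "scores": pd.DataFrame(scores, index=panel.columns, columns=pcs),
        "loadings": pd.DataFrame(Vt.T, index=features, columns=pcs),
        "variance_explained": pd.Series(var / var.sum(), index=pcs),
        "variance": pd.Series(var, index=pcs),
    }


# ---------------------------------------------------------------------------
# random-intercept LMM (profiled ML)


@dataclass
class LmmFit:
    params: pd.Series  # fixed effects
    se: pd.Series
    sigma_b2: float
    sigma_e2: float
    llf: float
    n_obs: int
    names: list[str]


def _lmm_profile(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, theta: float
):
    """GLS fit and profile log-likelihood at variance ratio theta=sb2/se2."""
    n = len(y)
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    logdet = 0.0
    parts = []
    for gidx in np.unique(groups):
        m = groups == gidx
        Xi, yi = X[m], y[m]
        ni = int(m.sum())
        c = theta / (1.0 + ni * theta)
        # V_i^{-1} = I - c * J
        XtVX += Xi.T @ Xi - c * np.outer(Xi.sum(0), Xi.sum(0))
        XtVy += Xi.T @ yi - c * Xi.sum(0) * yi.sum()
        logdet += np.log1p(ni * theta)
        parts.append((Xi, yi, ni, c))
    beta = np.linalg.solve(XtVX, XtVy)
    rss = 0.0
    for Xi, yi, ni, c in parts:
        r = yi - Xi @ beta
        rss += r @ r - c * r.sum() ** 2
    sigma_e2 = rss / n
    llf = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + logdet + n)
    return beta, sigma_e2, llf, XtVX


def fit_random_intercept_lmm(
    y,
    age,
    treatment,
    patient_id,
    include_treatment: bool = True,
) -> LmmFit:
    """ML random-intercept model ``y ~ age (+ treatment) + (1|patient)``.

    The variance ratio ``theta = sigma_b^2/sigma_e^2`` is profiled out: for a
    given theta the GLS fixed effects and the ML residual variance have
    closed forms, leaving a 1-D log-likelihood maximized over theta >= 0
    (the boundary estimate sigma_b^2 = 0 is allowed).  Fixed-effect SEs are
    ``sqrt(diag(sigma_e^2 (X' V^-1 X)^-1))``.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    trt_raw = np.asarray(treatment)
    trt = np.asarray(
        [1.0 if v in (1, "Off", True) else 0.0 for v in trt_raw]
    )
    groups = pd.factorize(np.asarray(patient_id))[0]
    if len(np.unique(groups)) < 2:
        raise PanelError("need >= 2 patients")
    if include_treatment and len(np.unique(trt)) < 2:
        raise PanelError(
            "treatment is constant; its effect is confounded with the baseline"
        )
    cols = [np.ones_like(y), age]
    names = ["Intercept", "age"]
    if include_treatment:
        cols.append(trt)
        names.append("treatment")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PanelError(
            "fixed effects are confounded (rank-deficient design); with one "
            "observation per patient the treatment effect cannot be separated "
            "from the patient baseline"
        )

    def neg_profile(log_theta: float) -> float:
        return -_lmm_profile(y, X, groups, np.exp(log_theta))[2]

    res = optimize.minimize_scalar(
        neg_profile, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(np.exp(res.x))
    beta, se2, llf, XtVX = _lmm_profile(y, X, groups, theta)
    # boundary check: sigma_b2 = 0
    beta0, se2_0, llf0, XtVX0 = _lmm_profile(y, X, groups, 0.0)
    if llf0 >= llf:
        theta, beta, se2, llf, XtVX = 0.0, beta0, se2_0, llf0, XtVX0
    cov = se2 * np.linalg.inv(XtVX)
    return LmmFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        sigma_b2=theta * se2,
        sigma_e2=se2,
        llf=float(llf),
        n_obs=len(y),
        names=names,
    )


def lmm_lrt(full: LmmFit, reduced: LmmFit) -> dict:
    """Chi-square(1) LRT of the treatment fixed effect (both fits ML)."""
    if "treatment" not in full.names or "treatment" in reduced.names:
        raise PanelError("expected full model with treatment, reduced without")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return {"stat": stat, "pvalue": float(stats.chi2.sf(stat, 1))}


def patient_panel_lmm(
    long_df: pd.DataFrame,
    value_col: str = "value",
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Per-metabolite LMM + treatment LRT over a long-format patient panel.

    Expects columns ``patient_id, age, treatment, metabolite`` and
    ``value_col``; ``log2_transform=True`` models log2 of the values (for
    concentrations on the natural scale).  BH is applied across metabolites.
    """
    rows = []
    for met, sub in long_df.groupby("metabolite", sort=True):
        yv = sub[value_col].to_numpy(dtype=float)
        if log2_transform:
            if (yv <= 0).any():
                raise PanelError(f"metabolite {met!r}: nonpositive concentration")
            yv = np.log2(yv)
        full = fit_random_intercept_lmm(
            yv, sub["age"], sub["treatment"], sub["patient_id"]
        )
        red = fit_random_intercept_lmm(
            yv, sub["age"], sub["treatment"], sub["patient_id"],
            include_treatment=False,
        )
        test = lmm_lrt(full, red)
        rows.append(
            {
                "metabolite": met,
                "beta_treatment": full.params["treatment"],
                "SE_treatment": full.se["treatment"],
                "beta_age": full.params["age"],
                "sigma_b2": full.sigma_b2,
                "sigma_e2": full.sigma_e2,
                "lrt_stat": test["stat"],
                "pvalue": test["pvalue"],
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    out["padj"] = adjust_bh(out["pvalue"])
    return out
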