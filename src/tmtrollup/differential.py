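"""Group-contrast inference on the normalized protein matrix.

Per protein, a group-means linear model yields the contrast estimate and a
pooled residual variance; an empirical-Bayes squeeze borrows information
across proteins by shrinking each residual variance toward a prior
(estimated by moment matching on the log residual variances under a
scaled-F model), buying ``d0`` extra degrees of freedom for the moderated
t statistic. P-values are adjusted by the Benjamini-Hochberg step-up.
Metric MDS and PCA summarize inter-sample structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .psm_io import Design
from .quantify import RatioMatrix

__all__ = [
    "LinearFit",
    "ModerationFit",
    "fit_linear_model",
    "moderate_variances",
    "moderated_t",
    "bh_adjust",
    "run_differential",
    "classical_mds",
    "pca_scores",
]


@dataclass
class LinearFit:
    """Per-protein two-group statistics: contrast estimate (A - B), pooled
    residual variance, residual df, and per-group observation counts."""

    table: pd.DataFrame  # columns: estimate, s2, df, n_a, n_b
    contrast: tuple[str, str]


def fit_linear_model(matrix: RatioMatrix, design: Design, contrast: tuple[str, str]) -> LinearFit:
    """Group-means model per protein on non-missing values.

    ``contrast = (A, B)`` gives ``estimate = mean(A) - mean(B)``, pooled
    residual variance over both groups, and residual df ``n_A + n_B - 2``.
    Proteins with fewer than 2 non-missing values in either group get NaN
    statistics.
    """
    cond_a, cond_b = contrast
    conditions = set(design.table.loc[~design.table["is_reference"], "condition"])
    for c in contrast:
        if c not in conditions:
            raise KeyError(f"condition {c!r} not in design (has {sorted(conditions)})")
    cols_a = [s for s in design.samples_for(cond_a) if s in matrix.values.columns]
    cols_b = [s for s in design.samples_for(cond_b) if s in matrix.values.columns]
    A = matrix.values[cols_a].to_numpy(dtype=float)
    B = matrix.values[cols_b].to_numpy(dtype=float)
    n_a = np.isfinite(A).sum(axis=1)
    n_b = np.isfinite(B).sum(axis=1)
    ok = (n_a >= 2) & (n_b >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
        ss_a = np.nansum((A - mean_a[:, None]) ** 2, axis=1)
        ss_b = np.nansum((B - mean_b[:, None]) ** 2, axis=1)
    df = n_a + n_b - 2.0
    est = np.where(ok, mean_a - mean_b, np.nan)
    s2 = np.where(ok, (ss_a + ss_b) / np.where(df > 0, df, np.nan), np.nan)
    tab = pd.DataFrame(
        {
            "estimate": est,
            "s2": s2,
            "df": np.where(ok, df, np.nan),
            "n_a": n_a,
            "n_b": n_b,
        },
        index=matrix.values.index,
    )
    return LinearFit(tab, (cond_a, cond_b))


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


@dataclass
class ModerationFit:
    """Prior df ``d0`` (may be inf), prior variance ``s0_sq``, and the
    per-protein posterior variances and total df."""

    d0: float
    s0_sq: float
    s_tilde_sq: np.ndarray
    df_total: np.ndarray


def moderate_variances(s2, df) -> ModerationFit:
    """Estimate (d0, s0^2) and squeeze the per-protein variances.

    Under the scaled-F model, ``e_g = log s_g^2 - digamma(d_g/2) +
    log(d_g/2)`` has mean ``log s0^2 + digamma(d0/2) - log(d0/2)`` and
    excess variance ``trigamma(d0/2)``; moment matching with a trigamma
    inversion yields d0, and the posterior variance is the df-weighted
    average ``(d0 s0^2 + d_g s_g^2) / (d0 + d_g)``. When the observed
    spread of e_g does not exceed its sampling variance, d0 is infinite and
    all posteriors equal s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    use = np.isfinite(s2) & np.isfinite(df) & (df >= 1) & (s2 >= 0)
    if use.sum() < 2:
        raise ValueError("need at least 2 non-negative variances with df >= 1")
    x = s2[use]
    med = float(np.median(x))
    if med > 0:  # offset exact zeros away from 0 before taking logs
        x = np.maximum(x, 1e-5 * med)
    else:
        x = np.maximum(x, 1e-300)
    z = np.log(x)
    half_df = df[use] / 2.0
    e = z - digamma(half_df) + np.log(half_df)
    emean = float(np.mean(e))
    n = len(e)
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(np.mean(polygamma(1, half_df)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond sampling noise: variances are exchangeable
        d0 = np.inf
        s0_sq = float(np.mean(x))
    if np.isinf(d0):
        s_tilde = np.where(np.isfinite(s2), np.full_like(s2, s0_sq), np.nan)
        df_total = np.full_like(df, np.inf)
    else:
        s_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    df_total = np.where(np.isfinite(df), df_total, np.nan)
    return ModerationFit(d0, s0_sq, s_tilde, df_total)


def moderated_t(estimate, s_tilde_sq, df_total, n_a, n_b):
    """Moderated t and two-sided p.

    ``t = estimate / sqrt(s_tilde^2 (1/n_a + 1/n_b))`` referred to a t
    distribution with ``d0 + d_g`` df (normal when d0 is infinite).
    A zero posterior variance yields p = 0 for a nonzero estimate (p = 1
    otherwise), with a warning.
    """
    estimate = np.asarray(estimate, dtype=float)
    s_tilde_sq = np.asarray(s_tilde_sq, dtype=float)
    df_total = np.asarray(df_total, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = estimate / se
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    zero_var = np.isfinite(estimate) & (se == 0)
    if np.any(zero_var):
        warnings.warn("zero posterior variance for some proteins", stacklevel=2)
        with np.errstate(invalid="ignore"):
            p = np.where(zero_var & (estimate != 0), 0.0, p)
            p = np.where(zero_var & (estimate == 0), 1.0, p)
            t = np.where(zero_var & (estimate != 0), np.inf * np.sign(estimate), t)
            t = np.where(zero_var & (estimate == 0), 0.0, t)
    return t, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaN entries passed through;
    m counts only the non-NaN p-values)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    q = p[mask]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(q)
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def run_differential(matrix: RatioMatrix, design: Design, contrast: tuple[str, str]) -> pd.DataFrame:
    """Full per-protein differential table for ``contrast = (A, B)``.

    Columns: per-sample normalized ratios, n observations per group,
    estimate, moderated t, total df, p, BH-adjusted p. Only proteins with
    >= 2 non-missing values per group are tested; BH's m counts tested
    proteins only.
    """
    fit = fit_linear_model(matrix, design, contrast)
    tab = fit.table
    tested = tab["s2"].notna() & (tab["df"] >= 1)
    mod = moderate_variances(tab.loc[tested, "s2"], tab.loc[tested, "df"])
    t = np.full(len(tab), np.nan)
    p = np.full(len(tab), np.nan)
    t_sub, p_sub = moderated_t(
        tab.loc[tested, "estimate"],
        mod.s_tilde_sq,
        mod.df_total,
        tab.loc[tested, "n_a"],
        tab.loc[tested, "n_b"],
    )
    t[tested.to_numpy()] = t_sub
    p[tested.to_numpy()] = p_sub
    df_total = np.full(len(tab), np.nan)
    df_total[tested.to_numpy()] = mod.df_total
    out = matrix.values.copy()
    out["n_a"] = tab["n_a"]
    out["n_b"] = tab["n_b"]
    out["estimate"] = tab["estimate"]
    out["t_mod"] = t
    out["df"] = df_total
    out["p"] = p
    out["adj_p"] = bh_adjust(p)
    out.index.name = "accession"
    out.attrs["d0"] = mod.d0
    out.attrs["s0_sq"] = mod.s0_sq
    out.attrs["contrast"] = f"{contrast[0]}-{contrast[1]}"
    return out


# ---------------------------------------------------------------------------
# sample-level summaries


def classical_mds(matrix: RatioMatrix, k: int = 2):
    """Classical (metric) MDS of samples from pairwise Euclidean distances.

    Distances use, per sample pair, the proteins non-missing in both
    samples. Double-centering of squared distances followed by an
    eigendecomposition gives the top-k coordinates. Returns
    ``(coords: DataFrame samples x k, eigenvalues)``.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    samples = list(matrix.values.columns)
    n = len(samples)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    D2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.isfinite(X[i]) & np.isfinite(X[j])
            if not shared.any():
                raise ValueError(f"samples {samples[i]!r}, {samples[j]!r} share no proteins")
            d2 = float(np.sum((X[i, shared] - X[j, shared]) ** 2))
            D2[i, j] = D2[j, i] = d2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    lam = np.clip(evals[:k], 0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    coords = _fix_signs(coords)
    return (
        pd.DataFrame(coords, index=samples, columns=[f"dim{i+1}" for i in range(k)]),
        evals,
    )


def pca_scores(matrix: RatioMatrix, k: int = 2):
    """PCA of samples on listwise-complete proteins.

    Column-centered SVD of the samples x proteins matrix; returns
    ``(scores: DataFrame samples x k, explained_variance_fractions)``.
    The sign convention makes each component's largest-magnitude loading
    positive.
    """
    complete = matrix.values.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no proteins complete across all samples")
    samples = list(matrix.values.columns)
    n = len(samples)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    X = complete.to_numpy(dtype=float).T  # samples x proteins
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for c in range(len(s)):  # deterministic sign: largest |loading| positive
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * s[:k]
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return (
        pd.DataFrame(scores, index=samples, columns=[f"PC{i+1}" for i in range(k)]),
        frac[:k],
    )


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for c in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, c])))
        if coords[j, c] < 0:
            coords[:, c] *= -1
    return coords
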