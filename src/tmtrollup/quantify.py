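"""Reporter-ion quantification: reference ratios, Dixon outlier removal,
median roll-ups, mixture-mode alignment, and trimmed scaling.

The quantification model follows the standard multiplexed-TMT design with a
pooled common-reference channel: each PSM's per-channel intensity is
converted to a log2 ratio against the mean of the plex's reference
channels, ratios are cleaned per peptide and channel with a recursive
Dixon's Q test, medians roll PSMs up to peptides and peptides up to
proteins, and each sample's protein log2-ratio distribution is normalized
by (i) shifting so the mode of a fitted 3-component Gaussian mixture sits
at zero and (ii) dividing by a doubly trimmed standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .identification import FdrConfig, ProteinGroup, filter_psm_fdr, infer_proteins, razor_map
from .psm_io import Design, PsmRecord

__all__ = [
    "FilterConfig",
    "DixonConfig",
    "ScalingConfig",
    "RatioMatrix",
    "MixtureFit",
    "MixtureFallback",
    "filter_psms",
    "compute_log2_ratios",
    "dixon_q",
    "remove_outliers_recursive",
    "apply_dixon",
    "rollup_median",
    "fit_mixture3",
    "align_to_mode",
    "trimmed_scale",
    "run_quant_pipeline",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FilterConfig:
    """PSM-level filters: minimum mean reporter intensity and removal of
    peptides shared between accepted protein groups."""

    min_intensity: float = 1000.0
    drop_shared_peptides: bool = True

    def __post_init__(self):
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")


# Two-tailed 95% critical values for Dixon's ratio statistics
# (Dixon/Rorabacher tables): r10 for n 3-7, r11 for 8-10, r21 for 11-13,
# r22 for 14-30.
_DIXON_CRIT: dict[int, float] = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
    8: 0.608, 9: 0.564, 10: 0.530,
    11: 0.619, 12: 0.583, 13: 0.557,
    14: 0.670, 15: 0.637, 16: 0.607, 17: 0.580, 18: 0.558, 19: 0.539,
    20: 0.522, 21: 0.508, 22: 0.495, 23: 0.484, 24: 0.473, 25: 0.464,
    26: 0.455, 27: 0.446, 28: 0.439, 29: 0.432, 30: 0.426,
}


@dataclass(frozen=True)
class DixonConfig:
    """Recursive Dixon's Q outlier removal at two-sided alpha = 0.05."""

    alpha: float = 0.05
    max_n: int = 30
    critical_values: dict[int, float] = field(default_factory=lambda: dict(_DIXON_CRIT))


@dataclass(frozen=True)
class ScalingConfig:
    """Normalization knobs: 5% two-sided trims for the scaling SD, the EM
    sigma floor, and the density-mode search grid."""

    trim_fraction: float = 0.05
    sigma_floor: float = 1e-3
    grid_points: int = 2001
    min_points: int = 30  # fewer ratios -> median fallback for alignment
    em_tol: float = 1e-8
    em_max_iter: int = 2000

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# containers


@dataclass
class RatioMatrix:
    """Entities x samples log2 ratios plus representative intensities.

    ``values`` and ``intensity`` share index (PSM ids, peptide keys, or
    protein accessions depending on ``level``) and columns (non-reference
    sample ids). NaN encodes missing.
    """

    level: str  # "psm" | "peptide" | "protein"
    values: pd.DataFrame
    intensity: pd.DataFrame

    def __post_init__(self):
        if self.level not in {"psm", "peptide", "protein"}:
            raise ValueError(f"unknown level {self.level!r}")
        if not self.values.columns.equals(self.intensity.columns) or not (
            self.values.index.equals(self.intensity.index)
        ):
            raise ValueError("values and intensity must be aligned")

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(self.level, self.values.copy(), self.intensity.copy())


@dataclass
class MixtureFit:
    """A fitted 3-component Gaussian mixture and the mode of its density."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    mode: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)[..., None]
        return np.sum(self.weights * norm.pdf(x, self.means, self.sds), axis=-1)


class MixtureFallback(Exception):
    """Raised when too few ratios are available for a mixture fit."""


# ---------------------------------------------------------------------------
# PSM-level filtering and ratio conversion


def filter_psms(psms, groups, cfg: FilterConfig | None = None):
    """Drop PSMs from shared peptides or with low mean reporter intensity.

    A peptide is *shared* when its candidate proteins fall in more than one
    accepted protein group. The intensity rule removes PSMs whose mean
    positive reporter intensity is below ``min_intensity``.
    """
    cfg = cfg or FilterConfig()
    acc_of: dict[str, str] = {}
    for g in groups:
        if not getattr(g, "accepted", False):
            continue
        for acc in {g.lead_accession} | set(g.members):
            acc_of[acc] = g.lead_accession
    kept = []
    for p in psms:
        if cfg.drop_shared_peptides:
            hits = {acc_of[a] for a in p.proteins if a in acc_of}
            if len(hits) > 1:
                continue
        if p.mean_intensity() < cfg.min_intensity:
            continue
        kept.append(p)
    return kept


def compute_log2_ratios(psms, design: Design) -> RatioMatrix:
    """Convert reporter intensities to log2 ratios against the plex's
    reference-channel mean.

    For PSM *i* in plex *p* and non-reference channel *c* carrying sample
    *s*: ``ratio[i, s] = log2(I_c / mean(I_ref))``, missing whenever the
    channel intensity or the reference mean is not positive. The intensity
    matrix keeps ``I_c``.
    """
    psms = list(psms)
    samples = design.samples
    plex_refs = {px: design.reference_channels(px) for px in design.plexes}
    plex_samp = {px: design.sample_channels(px) for px in design.plexes}
    n = len(psms)
    vals = np.full((n, len(samples)), np.nan)
    intens = np.full((n, len(samples)), np.nan)
    col = {s: j for j, s in enumerate(samples)}
    for i, p in enumerate(psms):
        if p.plex_id not in plex_refs:
            raise KeyError(f"plex {p.plex_id!r} not present in design")
        refs = [p.intensities.get(c, 0.0) for c in plex_refs[p.plex_id]]
        ref_mean = float(np.mean(refs)) if refs else 0.0
        for ch, sample in plex_samp[p.plex_id]:
            ic = p.intensities.get(ch, 0.0)
            if ic > 0:
                intens[i, col[sample]] = ic
            if ic > 0 and ref_mean > 0:
                vals[i, col[sample]] = math.log2(ic / ref_mean)
    idx = pd.Index([p.psm_id for p in psms], name="entity")
    return RatioMatrix(
        "psm",
        pd.DataFrame(vals, index=idx, columns=samples),
        pd.DataFrame(intens, index=idx, columns=samples),
    )


# ---------------------------------------------------------------------------
# Dixon's Q


def _dixon_stats(x: np.ndarray) -> tuple[float, float] | None:
    """(low-tail, high-tail) Dixon ratio statistics for sorted x, or None
    when n is outside 3..30."""
    n = len(x)
    if n < 3 or n > 30:
        return None

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    if n <= 7:  # r10
        lo = ratio(x[1] - x[0], x[-1] - x[0])
        hi = ratio(x[-1] - x[-2], x[-1] - x[0])
    elif n <= 10:  # r11
        lo = ratio(x[1] - x[0], x[-2] - x[0])
        hi = ratio(x[-1] - x[-2], x[-1] - x[1])
    elif n <= 13:  # r21
        lo = ratio(x[2] - x[0], x[-2] - x[0])
        hi = ratio(x[-1] - x[-3], x[-1] - x[1])
    else:  # r22
        lo = ratio(x[2] - x[0], x[-3] - x[0])
        hi = ratio(x[-1] - x[-3], x[-1] - x[2])
    return lo, hi


def dixon_q(values) -> tuple[float, int] | None:
    """Range-appropriate Dixon statistic for the more extreme tail.

    Returns ``(q_stat, suspect_index)`` where the index refers to the input
    vector, or ``None`` (no-test signal) when n < 3, n > 30, or all values
    are equal.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or len(v) > 30 or np.ptp(v) == 0:
        return None
    x = np.sort(v)
    lo, hi = _dixon_stats(x)
    if hi >= lo:
        return hi, int(np.argmax(v))
    return lo, int(np.argmin(v))


def remove_outliers_recursive(values, cfg: DixonConfig | None = None) -> np.ndarray:
    """Boolean keep-mask after recursive Dixon removal at two-sided 95%.

    Vectors with n <= 2 (or n > ``max_n``) are returned unchanged; otherwise
    the suspect value is removed whenever its Q statistic exceeds the
    critical value for the current n, and the test recurses on the rest.
    """
    cfg = cfg or DixonConfig()
    v = np.asarray(values, dtype=float)
    keep = np.ones(len(v), dtype=bool)
    if len(v) > cfg.max_n:
        return keep
    while keep.sum() >= 3:
        idx = np.flatnonzero(keep)
        res = dixon_q(v[idx])
        if res is None:
            break
        q, local = res
        crit = cfg.critical_values.get(int(keep.sum()))
        if crit is None or q <= crit:
            break
        keep[idx[local]] = False
    return keep


def apply_dixon(matrix: RatioMatrix, grouping: dict[str, str], cfg: DixonConfig | None = None) -> RatioMatrix:
    """Mask Dixon outliers per (parent entity, sample) among child ratios.

    Applied to the PSM-level matrix with the PSM -> peptide grouping: for
    each peptide and channel with more than two identifying PSMs, recursive
    Dixon removal masks the flagged ratios (set to missing).
    """
    cfg = cfg or DixonConfig()
    out = matrix.copy()
    vals = out.values
    parents = pd.Series([grouping.get(e) for e in vals.index], index=vals.index)
    for _, members in vals.groupby(parents, sort=False):
        if len(members) <= 2:
            continue
        for s in vals.columns:
            col = members[s]
            obs = col.dropna()
            if len(obs) <= 2:
                continue
            keep = remove_outliers_recursive(obs.to_numpy(), cfg)
            dropped = obs.index[~keep]
            if len(dropped):
                vals.loc[dropped, s] = np.nan
    return out


def rollup_median(matrix: RatioMatrix, grouping: dict[str, str], level: str) -> RatioMatrix:
    """Median roll-up one level (PSM -> peptide or peptide -> protein).

    Per parent and sample, the value is the median of non-missing child
    ratios (missing when none), and the representative intensity is the
    median of child intensities.
    """
    missing = [e for e in matrix.values.index if e not in grouping]
    if missing:
        raise KeyError(f"grouping does not cover entity {missing[0]!r}")
    parents = pd.Series([grouping[e] for e in matrix.values.index], index=matrix.values.index)
    vals = matrix.values.groupby(parents, sort=True).median()
    intens = matrix.intensity.groupby(parents, sort=True).median()
    vals.index.name = intens.index.name = "entity"
    return RatioMatrix(level, vals, intens)


# ---------------------------------------------------------------------------
# 3-component Gaussian mixture and normalization


def fit_mixture3(ratios, cfg: ScalingConfig | None = None) -> MixtureFit:
    """Fit a 3-component Gaussian mixture by EM and locate its density mode.

    Deterministic initialization (component means at the 25th/50th/75th
    percentiles, equal weights, component SDs = overall SD), relative
    log-likelihood tolerance ``em_tol`` or ``em_max_iter`` iterations,
    SDs floored at ``sigma_floor``. The mode is the argmax of the fitted
    density over ``grid_points`` spanning mean +/- 6 SD, refined by one
    golden-section pass. Raises :class:`MixtureFallback` when fewer than
    ``min_points`` finite ratios are supplied.
    """
    cfg = cfg or ScalingConfig()
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < cfg.min_points:
        raise MixtureFallback(f"only {len(x)} ratios (< {cfg.min_points})")
    if np.ptp(x) == 0:
        c = float(x[0])
        return MixtureFit(
            weights=np.full(3, 1 / 3),
            means=np.full(3, c),
            sds=np.full(3, cfg.sigma_floor),
            loglik=float(np.sum(norm.logpdf(x, c, cfg.sigma_floor))),
            mode=c,
            n_iter=0,
            converged=True,
            loglik_trace=np.empty(0),
        )

    mu = np.percentile(x, [25, 50, 75]).astype(float)
    sd = np.full(3, max(float(np.std(x)), cfg.sigma_floor))
    w = np.full(3, 1 / 3)
    xx = x[:, None]
    trace = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.em_max_iter + 1):
        logp = np.log(w) + norm.logpdf(xx, mu, sd)
        ll_i = logsumexp(logp, axis=1)
        ll = float(ll_i.sum())
        trace.append(ll)
        r = np.exp(logp - ll_i[:, None])
        nk = r.sum(axis=0)
        w = nk / len(x)
        mu = (r * xx).sum(axis=0) / nk
        var = (r * (xx - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, cfg.sigma_floor**2))
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= cfg.em_tol * abs(ll):
            converged = True
            break
        ll_prev = ll
    fit = MixtureFit(
        weights=w,
        means=mu,
        sds=sd,
        loglik=trace[-1],
        mode=0.0,
        n_iter=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )
    fit.mode = _density_mode(fit, float(np.mean(x)), float(np.std(x)), cfg)
    return fit


def _density_mode(fit: MixtureFit, center: float, spread: float, cfg: ScalingConfig) -> float:
    spread = max(spread, cfg.sigma_floor)
    grid = np.linspace(center - 6 * spread, center + 6 * spread, cfg.grid_points)
    dens = fit.pdf(grid)
    i = int(np.argmax(dens))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i])
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda t: -fit.pdf(t), bounds=(lo, hi), method="bounded")
    best = float(res.x)
    return best if fit.pdf(best) >= dens[i] else float(grid[i])


@dataclass
class AlignmentInfo:
    """Per-sample alignment record: the subtracted shift, how it was
    obtained, and the mixture fit (None for median fallback)."""

    shift: float
    method: str  # "mixture_mode" | "median"
    fit: MixtureFit | None


def align_to_mode(matrix: RatioMatrix, cfg: ScalingConfig | None = None):
    """Center each sample's ratio distribution at its mixture-density mode.

    Returns the shifted matrix and a dict sample -> :class:`AlignmentInfo`.
    Samples with too few ratios for a mixture fit are centered at their
    median instead (warned).
    """
    cfg = cfg or ScalingConfig()
    out = matrix.copy()
    info: dict[str, AlignmentInfo] = {}
    for s in out.values.columns:
        col = out.values[s].to_numpy(dtype=float)
        obs = col[np.isfinite(col)]
        if len(obs) == 0:
            info[s] = AlignmentInfo(0.0, "median", None)
            continue
        try:
            fit = fit_mixture3(obs, cfg)
            shift = fit.mode
            info[s] = AlignmentInfo(shift, "mixture_mode", fit)
        except MixtureFallback:
            shift = float(np.median(obs))
            info[s] = AlignmentInfo(shift, "median", None)
            warnings.warn(
                f"sample {s!r}: too few ratios for mixture fit; centering at median",
                stacklevel=2,
            )
        out.values[s] = out.values[s] - shift
    return out, info


def trimmed_sd(ratios: np.ndarray, intensities: np.ndarray, trim_fraction: float) -> float:
    """SD of ratios after excluding the two-sided ``trim_fraction`` extremes
    of both the ratio values and the paired intensities (NaN-aware)."""
    m = np.isfinite(ratios)
    r = ratios[m]
    if len(r) < 2:
        return float("nan")
    keep = np.ones(len(r), dtype=bool)
    if trim_fraction > 0:
        q_lo, q_hi = np.quantile(r, [trim_fraction, 1 - trim_fraction])
        keep &= (r >= q_lo) & (r <= q_hi)
        it = intensities[m]
        fin = np.isfinite(it)
        if fin.any():
            i_lo, i_hi = np.quantile(it[fin], [trim_fraction, 1 - trim_fraction])
            keep &= fin & (it >= i_lo) & (it <= i_hi)
    if keep.sum() < 2:
        return float("nan")
    return float(np.std(r[keep], ddof=1))


def trimmed_scale(matrix: RatioMatrix, cfg: ScalingConfig | None = None):
    """Standardize each sample by its doubly trimmed SD.

    The SD excludes ratios in the top/bottom ``trim_fraction`` quantiles of
    ratio value and ratios of entities in the top/bottom quantiles of the
    sample's intensity; *all* of the sample's ratios are then divided by it.
    Returns the scaled matrix and a dict sample -> divisor (None when the
    trimmed SD was 0 or undefined, in which case the sample is left
    unscaled with a warning).
    """
    cfg = cfg or ScalingConfig()
    out = matrix.copy()
    divisors: dict[str, float | None] = {}
    for s in out.values.columns:
        sd = trimmed_sd(
            out.values[s].to_numpy(dtype=float),
            out.intensity[s].to_numpy(dtype=float),
            cfg.trim_fraction,
        )
        if not np.isfinite(sd) or sd == 0:
            divisors[s] = None
            warnings.warn(f"sample {s!r}: trimmed sd is 0/undefined; scaling skipped", stacklevel=2)
            continue
        out.values[s] = out.values[s] / sd
        divisors[s] = sd
    return out, divisors


# ---------------------------------------------------------------------------
# full pipeline


def run_quant_pipeline(
    psms,
    design: Design,
    fdr_cfg: FdrConfig | None = None,
    filter_cfg: FilterConfig | None = None,
    dixon_cfg: DixonConfig | None = None,
    scaling_cfg: ScalingConfig | None = None,
):
    """PSMs -> normalized protein log2-ratio matrix.

    Stages: target-decoy FDR filter -> parsimony inference -> shared/low-
    intensity PSM removal -> log2 reference ratios -> per-(peptide, sample)
    recursive Dixon removal -> PSM->peptide median roll-up -> peptide->
    protein median roll-up (accepted groups only) -> mixture-mode alignment
    -> trimmed scaling. Returns ``(RatioMatrix, provenance)`` where the
    provenance dict records counts removed at each stage, per-sample
    alignment shifts, and per-sample scaling divisors.
    """
    psms = list(psms)
    prov: dict = {"n_input_psms": len(psms)}
    confident = filter_psm_fdr(psms, fdr_cfg)
    prov["n_after_fdr"] = len(confident)
    groups = infer_proteins(confident)
    prov["n_groups"] = len(groups)
    prov["n_accepted_groups"] = sum(g.accepted for g in groups)
    clean = filter_psms(confident, groups, filter_cfg)
    prov["n_after_psm_filters"] = len(clean)

    samples = design.samples
    empty = lambda: RatioMatrix(
        "protein",
        pd.DataFrame(index=pd.Index([], name="entity"), columns=samples, dtype=float),
        pd.DataFrame(index=pd.Index([], name="entity"), columns=samples, dtype=float),
    )
    if not clean:
        prov.update(n_peptides=0, n_proteins=0, alignment={}, scaling={})
        return empty(), prov

    psm_matrix = compute_log2_ratios(clean, design)
    psm_to_pep = {p.psm_id: p.peptide_key for p in clean}
    psm_matrix = apply_dixon(psm_matrix, psm_to_pep, dixon_cfg)
    pep_matrix = rollup_median(psm_matrix, psm_to_pep, "peptide")
    prov["n_peptides"] = len(pep_matrix.values)

    pep_to_prot = razor_map(groups, accepted_only=True)
    quantifiable = [p for p in pep_matrix.values.index if p in pep_to_prot]
    prov["n_peptides_razor_assigned"] = len(quantifiable)
    if not quantifiable:
        prov.update(n_proteins=0, alignment={}, scaling={})
        return empty(), prov
    pep_matrix = RatioMatrix(
        "peptide",
        pep_matrix.values.loc[quantifiable],
        pep_matrix.intensity.loc[quantifiable],
    )
    prot_matrix = rollup_median(pep_matrix, pep_to_prot, "protein")
    prov["n_proteins"] = len(prot_matrix.values)

    aligned, align_info = align_to_mode(prot_matrix, scaling_cfg)
    prov["alignment"] = {
        s: {"shift": a.shift, "method": a.method} for s, a in align_info.items()
    }
    scaled, divisors = trimmed_scale(aligned, scaling_cfg)
    prov["scaling"] = divisors
    return scaled, prov
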