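"""Synthetic multi-plex TMT10 experiments with known ground truth.

The generator emulates the study design the analysis assumes: a 10-plex
with one pooled-reference channel (an equal mixture of all samples), 4 WT
vs 3 conditional-knockout samples, a minority of upregulated proteins
(with an optional small strongly-induced "stefin-like" block), shared
peptides, sub-threshold intensities, PSM-level outliers, and target/decoy
score distributions. Each dataset carries a truth table so planted effects
and artifacts are recoverable in tests.

Abundance model: protein abundance in sample s is
``base * 2^(log2FC * I[s is Cko])``; a peptide multiplies this by a
log-normal ionization efficiency; each PSM observes the product times
multiplicative log-normal measurement noise per channel. The reference
channel carries the mean of the sample intensities for that PSM (the
pooled-lysate reading), optionally with its own measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .psm_io import Design, PsmRecord

__all__ = [
    "TMT10_CHANNELS",
    "SimConfig",
    "TruthTable",
    "simulate_dataset",
    "simulate_null",
    "simulate_two_groups",
    "simulate_protein_matrix",
]

TMT10_CHANNELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131")

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulated TMT experiment."""

    seed: int = 0
    n_plexes: int = 1
    channels_per_plex: int = 10
    n_ref_channels: int = 1
    n_wt: int = 4
    n_cko: int = 3
    n_proteins: int = 1000
    frac_de: float = 0.10
    log2fc: float = 1.0
    n_stefin_block: int = 0  # extra strongly induced proteins
    stefin_log2fc: float = 2.0
    peptides_per_protein_mean: float = 3.0  # 1 + Poisson(mean - 1)
    psms_per_peptide_mean: float = 2.0
    frac_shared_peptides: float = 0.05
    log10_base_intensity_loc: float = 4.5
    log10_base_intensity_scale: float = 0.6
    frac_sub_threshold: float = 0.05
    psm_noise_sd: float = 0.3  # log2 scale
    outlier_prob: float = 0.02
    outlier_shift_range: tuple[float, float] = (2.0, 4.0)
    decoy_frac: float = 0.3
    target_score: tuple[float, float] = (40.0, 8.0)  # mean, sd
    decoy_score: tuple[float, float] = (18.0, 6.0)
    efficiency_log2_sd: float = 1.0
    frac_modified: float = 0.10
    noisy_reference: bool = False  # independent measurement noise on the ref channel

    def __post_init__(self):
        for name in ("frac_de", "frac_shared_peptides", "frac_sub_threshold", "outlier_prob", "decoy_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_wt + self.n_cko > self.channels_per_plex - self.n_ref_channels:
            raise ValueError(
                f"{self.n_wt}+{self.n_cko} samples do not fit in "
                f"{self.channels_per_plex - self.n_ref_channels} non-reference channels"
            )
        if self.channels_per_plex > len(TMT10_CHANNELS):
            raise ValueError("at most 10 channels per plex")


@dataclass
class TruthTable:
    """Ground truth: per-protein planted effect and per-PSM artifact flags."""

    proteins: pd.DataFrame  # accession, log2fc, is_de, is_stefin_block
    psms: pd.DataFrame  # psm_id, is_outlier, is_shared, is_sub_threshold


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 16))
    return "".join(rng.choice(_AA, size=length)) + "K"


def _make_design(cfg: SimConfig) -> Design:
    rows = []
    channels = TMT10_CHANNELS[: cfg.channels_per_plex]
    for px in range(1, cfg.n_plexes + 1):
        plex = f"plex{px}"
        for ch in channels[: cfg.n_ref_channels]:
            rows.append((plex, ch, f"{plex}_ref", "Reference", True))
        conditions = ["WT"] * cfg.n_wt + ["Cko"] * cfg.n_cko
        counters = {"WT": 0, "Cko": 0}
        for ch, cond in zip(channels[cfg.n_ref_channels :], conditions):
            counters[cond] += 1
            rows.append((plex, ch, f"{plex}_{cond}{counters[cond]}", cond, False))
    return Design(
        pd.DataFrame(rows, columns=["plex_id", "channel_label", "sample_id", "condition", "is_reference"])
    )


def simulate_dataset(cfg: SimConfig) -> tuple[list[PsmRecord], Design, TruthTable]:
    """Generate (PSM records, design, truth) deterministically from cfg.seed.

    One master RNG drives the protein-independent draws; each protein's
    peptides/PSMs come from a substream seeded by (seed, protein index) so
    partial regeneration is reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)

    n = cfg.n_proteins
    accs = [f"PROT{i:05d}" for i in range(n)]
    is_stefin = np.zeros(n, dtype=bool)
    is_stefin[: min(cfg.n_stefin_block, n)] = True
    is_de = rng.random(n) < cfg.frac_de
    is_de |= is_stefin
    log2fc = np.where(is_de, cfg.log2fc, 0.0)
    log2fc = np.where(is_stefin, cfg.stefin_log2fc, log2fc)
    truth_prot = pd.DataFrame(
        {"accession": accs, "log2fc": log2fc, "is_de": is_de, "is_stefin_block": is_stefin}
    )

    channels = TMT10_CHANNELS[: cfg.channels_per_plex]
    ref_channels = channels[: cfg.n_ref_channels]
    plex_samples = {px: design.sample_channels(px) for px in design.plexes}
    cond_of = {s: design.condition_of(s) for s in design.samples}

    records: list[PsmRecord] = []
    truth_rows = []
    psm_counter = 0
    for i in range(n):
        prng = np.random.default_rng([cfg.seed, i])
        base = 10.0 ** prng.normal(cfg.log10_base_intensity_loc, cfg.log10_base_intensity_scale)
        n_pep = 1 + prng.poisson(max(cfg.peptides_per_protein_mean - 1, 0))
        for _ in range(n_pep):
            seq = _random_peptide(prng)
            shared = prng.random() < cfg.frac_shared_peptides and n > 1
            proteins = {accs[i]}
            if shared:
                j = int(prng.integers(n - 1))
                proteins.add(accs[j if j < i else j + 1])
            eff = 2.0 ** prng.normal(0.0, cfg.efficiency_log2_sd)
            mod = "Oxidation (M)" if prng.random() < cfg.frac_modified else ""
            n_psm = 1 + prng.poisson(max(cfg.psms_per_peptide_mean - 1, 0))
            for _ in range(n_psm):
                psm_counter += 1
                psm_id = f"PSM{psm_counter:07d}"
                plex = design.plexes[int(prng.integers(len(design.plexes)))]
                sample_chs = plex_samples[plex]
                intens: dict[str, float] = {}
                sample_vals = []
                for ch, sample in sample_chs:
                    fc = log2fc[i] if cond_of[sample] == "Cko" else 0.0
                    noise = 2.0 ** prng.normal(0.0, cfg.psm_noise_sd) if cfg.psm_noise_sd > 0 else 1.0
                    v = base * (2.0**fc) * eff * noise
                    intens[ch] = v
                    sample_vals.append(v)
                is_outlier = prng.random() < cfg.outlier_prob
                if is_outlier and sample_chs:
                    k = int(prng.integers(len(sample_chs)))
                    lo, hi = cfg.outlier_shift_range
                    shift = prng.uniform(lo, hi) * (1 if prng.random() < 0.5 else -1)
                    ch_k = sample_chs[k][0]
                    intens[ch_k] *= 2.0**shift
                    sample_vals[k] = intens[ch_k]
                ref_val = float(np.mean(sample_vals)) if sample_vals else 0.0
                for ch in ref_channels:
                    noise = (
                        2.0 ** prng.normal(0.0, cfg.psm_noise_sd)
                        if cfg.noisy_reference and cfg.psm_noise_sd > 0
                        else 1.0
                    )
                    intens[ch] = ref_val * noise
                is_sub = prng.random() < cfg.frac_sub_threshold
                if is_sub:
                    mean_now = float(np.mean([v for v in intens.values() if v > 0])) or 1.0
                    scale = prng.uniform(50.0, 900.0) / mean_now
                    intens = {ch: v * scale for ch, v in intens.items()}
                score = float(prng.normal(*cfg.target_score))
                records.append(
                    PsmRecord(
                        psm_id=psm_id,
                        peptide_seq=seq,
                        mod_string=mod,
                        proteins=frozenset(proteins),
                        plex_id=plex,
                        intensities=intens,
                        score=score,
                        is_decoy=False,
                    )
                )
                truth_rows.append((psm_id, is_outlier, shared, is_sub))

    n_decoys = int(round(cfg.decoy_frac * len(records)))
    for _ in range(n_decoys):
        psm_counter += 1
        psm_id = f"PSM{psm_counter:07d}"
        plex = design.plexes[int(rng.integers(len(design.plexes)))]
        intens = {ch: float(10.0 ** rng.normal(3.0, 0.5)) for ch in channels}
        records.append(
            PsmRecord(
                psm_id=psm_id,
                peptide_seq=_random_peptide(rng),
                mod_string="",
                proteins=frozenset({f"REV_PROT{int(rng.integers(n)):05d}"}),
                plex_id=plex,
                intensities=intens,
                score=float(rng.normal(*cfg.decoy_score)),
                is_decoy=True,
            )
        )
        truth_rows.append((psm_id, False, False, False))

    truth_psm = pd.DataFrame(truth_rows, columns=["psm_id", "is_outlier", "is_shared", "is_sub_threshold"])
    return records, design, TruthTable(truth_prot, truth_psm)


def simulate_null(cfg: SimConfig) -> tuple[list[PsmRecord], Design, TruthTable]:
    """Same generative process with every planted effect switched off."""
    return simulate_dataset(replace(cfg, frac_de=0.0, n_stefin_block=0))


def simulate_two_groups(n_a: int, n_b: int, shift: float, seed: int, sd: float = 1.0):
    """Two Gaussian samples with group_b shifted by ``shift`` (for the
    small-sample test statistics)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, size=n_a), rng.normal(shift, sd, size=n_b)


def simulate_protein_matrix(
    n_proteins: int,
    n_a: int,
    n_b: int,
    seed: int,
    frac_de: float = 0.0,
    log2fc: float = 1.0,
    sd: float = 1.0,
    var_prior_df: float = 10.0,
):
    """Protein-level ratio matrix with planted group effects, for
    calibration studies needing many replicates.

    Per-protein variances are drawn from the scaled inverse-chi-square
    family, ``sigma_g^2 = sd^2 * var_prior_df / chi2(var_prior_df)``,
    mirroring the variance heterogeneity of real roll-up output (proteins
    differ in peptide/PSM support); ``var_prior_df=inf`` gives constant
    variance ``sd^2``. Entries are centered Gaussians with the planted
    log2FC added to group-A columns of DE proteins. Returns
    ``(values DataFrame, de_mask)`` with columns ``A1..`` then ``B1..``.
    """
    rng = np.random.default_rng(seed)
    cols = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    if np.isinf(var_prior_df):
        sig = np.full(n_proteins, float(sd))
    else:
        sig = sd * np.sqrt(var_prior_df / rng.chisquare(var_prior_df, n_proteins))
    X = rng.normal(0.0, 1.0, size=(n_proteins, n_a + n_b)) * sig[:, None]
    de = rng.random(n_proteins) < frac_de
    X[de, :n_a] += log2fc
    idx = pd.Index([f"PROT{i:05d}" for i in range(n_proteins)], name="entity")
    return pd.DataFrame(X, index=idx, columns=cols), de
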