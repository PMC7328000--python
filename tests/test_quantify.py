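import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from tmtrollup.identification import ProteinGroup
from tmtrollup.psm_io import Design, PsmRecord
from tmtrollup.quantify import (
    DixonConfig,
    FilterConfig,
    MixtureFallback,
    RatioMatrix,
    ScalingConfig,
    align_to_mode,
    apply_dixon,
    compute_log2_ratios,
    dixon_q,
    filter_psms,
    fit_mixture3,
    remove_outliers_recursive,
    rollup_median,
    run_quant_pipeline,
    trimmed_scale,
    trimmed_sd,
)
from tmtrollup.synthetic_data import SimConfig, simulate_dataset


def _design():
    return Design(
        pd.DataFrame(
            {
                "plex_id": ["plex1"] * 4,
                "channel_label": ["126", "127N", "127C", "128N"],
                "sample_id": ["ref", "ref2", "s1", "s2"],
                "condition": ["Reference", "Reference", "WT", "Cko"],
                "is_reference": [True, True, False, False],
            }
        )
    )


def _psm(pid, intens, proteins=("A",), seq="PEPK", plex="plex1"):
    return PsmRecord(pid, seq, "", frozenset(proteins), plex, intens, 10.0, False)


def _group(lead, members=(), razor=(), accepted=True):
    return ProteinGroup(lead, set(members), set(razor), set(), accepted)


class TestFilterPsms:
    def test_low_mean_intensity_removed(self):
        psm = _psm("1", {"126": 999.9, "127N": 999.9})
        groups = [_group("A", razor={"PEPK"})]
        assert filter_psms([psm], groups) == []

    def test_shared_between_accepted_groups_removed(self):
        psm = _psm("1", {"126": 1e6}, proteins=("A", "B"))
        groups = [_group("A"), _group("B")]
        assert filter_psms([psm], groups) == []

    def test_unique_above_threshold_kept(self):
        psm = _psm("1", {"126": 1500.0})
        groups = [_group("A")]
        assert filter_psms([psm], groups) == [psm]

    def test_shared_within_one_group_kept(self):
        psm = _psm("1", {"126": 1e5}, proteins=("A", "B"))
        groups = [_group("A", members={"B"})]
        assert filter_psms([psm], groups) == [psm]


class TestLog2Ratios:
    def test_equal_to_reference_gives_zero(self):
        m = compute_log2_ratios(
            [_psm("1", {"126": 1000.0, "127N": 1000.0, "127C": 1000.0})], _design()
        )
        assert m.values.loc["1", "s1"] == pytest.approx(0.0)

    def test_double_reference_gives_one(self):
        m = compute_log2_ratios(
            [_psm("1", {"126": 1000.0, "127N": 1000.0, "127C": 2000.0})], _design()
        )
        assert m.values.loc["1", "s1"] == pytest.approx(1.0)
        assert m.intensity.loc["1", "s1"] == pytest.approx(2000.0)

    def test_zero_intensity_is_missing(self):
        m = compute_log2_ratios(
            [_psm("1", {"126": 1000.0, "127N": 1000.0, "127C": 0.0, "128N": 500.0})],
            _design(),
        )
        assert np.isnan(m.values.loc["1", "s1"])
        assert m.values.loc["1", "s2"] == pytest.approx(-1.0)

    def test_unknown_plex_raises(self):
        with pytest.raises(KeyError, match="plexX"):
            compute_log2_ratios([_psm("1", {"126": 1.0}, plex="plexX")], _design())


class TestDixonQ:
    def test_high_outlier_r10(self):
        q, idx = dixon_q([1.0, 2.0, 10.0])
        assert idx == 2
        assert q == pytest.approx((10 - 2) / (10 - 1))

    def test_low_outlier_r10(self):
        q, idx = dixon_q([-10.0, 1.0, 2.0])
        assert idx == 0
        assert q == pytest.approx((1 - (-10)) / (2 - (-10)))

    def test_constant_vector_no_test(self):
        assert dixon_q([0.0, 0.0, 0.0]) is None

    def test_short_vector_no_test(self):
        assert dixon_q([1.0, 2.0]) is None

    def test_critical_values_strictly_decreasing_within_ranges(self):
        crit = DixonConfig().critical_values
        for lo, hi in [(3, 7), (8, 10), (11, 13), (14, 30)]:
            vals = [crit[n] for n in range(lo, hi + 1)]
            assert all(a > b for a, b in zip(vals, vals[1:]))


def _brute_force_dixon(values, crit):
    """Naive loop reimplementation of the recursive removal."""
    vals = list(enumerate(values))
    removed = set()
    while True:
        current = [(i, v) for i, v in vals if i not in removed]
        n = len(current)
        if n < 3 or n > 30:
            break
        xs = sorted(v for _, v in current)
        if xs[-1] == xs[0]:
            break

        def r(num, den):
            return num / den if den > 0 else 0.0

        if n <= 7:
            lo, hi = r(xs[1] - xs[0], xs[-1] - xs[0]), r(xs[-1] - xs[-2], xs[-1] - xs[0])
        elif n <= 10:
            lo, hi = r(xs[1] - xs[0], xs[-2] - xs[0]), r(xs[-1] - xs[-2], xs[-1] - xs[1])
        elif n <= 13:
            lo, hi = r(xs[2] - xs[0], xs[-2] - xs[0]), r(xs[-1] - xs[-3], xs[-1] - xs[1])
        else:
            lo, hi = r(xs[2] - xs[0], xs[-3] - xs[0]), r(xs[-1] - xs[-3], xs[-1] - xs[2])
        if hi >= lo:
            q = hi
            suspect = next(t for t in current if t[1] == max(v for _, v in current))
        else:
            q = lo
            suspect = next(t for t in current if t[1] == min(v for _, v in current))
        if q > crit[n]:
            removed.add(suspect[0])
        else:
            break
    return [i not in removed for i in range(len(values))]


class TestRecursiveRemoval:
    def test_no_outlier_in_tight_triple(self):
        assert remove_outliers_recursive([1.0, 1.1, 0.9]).all()

    def test_two_step_recursion_removes_only_extreme(self):
        keep = remove_outliers_recursive([0.0, 0.1, 0.05, 8.0])
        assert keep.tolist() == [True, True, True, False]

    def test_pairs_returned_unchanged(self):
        assert remove_outliers_recursive([0.0, 100.0]).all()

    def test_oversized_vectors_untouched(self):
        v = np.r_[np.zeros(34), 50.0]
        assert remove_outliers_recursive(v).all()

    def test_agrees_with_brute_force_on_small_integer_vectors(self):
        """Exhaustive over all sorted multisets of length 3-4 with entries
        0..9, in a shuffled order, plus a random sample of longer ones."""
        cfg = DixonConfig()
        rng = np.random.default_rng(7)
        cases = []
        for n in (3, 4):
            for combo in itertools.combinations_with_replacement(range(10), n):
                cases.append(list(combo))
        for n in (5, 6):
            for _ in range(400):
                cases.append(rng.integers(0, 10, size=n).tolist())
        for base in cases:
            v = list(base)
            rng.shuffle(v)
            got = remove_outliers_recursive(np.array(v, dtype=float), cfg).tolist()
            want = _brute_force_dixon(v, cfg.critical_values)
            assert got == want, f"disagreement on {v}"


class TestRollup:
    def _matrix(self, vals, intens=None):
        idx = pd.Index([f"c{i}" for i in range(len(vals))], name="entity")
        v = pd.DataFrame({"s1": vals}, index=idx)
        it = pd.DataFrame({"s1": intens if intens is not None else np.ones(len(vals))}, index=idx)
        return RatioMatrix("psm", v, it)

    def test_constant_children(self):
        m = rollup_median(self._matrix([1.0, 1.0, 1.0]), {f"c{i}": "P" for i in range(3)}, "peptide")
        assert m.values.loc["P", "s1"] == pytest.approx(1.0)

    def test_odd_median(self):
        m = rollup_median(self._matrix([0.0, 0.4, 1.0]), {f"c{i}": "P" for i in range(3)}, "peptide")
        assert m.values.loc["P", "s1"] == pytest.approx(0.4)

    def test_median_ignores_missing(self):
        m = rollup_median(self._matrix([0.0, np.nan, 1.0]), {f"c{i}": "P" for i in range(3)}, "peptide")
        assert m.values.loc["P", "s1"] == pytest.approx(0.5)

    def test_uncovered_entity_raises(self):
        with pytest.raises(KeyError):
            rollup_median(self._matrix([1.0]), {}, "peptide")

    def test_monotone_in_children(self):
        g = {f"c{i}": "P" for i in range(3)}
        lo = rollup_median(self._matrix([0.0, 0.4, 1.0]), g, "peptide").values.loc["P", "s1"]
        hi = rollup_median(self._matrix([0.0, 0.9, 1.0]), g, "peptide").values.loc["P", "s1"]
        assert hi >= lo

    def test_intensity_rolled_as_median(self):
        m = rollup_median(
            self._matrix([0.0, 0.0, 0.0], intens=[10.0, 20.0, 80.0]),
            {f"c{i}": "P" for i in range(3)},
            "peptide",
        )
        assert m.intensity.loc["P", "s1"] == pytest.approx(20.0)


class TestMixture:
    def test_single_gaussian_mode_near_mean(self):
        rng = np.random.default_rng(0)
        fit = fit_mixture3(rng.normal(0.7, 1.0, 10_000))
        assert fit.mode == pytest.approx(0.7, abs=0.05)

    def test_constant_data_degenerate(self):
        fit = fit_mixture3(np.zeros(100))
        assert fit.mode == 0.0
        assert (fit.sds == ScalingConfig().sigma_floor).all()

    def test_bimodal_mode_at_tallest_component(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(-2.0, 0.3, 5_000), rng.normal(0.0, 0.3, 5_000)]
        fit = fit_mixture3(x)
        assert min(abs(fit.mode - 0.0), abs(fit.mode - (-2.0))) < 0.1
        grid = np.linspace(-4, 2, 4001)
        assert fit.pdf(fit.mode) >= fit.pdf(grid).max() - 1e-9

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(-1, 0.5, 300), rng.normal(1, 0.8, 500)]
        fit = fit_mixture3(x)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-7 * np.abs(fit.loglik_trace[1:])).all()

    def test_too_few_points_signals_fallback(self):
        with pytest.raises(MixtureFallback):
            fit_mixture3(np.arange(5.0))

    def test_matches_sklearn_from_same_start(self):
        """Same EM problem handed to scikit-learn from the identical
        initialization reaches the same log-likelihood and a nearby mode."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(-0.5, 0.4, 2_000), rng.normal(0.6, 0.7, 3_000)]
        fit = fit_mixture3(x)
        means_init = np.percentile(x, [25, 50, 75]).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=3,
            weights_init=np.full(3, 1 / 3),
            means_init=means_init,
            precisions_init=(1 / np.var(x)) * np.ones((3, 1, 1)),
            tol=1e-8,
            max_iter=2000,
            reg_covar=1e-10,
        ).fit(x.reshape(-1, 1))
        sk_ll = gm.score(x.reshape(-1, 1)) * len(x)
        assert fit.loglik == pytest.approx(sk_ll, rel=1e-4)


class TestNormalization:
    def _protein_matrix(self, rng, shift=0.0, scale=1.0, n=10_000):
        vals = rng.normal(shift, scale, size=(n, 2))
        intens = rng.lognormal(8, 1, size=(n, 2))
        idx = pd.Index([f"P{i}" for i in range(n)], name="entity")
        return RatioMatrix(
            "protein",
            pd.DataFrame(vals, index=idx, columns=["s1", "s2"]),
            pd.DataFrame(intens, index=idx, columns=["s1", "s2"]),
        )

    def test_alignment_removes_shift(self):
        rng = np.random.default_rng(4)
        m = self._protein_matrix(rng, shift=0.5)
        aligned, info = align_to_mode(m)
        assert info["s1"].method == "mixture_mode"
        assert info["s1"].shift == pytest.approx(0.5, abs=0.06)
        refit = fit_mixture3(aligned.values["s1"].dropna().to_numpy())
        assert abs(refit.mode) <= 0.01

    def test_alignment_idempotent_when_centered(self):
        rng = np.random.default_rng(5)
        m = self._protein_matrix(rng, shift=0.0)
        _, info = align_to_mode(m)
        assert abs(info["s1"].shift) < 0.06

    def test_alignment_independent_per_sample(self):
        rng = np.random.default_rng(6)
        m = self._protein_matrix(rng)
        m.values["s1"] += 1.0
        m.values["s2"] -= 1.0
        _, info = align_to_mode(m)
        assert info["s1"].shift == pytest.approx(1.0, abs=0.08)
        assert info["s2"].shift == pytest.approx(-1.0, abs=0.08)

    def test_few_ratios_fall_back_to_median(self):
        idx = pd.Index([f"P{i}" for i in range(5)], name="entity")
        m = RatioMatrix(
            "protein",
            pd.DataFrame({"s1": [0.0, 1.0, 2.0, 3.0, 4.0]}, index=idx),
            pd.DataFrame({"s1": np.ones(5)}, index=idx),
        )
        with pytest.warns(UserWarning, match="median"):
            _, info = align_to_mode(m)
        assert info["s1"].method == "median"
        assert info["s1"].shift == pytest.approx(2.0)

    def test_trimmed_scale_unit_sd_afterwards(self):
        rng = np.random.default_rng(7)
        m = self._protein_matrix(rng, scale=2.0, n=10_000)
        scaled, divisors = trimmed_scale(m)
        cfg = ScalingConfig()
        for s in ("s1", "s2"):
            sd = trimmed_sd(
                scaled.values[s].to_numpy(), scaled.intensity[s].to_numpy(), cfg.trim_fraction
            )
            assert sd == pytest.approx(1.0, abs=1e-6)
            # 5% two-sided value trimming shrinks a Gaussian SD to
            # sigma * sqrt(1 - 2 z f(z) / 0.9) with z = 1.645
            from scipy.stats import norm as _norm

            z = _norm.ppf(0.95)
            factor = np.sqrt(1 - 2 * z * _norm.pdf(z) / 0.9)
            assert divisors[s] == pytest.approx(2.0 * factor, rel=0.03)

    def test_constant_ratios_skip_scaling(self):
        idx = pd.Index([f"P{i}" for i in range(40)], name="entity")
        m = RatioMatrix(
            "protein",
            pd.DataFrame({"s1": np.ones(40)}, index=idx),
            pd.DataFrame({"s1": np.ones(40)}, index=idx),
        )
        with pytest.warns(UserWarning, match="skipped"):
            scaled, divisors = trimmed_scale(m)
        assert divisors["s1"] is None
        assert (scaled.values["s1"] == 1.0).all()

    def test_zero_trim_reduces_to_plain_z_scaling(self):
        rng = np.random.default_rng(8)
        m = self._protein_matrix(rng, scale=3.0)
        scaled, divisors = trimmed_scale(m, ScalingConfig(trim_fraction=0.0))
        for s in ("s1", "s2"):
            assert divisors[s] == pytest.approx(
                np.std(m.values[s].to_numpy(), ddof=1), rel=1e-12
            )


class TestPipeline:
    def test_null_dataset_mode_zero_sd_one(self):
        cfg = SimConfig(seed=21, n_proteins=400, frac_de=0.0)
        psms, design, _ = simulate_dataset(cfg)
        matrix, prov = run_quant_pipeline(psms, design)
        scfg = ScalingConfig()
        for s in matrix.values.columns:
            obs = matrix.values[s].dropna().to_numpy()
            refit = fit_mixture3(obs, scfg)
            # mode was zeroed before scaling; on the scaled (unit-sd)
            # ratios it must still sit near zero
            assert abs(refit.mode) <= 0.15
            assert trimmed_sd(obs, matrix.intensity[s].dropna().to_numpy(), 0.05) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_planted_upregulation_detected_in_direction(self, default_dataset, default_pipeline):
        _, _, design, truth = default_dataset
        matrix, _ = default_pipeline
        tp = truth.proteins.set_index("accession")
        common = matrix.values.index.intersection(tp.index)
        de = tp.loc[common, "is_de"]
        cko = [s for s in design.samples_for("Cko") if s in matrix.values.columns]
        wt = [s for s in design.samples_for("WT") if s in matrix.values.columns]
        est = matrix.values.loc[common, cko].mean(axis=1) - matrix.values.loc[common, wt].mean(axis=1)
        assert est[de].mean() > 0
        assert (est[de] > 0).mean() > 0.95

    def test_psm_order_permutation_invariant(self):
        cfg = SimConfig(seed=9, n_proteins=60)
        psms, design, _ = simulate_dataset(cfg)
        m1, _ = run_quant_pipeline(psms, design)
        rng = np.random.default_rng(0)
        shuffled = list(psms)
        rng.shuffle(shuffled)
        m2, _ = run_quant_pipeline(shuffled, design)
        pd.testing.assert_frame_equal(
            m1.values.sort_index(), m2.values.sort_index(), check_like=True
        )

    def test_empty_input(self):
        cfg = SimConfig(seed=1, n_proteins=10)
        _, design, _ = simulate_dataset(cfg)
        matrix, prov = run_quant_pipeline([], design)
        assert matrix.values.empty
        assert prov["n_input_psms"] == 0
        assert prov["n_proteins"] == 0

    def test_provenance_counts_monotone(self, default_pipeline):
        _, prov = default_pipeline
        assert prov["n_input_psms"] >= prov["n_after_fdr"] >= prov["n_after_psm_filters"]
        assert prov["n_proteins"] <= prov["n_peptides"]


def test_dixon_masking_per_peptide_channel():
    idx = pd.Index(["a", "b", "c", "d"], name="entity")
    vals = pd.DataFrame({"s1": [0.0, 0.1, 0.05, 8.0]}, index=idx)
    m = RatioMatrix("psm", vals, pd.DataFrame(np.ones((4, 1)), index=idx, columns=["s1"]))
    out = apply_dixon(m, {k: "pep1" for k in idx})
    assert np.isnan(out.values.loc["d", "s1"])
    assert out.values.loc["a", "s1"] == 0.0
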