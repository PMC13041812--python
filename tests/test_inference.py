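import numpy as np
import pandas as pd
import pytest

from riskseq.inference import (
    BootstrapBands,
    GEEFit,
    ModelSpec,
    bootstrap_timecourse,
    bspline_basis,
    build_design,
    fit_gee,
    interaction_columns,
    one_sample_significance,
    pairwise_band_difference,
    simulate_units,
    wald_joint,
)
from riskseq.perievent import AlignmentRule, PeriEventUnit
from riskseq.sequences import SEQ_CC, SEQ_GO, SEQ_NOGO

BIN_TIMES = AlignmentRule().bin_centers


def flat_units(n_animals=4, upa=3, types=(SEQ_CC, SEQ_NOGO, SEQ_GO), seed=0, sd=1.0):
    profiles = {tp: np.zeros(90) for tp in types}
    return simulate_units(n_animals, upa, profiles, BIN_TIMES, rho=0.5, noise_sd=sd, seed=seed)


class TestDesign:
    def test_default_spec_fifteen_columns(self):
        design, y, groups, tidx = build_design(flat_units())
        assert design.shape[1] == 15
        assert list(design.columns)[0] == "Intercept"
        assert len(interaction_columns()) == 8

    def test_single_level_five_columns(self):
        spec = ModelSpec(sequence_levels=(SEQ_CC,))
        units = flat_units(types=(SEQ_CC,))
        design, _, _, _ = build_design(units, spec)
        assert design.shape[1] == 5

    def test_row_count_units_times_bins(self):
        # 612 units x 90 bins -> 55,080 rows
        rng = np.random.default_rng(0)
        units = []
        for i in range(612):
            units.append(
                PeriEventUnit(
                    animal=f"m{i % 14}", hemisphere="left", event=i,
                    sequence_type=(SEQ_CC, SEQ_NOGO, SEQ_GO)[i % 3],
                    bin_times=BIN_TIMES, values=rng.normal(size=90),
                )
            )
        design, y, groups, _ = build_design(units)
        assert design.shape[0] == 612 * 90 == 55080
        assert len(np.unique(groups)) == 612

    def test_missing_level_rejected(self):
        units = flat_units(types=(SEQ_CC, SEQ_NOGO))
        with pytest.raises(ValueError, match="Go"):
            build_design(units, ModelSpec())

    def test_basis_partition_of_unity_with_intercept(self):
        x = np.linspace(-3, 3, 90)
        B = bspline_basis(x, df=4)
        assert B.shape == (90, 4)
        full = bspline_basis(x, df=4)
        # together with the dropped first function the basis sums to 1;
        # check the returned columns are within [0, 1] and well-conditioned
        assert (B >= -1e-12).all() and (B <= 1 + 1e-12).all()
        X = np.column_stack([np.ones(90), B])
        assert np.linalg.matrix_rank(X) == 5


class TestFit:
    def test_rank_deficiency_names_columns(self):
        design, y, groups, tidx = build_design(flat_units())
        design["dup"] = design["s1"]
        with pytest.raises(ValueError, match="dup|s1"):
            fit_gee(design, y, groups, tidx)

    def test_white_noise_rho_near_zero(self):
        profiles = {tp: np.zeros(90) for tp in (SEQ_CC, SEQ_NOGO, SEQ_GO)}
        units = simulate_units(20, 5, profiles, BIN_TIMES, rho=0.0, noise_sd=1.0, seed=1)
        design, y, groups, tidx = build_design(units)
        fit = fit_gee(design, y, groups, tidx)
        assert abs(fit.ar1_rho) < 0.05

    def test_rho_recovery(self):
        profiles = {tp: np.zeros(90) for tp in (SEQ_CC, SEQ_NOGO, SEQ_GO)}
        units = simulate_units(20, 5, profiles, BIN_TIMES, rho=0.9, noise_sd=1.0, seed=2)
        design, y, groups, tidx = build_design(units)
        fit = fit_gee(design, y, groups, tidx)
        assert fit.ar1_rho == pytest.approx(0.9, abs=0.05)
        assert abs(fit.ar1_rho) < 1

    def test_beta_recovery_within_robust_ses(self):
        # response built from known coefficients + AR(1) noise: estimates
        # land within 3 robust SEs for >= 95% of coefficients over reps
        rng = np.random.default_rng(3)
        hits = total = 0
        for rep in range(5):
            units = flat_units(n_animals=10, upa=10, seed=100 + rep)
            design, _, groups, tidx = build_design(units)
            beta = rng.normal(0, 0.5, design.shape[1])
            noise = np.concatenate(
                [u.values for u in units]
            )  # AR(1) noise from the simulated units
            y = design.to_numpy() @ beta + noise
            fit = fit_gee(design, y, groups, tidx)
            se = fit.robust_se().to_numpy()
            hits += int((np.abs(fit.params.to_numpy() - beta) <= 3 * se).sum())
            total += design.shape[1]
        assert hits / total >= 0.95

    def test_covariance_matrices_symmetric_psd(self):
        design, y, groups, tidx = build_design(flat_units(seed=5))
        fit = fit_gee(design, y, groups, tidx)
        for cov in (fit.cov, fit.cov_naive, fit.cov_bc):
            V = cov.to_numpy()
            assert np.allclose(V, V.T, atol=1e-10)
            assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_sandwich_close_to_model_based_when_correlation_true(self):
        # with a correctly specified AR(1) working correlation the
        # sandwich and model-based variances agree at large n
        profiles = {tp: np.zeros(90) for tp in (SEQ_CC, SEQ_NOGO, SEQ_GO)}
        units = simulate_units(100, 3, profiles, BIN_TIMES, rho=0.8, noise_sd=1.0, seed=7)
        design, y, groups, tidx = build_design(units)
        fit = fit_gee(design, y, groups, tidx)
        ratio = np.diag(fit.cov.to_numpy()) / np.diag(fit.cov_naive.to_numpy())
        assert abs(np.median(ratio) - 1) < 0.10


class TestWald:
    def make_fit(self, params, variances):
        cols = list(params)
        V = pd.DataFrame(np.diag(variances), index=cols, columns=cols)
        return GEEFit(
            params=pd.Series(params), cov=V, cov_naive=V, cov_bc=V,
            ar1_rho=0.0, n_units=50, n_obs=4500, converged=True,
        )

    def test_null_block_statistic_zero(self):
        fit = self.make_fit({"a": 0.0, "b": 0.0}, [1e-8, 1e-8])
        res = wald_joint(fit, ["a", "b"])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_df_equals_block_size(self):
        fit = self.make_fit({"a": 1.0, "b": 2.0, "c": 0.5}, [0.1, 0.1, 0.1])
        assert wald_joint(fit, ["a", "b"]).df == 2

    def test_empty_selection_rejected(self):
        fit = self.make_fit({"a": 1.0}, [0.1])
        with pytest.raises(ValueError, match="empty"):
            wald_joint(fit, [])

    def test_unknown_column_rejected(self):
        fit = self.make_fit({"a": 1.0}, [0.1])
        with pytest.raises(ValueError, match="unknown"):
            wald_joint(fit, ["zzz"])

    def test_pairwise_contrast_df_four(self):
        units = flat_units(n_animals=6, upa=5, seed=9)
        design, y, groups, tidx = build_design(units)
        fit = fit_gee(design, y, groups, tidx)
        cols = [f"type[{SEQ_GO}]:s{j + 1}" for j in range(4)]
        assert wald_joint(fit, cols).df == 4

    def test_invariance_under_reference_swap(self):
        # the joint interaction test is unchanged when the reference
        # level changes (same column space)
        units = flat_units(n_animals=6, upa=5, seed=11)
        stats = []
        for levels in ((SEQ_CC, SEQ_NOGO, SEQ_GO), (SEQ_NOGO, SEQ_GO, SEQ_CC)):
            spec = ModelSpec(sequence_levels=levels)
            design, y, groups, tidx = build_design(units, spec)
            fit = fit_gee(design, y, groups, tidx)
            stats.append(wald_joint(fit, interaction_columns(spec)).statistic)
        assert stats[0] == pytest.approx(stats[1], rel=1e-4)


class TestBootstrap:
    def test_identical_constant_units_collapse(self):
        units = [
            PeriEventUnit(
                animal=f"m{a}", hemisphere="left", event=e, sequence_type=SEQ_CC,
                bin_times=BIN_TIMES, values=np.full(90, 1.5),
            )
            for a in range(4)
            for e in range(3)
        ]
        bands = bootstrap_timecourse(units, n_resamples=200, seed=0)
        assert np.allclose(bands.lo95[SEQ_CC], 1.5)
        assert np.allclose(bands.hi99[SEQ_CC], 1.5)
        assert np.allclose(bands.mean[SEQ_CC], 1.5)

    def test_same_seed_bit_identical(self):
        units = flat_units(seed=13)
        b1 = bootstrap_timecourse(units, n_resamples=300, seed=5)
        b2 = bootstrap_timecourse(units, n_resamples=300, seed=5)
        for tp in b1.types:
            assert np.array_equal(b1.lo95[tp], b2.lo95[tp])
            assert np.array_equal(b1.hi99[tp], b2.hi99[tp])

    def test_bands_nested_and_ordered(self):
        units = flat_units(n_animals=8, upa=4, seed=15)
        bands = bootstrap_timecourse(units, n_resamples=500, seed=2)
        for tp in bands.types:
            assert (bands.lo99[tp] <= bands.lo95[tp] + 1e-12).all()
            assert (bands.hi95[tp] <= bands.hi99[tp] + 1e-12).all()
            assert (bands.lo95[tp] <= bands.mean[tp] + 1e-9).all()
            assert (bands.mean[tp] <= bands.hi95[tp] + 1e-9).all()

    def test_single_animal_rejected(self):
        units = [
            PeriEventUnit(
                animal="m0", hemisphere="left", event=e, sequence_type=SEQ_CC,
                bin_times=BIN_TIMES, values=np.zeros(90),
            )
            for e in range(5)
        ]
        with pytest.raises(ValueError, match="one cluster"):
            bootstrap_timecourse(units, n_resamples=100, seed=0)


class TestSignificance:
    def band_fixture(self, lo, hi):
        n = 90
        arr = lambda v: np.full(n, float(v))
        return BootstrapBands(
            bin_times=BIN_TIMES, types=(SEQ_CC,),
            mean={SEQ_CC: (arr(lo) + arr(hi)) / 2},
            lo95={SEQ_CC: arr(lo)}, hi95={SEQ_CC: arr(hi)},
            lo99={SEQ_CC: arr(lo)}, hi99={SEQ_CC: arr(hi)},
            n_resamples=100, seed=0,
        )

    def test_strictly_positive_band_full_interval(self):
        bands = self.band_fixture(0.5, 1.0)
        ivs = one_sample_significance(bands, level=99)
        assert len(ivs) == 1
        assert ivs[0].t_start == pytest.approx(BIN_TIMES[0])
        assert ivs[0].t_end == pytest.approx(BIN_TIMES[-1])

    def test_straddling_band_empty(self):
        bands = self.band_fixture(-0.5, 0.5)
        assert one_sample_significance(bands, level=99) == []

    def test_isolated_single_bin_suppressed(self):
        bands = self.band_fixture(-0.5, 0.5)
        bands.lo99[SEQ_CC][40] = 0.1  # single significant bin
        assert one_sample_significance(bands, level=99, min_bins=2) == []
        assert len(one_sample_significance(bands, level=99, min_bins=1)) == 1

    def test_detection_of_injected_effect(self):
        mu = np.where((BIN_TIMES >= 0.5) & (BIN_TIMES < 2.0), 1.0, 0.0)
        units = simulate_units(
            12, 6, {SEQ_CC: mu}, BIN_TIMES, rho=0.9, noise_sd=0.5,
            animal_sd=0.1, seed=17,
        )
        bands = bootstrap_timecourse(units, n_resamples=500, seed=3)
        ivs = one_sample_significance(bands, level=99)
        assert ivs  # effect support detected
        covered = any(iv.t_start <= 1.0 <= iv.t_end for iv in ivs)
        assert covered


class TestPairwise:
    def test_self_contrast_empty(self):
        units = flat_units(n_animals=6, upa=6, types=(SEQ_CC,), seed=19)
        band, ivs = pairwise_band_difference(units, (SEQ_CC, SEQ_CC), n_resamples=200, seed=0)
        assert ivs == []
        assert np.allclose(band["diff"], 0.0)

    def test_absent_type_rejected(self):
        units = flat_units(types=(SEQ_CC,), seed=21)
        with pytest.raises(ValueError, match="absent"):
            pairwise_band_difference(units, (SEQ_CC, SEQ_GO), n_resamples=100, seed=0)

    def test_effect_support_recovered(self):
        support = (BIN_TIMES >= 0.5) & (BIN_TIMES < 2.0)
        profiles = {SEQ_CC: np.where(support, 1.0, 0.0), SEQ_GO: np.zeros(90)}
        units = simulate_units(
            12, 8, profiles, BIN_TIMES, rho=0.9, noise_sd=1.0, animal_sd=0.2, seed=23
        )
        band, ivs = pairwise_band_difference(units, (SEQ_CC, SEQ_GO), n_resamples=500, seed=1)
        detected = np.zeros(90, dtype=bool)
        for iv in ivs:
            detected |= (BIN_TIMES >= iv.t_start - 1e-9) & (BIN_TIMES <= iv.t_end + 1e-9)
        overlap = (detected & support).sum() / support.sum()
        assert overlap >= 0.8

    def test_methods_agree_on_strong_effect(self):
        profiles = {SEQ_CC: np.full(90, 3.0), SEQ_GO: np.zeros(90)}
        units = simulate_units(10, 6, profiles, BIN_TIMES, rho=0.5, noise_sd=0.5, seed=25)
        for method in ("bands", "diff"):
            _, ivs = pairwise_band_difference(
                units, (SEQ_CC, SEQ_GO), n_resamples=300, seed=2, method=method
            )
            assert len(ivs) == 1
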