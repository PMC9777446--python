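import numpy as np
import pytest
from scipy.linalg import subspace_angles

from matcnv.genome import build_genome_model
from matcnv.normalize import (NormalizedProfile, fit_reference_panel,
                              loess_gc_correct, normalize_cohort,
                              pca_denoise, robust_sd)
from matcnv.simulate import (BinnedSample, CohortSpec, TruthVariant,
                             gc_bias_curve, simulate_cohort,
                             _smooth_loadings)


def make_profile(model, ratio):
    auto = model.mappable_view().autosomal
    return NormalizedProfile("p", np.asarray(ratio, float),
                             robust_sd(np.asarray(ratio)[auto]))


class TestLoess:
    def test_counts_proportional_to_smooth_gc_trend_flatten_to_one(
            self, mini_model):
        """Counts exactly proportional to a (linear) function of GC are
        corrected to ratio 1 away from the GC support edges."""
        mb = mini_model.mappable_view()
        counts = 5000.0 + 20000.0 * mb.gc  # exact, no rounding noise
        prof = loess_gc_correct(
            BinnedSample("s", counts, int(counts.sum())), mini_model)
        gmin, gmax = mb.gc.min(), mb.gc.max()
        interior = (mb.gc > gmin + 0.02) & (mb.gc < gmax - 0.02)
        assert np.abs(prof.ratio[interior] - 1).max() < 1e-6

    def test_flat_gc_spike_passes_through_as_ratio_two(self):
        model = build_genome_model(
            {"chr1": 6_000_000},
            gc_profile=lambda c, x: np.full(x.size, 0.42))
        counts = np.full(model.n_mappable, 10.0)
        counts[100] = 20.0
        with pytest.warns(UserWarning, match="degenerate GC"):
            prof = loess_gc_correct(
                BinnedSample("s", counts, int(counts.sum())), model)
        assert prof.ratio[100] == pytest.approx(2.0)
        assert np.median(prof.ratio) == pytest.approx(1.0)

    def test_noisy_quadratic_gc_bias_removed(self, mini_model):
        """After correction the residual GC correlation is small."""
        spec = CohortSpec(n_samples=1, reads_range=(80_000, 80_000),
                          gc_bias_strength=30.0, batch_rank=0, seed=21)
        (s,) = simulate_cohort(mini_model, spec)
        mb = mini_model.mappable_view()
        auto = mb.autosomal
        # the quadratic bias is symmetric around its peak, so compare
        # against the bias curve itself, not raw GC
        bias = gc_bias_curve(mb.gc[auto], 30.0, 0.42)
        raw_corr = np.corrcoef(s.counts[auto], bias)[0, 1]
        prof = loess_gc_correct(s, mini_model)
        assert raw_corr > 0.3          # the bias was really there
        assert abs(np.corrcoef(prof.ratio[auto],
                               mb.gc[auto])[0, 1]) < 0.05
        assert abs(np.corrcoef(prof.ratio[auto], bias)[0, 1]) < 0.05

    def test_autosomal_median_is_exactly_one(self, mini_cohort, mini_model):
        prof = loess_gc_correct(mini_cohort[0], mini_model)
        auto = mini_model.mappable_view().autosomal
        assert np.median(prof.ratio[auto]) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self, mini_model):
        zeros = np.zeros(mini_model.n_mappable)
        with pytest.raises(ValueError, match="all-zero"):
            loess_gc_correct(BinnedSample("s", zeros, 0), mini_model)

    def test_wrong_bin_count_rejected(self, mini_model):
        with pytest.raises(ValueError, match="bins"):
            loess_gc_correct(BinnedSample("s", np.ones(10), 10), mini_model)


class TestReferencePanel:
    def test_identical_profiles_reduce_k_with_warning(self, mini_model):
        flat = np.ones(mini_model.n_mappable)
        profs = [make_profile(mini_model, flat) for _ in range(6)]
        with pytest.warns(UserWarning, match="rank-deficient"):
            panel = fit_reference_panel(profs, mini_model, k=3)
        assert panel.k == 0

    def test_known_batch_subspace_recovered(self, mini_model):
        """Panel components align with the generator's low-rank batch
        loadings to within 10 degrees."""
        # deep, low-dispersion regime where the batch subspace is
        # identifiable above the counting-noise floor
        spec = CohortSpec(n_samples=100, reads_range=(400_000, 400_000),
                          batch_rank=2, batch_scale=0.08,
                          dispersion=0.002, seed=22)
        samples = simulate_cohort(mini_model, spec)
        profs = [loess_gc_correct(s, mini_model) for s in samples]
        panel = fit_reference_panel(profs, mini_model, k=2)
        # regenerate the loadings the simulator drew (same stream)
        rng = np.random.default_rng(spec.seed)
        loadings = _smooth_loadings(rng, 2, mini_model.n_mappable)
        auto = mini_model.mappable_view().autosomal
        angles = subspace_angles(panel.components.T, loadings[:, auto].T)
        assert np.degrees(angles).max() < 10.0

    def test_k_zero_keeps_mean_only(self, mini_model):
        profs = [make_profile(mini_model,
                              1 + 0.01 * np.arange(mini_model.n_mappable))
                 for _ in range(4)]
        panel = fit_reference_panel(profs, mini_model, k=0)
        assert panel.k == 0 and panel.components.shape[0] == 0

    def test_k_geq_samples_rejected(self, mini_model):
        profs = [make_profile(mini_model, np.ones(mini_model.n_mappable))
                 for _ in range(3)]
        with pytest.raises(ValueError, match="k="):
            fit_reference_panel(profs, mini_model, k=3)

    def test_component_sign_is_deterministic(self, mini_model):
        spec = CohortSpec(n_samples=10, reads_range=(80_000, 90_000),
                          seed=23)
        samples = simulate_cohort(mini_model, spec)
        profs = [loess_gc_correct(s, mini_model) for s in samples]
        a = fit_reference_panel(profs, mini_model, k=2)
        b = fit_reference_panel(profs, mini_model, k=2)
        assert np.array_equal(a.components, b.components)
        for row in a.components:
            assert row[np.argmax(np.abs(row))] > 0


class TestPcaDenoise:
    def test_profile_equal_to_panel_mean_becomes_flat_one(self, mini_model):
        """A panel of diploid profiles varying only along one artifact
        direction has mean 1; a profile equal to that mean comes out
        identically 1.0."""
        rng = np.random.default_rng(24)
        n = mini_model.n_mappable
        direction = rng.standard_normal(n)
        amplitudes = (-0.1, -0.05, 0.05, 0.1)  # sums to zero: mean is 1
        profs = [make_profile(mini_model, 1 + a * direction)
                 for a in amplitudes]
        panel = fit_reference_panel(profs, mini_model, k=1)
        out = pca_denoise(make_profile(mini_model, np.ones(n)),
                          panel, mini_model)
        assert np.abs(out.ratio - 1.0).max() < 1e-10

    def test_single_component_contribution_removed(self, mini_model):
        rng = np.random.default_rng(25)
        n = mini_model.n_mappable
        auto = mini_model.mappable_view().autosomal
        mean = np.ones(n)
        direction = rng.standard_normal(n)
        profs = [make_profile(mini_model,
                              mean + a * direction)
                 for a in (-0.1, -0.05, 0.0, 0.05, 0.1)]
        panel = fit_reference_panel(profs, mini_model, k=1)
        contaminated = make_profile(mini_model, mean + 0.3 * direction)
        out = pca_denoise(contaminated, panel, mini_model)
        assert np.abs(out.ratio[auto] - 1).max() < 1e-8

    def test_double_application_is_a_no_op(self, mini_model, mini_cohort):
        corrected = [loess_gc_correct(s, mini_model) for s in mini_cohort]
        panel = fit_reference_panel(corrected[1:], mini_model, k=3)
        once = pca_denoise(corrected[0], panel, mini_model)
        twice = pca_denoise(once, panel, mini_model)
        assert np.abs(twice.ratio - once.ratio).max() < 1e-10

    def test_batch_variance_reduced_across_cohort(self, mini_model):
        spec = CohortSpec(n_samples=40, reads_range=(80_000, 100_000),
                          batch_rank=2, batch_scale=0.08, seed=26)
        samples = simulate_cohort(mini_model, spec)
        corrected = [loess_gc_correct(s, mini_model) for s in samples]
        denoised = normalize_cohort(samples, mini_model, k=3)
        auto = mini_model.mappable_view().autosomal
        var_before = np.stack([p.ratio[auto] for p in corrected]).var(axis=0)
        var_after = np.stack([p.ratio[auto] for p in denoised]).var(axis=0)
        assert np.median(var_after) / np.median(var_before) < 0.8

    def test_x_bins_never_projected(self, mini_model, mini_cohort):
        corrected = [loess_gc_correct(s, mini_model) for s in mini_cohort]
        panel = fit_reference_panel(corrected[1:], mini_model, k=3)
        prof = corrected[0]
        out = pca_denoise(prof, panel, mini_model)
        auto = mini_model.mappable_view().autosomal
        # X ratios change only by the constant re-centering shift
        shift = prof.ratio[~auto] - out.ratio[~auto]
        assert np.ptp(shift) < 1e-12

    def test_grid_mismatch_rejected(self, mini_model):
        profs = [make_profile(mini_model, np.ones(mini_model.n_mappable))
                 for _ in range(4)]
        panel = fit_reference_panel(profs, mini_model, k=0)
        bad = NormalizedProfile("b", np.ones(10), 0.1)
        with pytest.raises(ValueError, match="grid"):
            pca_denoise(bad, panel, mini_model)


class TestCohortNormalization:
    def test_injected_gain_survives_both_steps(self, toy_model):
        """LOESS + leave-one-out PCA keep a 1.5x maternal gain's mean
        ratio near 1.5 (the panel must not absorb the sample's own
        CNV).  Needs the full toy genome: signal preservation requires
        many more bins than CNV-carrier rows in the panel."""
        spec = CohortSpec(n_samples=40, reads_range=(380_000, 520_000),
                          variant_catalog=(
                              TruthVariant("chr1", 3_000_000, 3_400_000, 3,
                                           "maternal", 0.05),),
                          seed=27)
        samples = simulate_cohort(toy_model, spec)
        profiles = normalize_cohort(samples, toy_model, k=3)
        mb = toy_model.mappable_view()
        mask = ((mb.chrom == 0) & (mb.start >= 3_000_000)
                & (mb.end <= 3_400_000))
        means = [p.ratio[mask].mean()
                 for s, p in zip(samples, profiles) if s.truth]
        assert means, "seeded cohort should contain carriers"
        assert 1.45 < np.mean(means) < 1.55

    def test_noise_sd_matches_count_statistics(self, mini_model,
                                               mini_cohort):
        """The MAD-based noise estimate tracks the NB counting noise:
        CV^2 = 1/mu + dispersion at ~80 reads per bin."""
        profs = normalize_cohort(mini_cohort, mini_model, k=3)
        mu = np.mean([s.counts.mean() for s in mini_cohort])
        predicted = np.sqrt(1 / mu + 0.01)
        observed = np.mean([p.noise_sd for p in profs])
        assert observed == pytest.approx(predicted, rel=0.3)
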