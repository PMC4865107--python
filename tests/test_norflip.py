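import numpy as np
import pytest

from topomap.genome import GenomeSpec
from topomap.norflip import (
    CleavageCallerParams,
    NorflipPeakModel,
    canonical_template,
    cleavage_template,
    cross_experiment_overlap,
    differential_track,
    estimate_cleavage_point,
    measure_shape,
    scan_cleavage,
    validate_sites,
)
from topomap.profiles import RatioTrack, StrandedProfile
from topomap.synthetic import (
    ArtifactRegion,
    PlantedSite,
    ShapeParams,
    add_artifacts,
    plant_chip_experiment,
    plant_norflip_experiment,
)

PARAMS = CleavageCallerParams()


class TestDifferentialTrack:
    def test_equal_strands_zero(self, small_genome, rng):
        x = rng.poisson(5, small_genome.length).astype(float)
        p = StrandedProfile(fwd=x.copy(), rev=x.copy(), genome=small_genome)
        assert np.allclose(differential_track(p), 0.0)

    def test_canonical_site_biphasic(self, canonical_exp):
        diff = differential_track(canonical_exp.ip)
        c = 50_000
        assert diff[c - 150] > 0 and diff[c + 150] < 0
        # antisymmetric construction: zero near the cleavage center
        assert abs(diff[c]) < 1e-6 * diff.max()

    def test_matches_bruteforce(self, rng):
        from topomap.profiles import rpm_normalize, smooth_circular

        g = GenomeSpec(length=2000, oriC=0, dif=1000)
        p = StrandedProfile(fwd=rng.poisson(5, 2000).astype(float),
                            rev=rng.poisson(5, 2000).astype(float), genome=g)
        q = rpm_normalize(p)
        oracle = smooth_circular(q.fwd, 200) - smooth_circular(q.rev, 200)
        assert np.allclose(differential_track(p), oracle)


class TestTemplate:
    def test_canonical_self_match(self, canonical_exp):
        diff = differential_track(canonical_exp.ip)
        tmpl = canonical_template()
        cands = scan_cleavage(diff, tmpl, PARAMS)
        assert len(cands) == 1
        assert cands[0].r > 0.999
        assert abs(cands[0].center - 50_000) <= 50

    def test_one_center_is_window_verbatim(self, canonical_exp):
        diff = differential_track(canonical_exp.ip)
        tmpl = cleavage_template(diff, [50_000], 600)
        assert np.array_equal(tmpl, diff[50_000 - 300: 50_000 + 300])

    def test_two_identical_sites_average(self, small_genome):
        exp = plant_norflip_experiment(
            small_genome, [PlantedSite(20_000), PlantedSite(60_000)], noise=False
        )
        diff = differential_track(exp.ip)
        tmpl = cleavage_template(diff, [20_000, 60_000], 600)
        assert np.allclose(tmpl, diff[19_700:20_300], atol=1e-9)

    def test_close_centers_rejected(self, canonical_exp):
        diff = differential_track(canonical_exp.ip)
        with pytest.raises(ValueError):
            cleavage_template(diff, [50_000, 50_100], 600)

    def test_template_matches_third_site(self, small_genome):
        exp = plant_norflip_experiment(
            small_genome,
            [PlantedSite(20_000), PlantedSite(50_000), PlantedSite(80_000)],
            noise=False,
        )
        diff = differential_track(exp.ip)
        tmpl = cleavage_template(diff, [20_000, 50_000], 600)
        cands = scan_cleavage(diff, tmpl, PARAMS)
        third = [c for c in cands if abs(c.center - 80_000) <= 100]
        assert len(third) == 1 and third[0].r > 0.999


class TestScanCleavage:
    def test_planted_sites_all_found(self):
        g = GenomeSpec(length=500_000, oriC=0, dif=250_000)
        centers = np.arange(20_000, 480_000, 40_000)  # 12 sites
        exp = plant_norflip_experiment(
            g, [PlantedSite(int(c), fold=10.0) for c in centers], seed=2
        )
        diff = differential_track(exp.ip)
        cands = scan_cleavage(diff, canonical_template(), PARAMS)
        for c in centers:
            assert min(abs(x.center - c) for x in cands) <= 100

    def test_mirrored_shape_not_called_at_center(self, small_genome):
        """A reverse-lobe-first site anticorrelates at alignment (r <= -0.72
        is not a call); only partial single-lobe matches away from the center
        can pass the r filter."""
        exp = plant_norflip_experiment(small_genome, [PlantedSite(50_000)], noise=False)
        swapped = StrandedProfile(fwd=exp.ip.rev.copy(), rev=exp.ip.fwd.copy(),
                                  genome=small_genome)
        diff = differential_track(swapped)
        from topomap._scan import pearson_scan

        starts, r = pearson_scan(diff, canonical_template(), 100)
        aligned = r[starts == 50_000 - 300][0]
        assert aligned < -0.99
        cands = scan_cleavage(diff, canonical_template(), PARAMS)
        assert all(abs(c.center - 50_000) >= 250 for c in cands)

    def test_background_has_no_validated_calls(self):
        """Noise windows can pass the r filter alone (the 200 bp smoothing
        leaves few effective degrees of freedom per window) but never survive
        the fold >= 2 validation."""
        g = GenomeSpec(length=1_000_000, oriC=0, dif=500_000)
        for seed in range(3):
            exp = plant_norflip_experiment(g, [], seed=seed)
            model = NorflipPeakModel.from_experiment(exp)
            res = model.fit()
            assert len(res.sites) == 0

    def test_constant_background_shift_invariance(self, small_genome):
        exp = plant_norflip_experiment(small_genome, [PlantedSite(50_000)], noise=False)
        shifted = StrandedProfile(fwd=exp.ip.fwd + 3.0, rev=exp.ip.rev + 3.0,
                                  genome=small_genome)
        c1 = scan_cleavage(differential_track(exp.ip), canonical_template(), PARAMS)
        c2 = scan_cleavage(differential_track(shifted), canonical_template(), PARAMS)
        assert [x.center for x in c1] == [x.center for x in c2]


class TestValidateSites:
    def _candidates(self, exp):
        diff = differential_track(exp.ip)
        return scan_cleavage(diff, canonical_template(), PARAMS)

    def test_fold_attached_and_thresholded(self, small_genome):
        exp = plant_norflip_experiment(small_genome, [PlantedSite(50_000, fold=30.0)],
                                       noise=False)
        model = NorflipPeakModel.from_experiment(exp)
        sites = validate_sites(self._candidates(exp), model._ratio(), 2.0, 600)
        assert len(sites) == 1
        assert sites[0].fold > 8  # strongest-site scale after 200 bp smoothing

    def test_low_fold_dropped(self, small_genome):
        exp = plant_norflip_experiment(small_genome, [PlantedSite(50_000, fold=1.5)],
                                       noise=False)
        model = NorflipPeakModel.from_experiment(exp)
        sites = validate_sites(self._candidates(exp), model._ratio(), 2.0, 600)
        assert sites == []

    def test_masked_candidate_dropped(self, small_genome):
        exp = plant_norflip_experiment(small_genome, [PlantedSite(50_000, fold=30.0)],
                                       noise=False)
        ratio = NorflipPeakModel.from_experiment(exp)._ratio()
        mask = np.zeros(len(ratio), dtype=bool)
        mask[49_000:51_000] = True
        masked = RatioTrack(ratio.values, mask=mask)
        assert validate_sites(self._candidates(exp), masked, 2.0, 600) == []


class TestCleavagePoint:
    def test_noise_free_exact(self, canonical_exp):
        point, fwd_center, flagged = estimate_cleavage_point(canonical_exp.ip, 50_000,
                                                             smooth=1)
        assert point == 50_000 and not flagged
        assert point - fwd_center == 150  # (fwd_span + gap) / 2 for 170/130

    def test_offset_candidate_still_exact(self, canonical_exp):
        point, _, _ = estimate_cleavage_point(canonical_exp.ip, 50_040, smooth=1)
        assert point == 50_000

    def test_symmetric_peak_falls_back_flagged(self, small_genome):
        exp = plant_chip_experiment(small_genome,
                                    [PlantedSite(50_000, kind="binding", fold=10.0)],
                                    noise=False)
        _, fwd_center, flagged = estimate_cleavage_point(exp.ip, 50_000, smooth=1)
        assert flagged and fwd_center is None

    def test_noisy_median_error_small(self):
        g = GenomeSpec(length=200_000, oriC=0, dif=100_000)
        errors = []
        for seed in range(10):
            exp = plant_norflip_experiment(g, [PlantedSite(100_000, fold=8.0)],
                                           depth=5, bg_rate=5, seed=seed)
            point, _, _ = estimate_cleavage_point(exp.ip, 100_000, smooth=51)
            errors.append(abs(point - 100_000))
        assert np.median(errors) <= 50


class TestMeasureShape:
    def test_canonical_values(self, canonical_exp):
        shp = measure_shape(canonical_exp.ip, 50_000, smooth=1)
        assert (shp.fwd_span, shp.gap, shp.read_depletion) == (170, 130, 100)

    def test_round_trip_wide_forward_span(self, small_genome):
        shape = ShapeParams(fwd_span=300, rev_span=170, gap=130, read_depletion=100)
        exp = plant_norflip_experiment(small_genome, [PlantedSite(50_000)],
                                       shape=shape, noise=False)
        shp = measure_shape(exp.ip, 50_000, smooth=1)
        assert abs(shp.fwd_span - 300) <= 1

    def test_flat_profile_rejected(self, small_genome):
        exp = plant_norflip_experiment(small_genome, [], noise=False)
        with pytest.raises(ValueError):
            measure_shape(exp.ip, 50_000, smooth=1)


class TestCrossExperimentOverlap:
    def test_identical_lists(self):
        sites = [1000, 5000, 9000]
        out = cross_experiment_overlap([sites, sites], tolerance=250)
        assert out["common_all"] == 3 and out["union"] == 3

    def test_disjoint_lists(self):
        out = cross_experiment_overlap([[1000, 5000], [20_000, 40_000]], tolerance=250)
        assert out["common_all"] == 0 and out["union"] == 4

    def test_three_experiments_shared_core(self, rng):
        """Three site lists engineered to share an 88-site core."""
        shared = np.sort(rng.choice(np.arange(10_000, 4_600_000, 5000), 88, replace=False))
        extras = rng.choice(np.arange(12_500, 4_620_000, 5000), 400, replace=False)
        extras = np.setdiff1d(extras, shared)
        lists = [
            np.sort(np.concatenate([shared, extras[:112]])),        # 200 sites
            np.sort(np.concatenate([shared, extras[112:204]])),     # 180 sites
            np.sort(np.concatenate([shared, extras[204:306]])),     # 190 sites
        ]
        out = cross_experiment_overlap([l.tolist() for l in lists], tolerance=250)
        assert out["common_all"] == 88
        assert out["union"] == 88 + 112 + 92 + 102

    def test_jittered_sites_still_match(self):
        a = [10_000, 50_000, 90_000]
        b = [10_120, 49_900, 90_240]
        out = cross_experiment_overlap([a, b], tolerance=250)
        assert out["common_all"] == 3

    def test_single_list_rejected(self):
        with pytest.raises(ValueError):
            cross_experiment_overlap([[1, 2]])


class TestPipeline:
    def test_antisymmetry_strand_swap_mirror(self):
        """Reverse-complementing the profile mirrors the called positions."""
        g = GenomeSpec(length=300_000, oriC=0, dif=150_000)
        centers = [60_000, 150_000, 240_000]
        exp = plant_norflip_experiment(g, [PlantedSite(c, fold=10.0) for c in centers],
                                       seed=4)
        mirrored = StrandedProfile(fwd=exp.ip.rev[::-1].copy(),
                                   rev=exp.ip.fwd[::-1].copy(), genome=g)
        cands_fwd = scan_cleavage(differential_track(exp.ip), canonical_template(), PARAMS)
        cands_mir = scan_cleavage(differential_track(mirrored), canonical_template(), PARAMS)
        got = sorted(x.center for x in cands_mir)
        expected = sorted((g.length - 1) - x.center for x in cands_fwd)
        assert len(got) == len(expected)
        assert all(abs(a - b) <= 150 for a, b in zip(got, expected))

    def test_artifact_region_removed_from_calls(self):
        g = GenomeSpec(length=500_000, oriC=0, dif=250_000)
        exp = plant_norflip_experiment(g, [PlantedSite(100_000, fold=10.0)], seed=6)
        exp = add_artifacts(exp, [ArtifactRegion(300_000, 304_000, 25.0)])
        res = NorflipPeakModel.from_experiment(exp).fit()
        assert all(abs(c - 100_000) < 1000 for c in res.centers)

    def test_recall_precision_planted(self):
        """>= 95% recall / precision on planted fold >= 5 sites at depth 5."""
        g = GenomeSpec(length=1_000_000, oriC=0, dif=500_000)
        tp = fp = fn = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            centers = np.sort(rng.choice(np.arange(5000, 995_000, 3000), 12, replace=False))
            folds = rng.uniform(5, 30, size=12)
            exp = plant_norflip_experiment(
                g, [PlantedSite(int(c), fold=float(f)) for c, f in zip(centers, folds)],
                seed=seed,
            )
            res = NorflipPeakModel.from_experiment(exp).fit()
            called = res.centers
            for c in centers:
                if len(called) and np.min(np.abs(called - c)) <= 250:
                    tp += 1
                else:
                    fn += 1
            for c in called:
                if np.min(np.abs(centers - c)) > 250:
                    fp += 1
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_data_template_mode(self):
        g = GenomeSpec(length=500_000, oriC=0, dif=250_000)
        centers = [100_000, 250_000, 400_000]
        exp = plant_norflip_experiment(
            g, [PlantedSite(c, fold=f) for c, f in zip(centers, [30.0, 25.0, 8.0])],
            seed=8,
        )
        res = NorflipPeakModel.from_experiment(exp).fit(template="data")
        assert all(min(abs(s - c) for s in res.centers) <= 100 for c in centers)

    def test_summary_mentions_counts(self, canonical_exp):
        res = NorflipPeakModel.from_experiment(canonical_exp).fit()
        assert "sites called" in res.summary()
        assert len(res.sites) == 1
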