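import math

import numpy as np
import pytest

from conftest import make_fragments, random_uniform_length_fragments
from puffin import (
    FragmentRecord,
    GenomicRegion,
    ProfileConfig,
    build_landscape_family,
    compute_landscape,
    compute_profile,
    fragment_weight,
    read_kernel,
)
from puffin.peaks import find_extrema


class TestKernel:
    def test_mode_value_is_gaussian_density_at_zero(self):
        alpha, w = 0.3, 146
        offsets, values = read_kernel(alpha, w)
        sigma = alpha * w
        assert values[offsets == 0][0] == pytest.approx(1 / (sigma * math.sqrt(2 * math.pi)))
        assert np.argmax(values) == np.nonzero(offsets == 0)[0][0]

    def test_symmetry(self):
        _, values = read_kernel(0.2, 150)
        assert np.allclose(values, values[::-1])

    @pytest.mark.parametrize("alpha,w", [(0.05, 146), (0.3, 100), (0.63, 200)])
    def test_mass_matches_gaussian_integral(self, alpha, w):
        # discrete sum over +-6 sigma vs the (essentially complete) integral
        _, values = read_kernel(alpha, w, truncation=6.0)
        assert 0.999 <= values.sum() <= 1.001

    def test_half_integer_shift_for_odd_lengths(self):
        offsets, values = read_kernel(0.2, 147, shift=0.5)
        # maximum sits at the offset nearest the (shifted) mean
        assert offsets[np.argmax(values)] in (0, 1)


class TestFragmentWeight:
    @pytest.mark.parametrize("w,n,expected", [
        (146, 10, 0.1),       # at the nucleosome size the penalty is 1
        (200, 10, 0.1),       # longer fragments are never penalized
        (73, 1, 0.5),         # default linear penalty: gamma(73) = 73/146
    ])
    def test_weights(self, w, n, expected):
        assert fragment_weight(w, n) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fragment_weight(146, 0)

    def test_weight_never_exceeds_uniform(self):
        for w in (10, 80, 146, 500):
            assert fragment_weight(w, 7) <= 1 / 7 + 1e-15


class TestProfile:
    def test_single_fragment_peak_at_midpoint(self, single_fragment_region):
        frags, region = single_fragment_region
        for alpha in (0.05, 0.3, 0.63):
            p = compute_profile(frags, alpha, region)
            assert abs(int(np.argmax(p.values)) + region.start - frags[0].midpoint) <= 1

    def test_mass_conservation(self):
        rng = np.random.default_rng(3)
        mids = np.rint(rng.uniform(600, 2400, 50))
        frags = make_fragments(mids, length=146)
        region = GenomicRegion("chr1", 0, 3600)
        total_beta = sum(fragment_weight(f.length, len(frags)) for f in frags)
        for alpha in (0.1, 0.4, 0.63):
            p = compute_profile(frags, alpha, region)
            # truncation at 6 sigma loses < 2e-9 of each unit of mass
            assert p.values.sum() == pytest.approx(total_beta, abs=len(frags) * 1e-6 + 1e-3)

    def test_linearity_of_union(self):
        a = make_fragments([500, 520], length=146)
        b = make_fragments([900], length=180)
        region = GenomicRegion("chr1", 0, 1600)
        n = len(a) + len(b)
        union = compute_profile(a + b, 0.3, region)
        pa = compute_profile(a, 0.3, region, n=n)
        pb = compute_profile(b, 0.3, region, n=n)
        assert np.allclose(union.values, pa.values + pb.values, atol=1e-12)

    def test_duplicate_fragment_equals_doubled_weight(self):
        f = make_fragments([500])[0]
        region = GenomicRegion("chr1", 0, 1000)
        twice = compute_profile([f, FragmentRecord(f.chrom, f.start, f.end)],
                                0.3, region, n=2)
        beta = fragment_weight(f.length, 2)
        doubled = compute_profile([f], 0.3, region, weights=[2 * beta])
        assert np.allclose(twice.values, doubled.values)

    def test_empty_fragments_give_zero_profile(self):
        region = GenomicRegion("chr1", 0, 100)
        p = compute_profile([], 0.3, region)
        assert not p.values.any()

    def test_alpha_to_zero_collapses_to_midpoints(self):
        mids = [300, 700, 701]
        frags = make_fragments(mids, length=146)
        region = GenomicRegion("chr1", 0, 1000)
        p = compute_profile(frags, 1e-3, region)
        support = np.nonzero(p.values)[0] + region.start
        assert all(min(abs(s - m) for m in mids) <= 1 for s in support)

    def test_roughness_nonincreasing_in_alpha(self):
        # heat-kernel causality: more smoothing never creates new maxima
        cfg = ProfileConfig(m=10)
        region = GenomicRegion("chr1", 0, 3200)
        for seed in range(5):
            frags = random_uniform_length_fragments(seed)
            counts = []
            for alpha in cfg.alpha_grid:
                p = compute_profile(frags, alpha, region)
                maxima, _ = find_extrema(p.values)
                counts.append(len(maxima))
            assert all(b <= a for a, b in zip(counts, counts[1:])), counts


class TestLandscape:
    def test_equal_profiles_give_exact_zero(self, single_fragment_region):
        frags, region = single_fragment_region
        p = compute_profile(frags, 0.3, region)
        ls = compute_landscape(p, p)
        assert not ls.values.any()

    def test_zero_against_zero_is_zero(self):
        region = GenomicRegion("chr1", 0, 50)
        z1 = compute_profile([], 0.2, region)
        z2 = compute_profile([], 1.5, region)
        assert not compute_landscape(z1, z2).values.any()

    def test_sign_follows_profile_ratio(self, single_fragment_region):
        frags, region = single_fragment_region
        fine = compute_profile(frags, 0.1, region)
        coarse = compute_profile(frags, 1.5, region)
        ls = compute_landscape(fine, coarse)
        above = fine.values > coarse.values
        assert np.all(ls.values[above] > 0)
        assert np.all(ls.values[~above] <= 0)

    def test_region_mismatch_rejected(self):
        p1 = compute_profile([], 0.2, GenomicRegion("chr1", 0, 50))
        p2 = compute_profile([], 1.5, GenomicRegion("chr1", 0, 60))
        with pytest.raises(ValueError):
            compute_landscape(p1, p2)


class TestLandscapeFamily:
    def test_family_size_and_order(self, single_fragment_region, small_config):
        frags, region = single_fragment_region
        landscapes, ref = build_landscape_family(frags, region, small_config)
        assert len(landscapes) == small_config.m
        alphas = [ls.alpha for ls in landscapes]
        assert alphas == sorted(alphas)
        assert ref.alpha == small_config.low_res_alpha

    def test_default_grid_has_forty_scales(self):
        cfg = ProfileConfig()
        assert cfg.m == 40
        assert cfg.alpha_grid[0] == pytest.approx(0.05)
        assert cfg.alpha_grid[-1] == pytest.approx(0.63)

    def test_single_fragment_unimodal_everywhere(self, single_fragment_region,
                                                 small_config):
        frags, region = single_fragment_region
        landscapes, _ = build_landscape_family(frags, region, small_config)
        for ls in landscapes:
            maxima, _ = find_extrema(ls.values)
            positive = [i for i in maxima if ls.values[i] > 0]
            assert len(positive) == 1
            assert abs(positive[0] + region.start - frags[0].midpoint) <= 1

    def test_coarse_scales_are_smoother(self):
        # four nucleosomes: three sharp, one fuzzy; coarse landscapes carry
        # fewer local maxima than fine ones
        rng = np.random.default_rng(8)
        mids = np.concatenate([
            rng.normal(300, 15, 40), rng.normal(700, 50, 40),
            rng.normal(1100, 15, 40), rng.normal(1270, 15, 40),
        ])
        frags = make_fragments(np.rint(mids))
        region = GenomicRegion("chr1", 0, 1600)
        cfg = ProfileConfig(m=2, alpha_min=0.07, alpha_max=0.62)
        (fine, coarse), _ = build_landscape_family(frags, region, cfg)
        n_fine = len(find_extrema(fine.values)[0])
        n_coarse = len(find_extrema(coarse.values)[0])
        assert n_coarse < n_fine


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(alpha_min=0.7, alpha_max=0.63),
        dict(low_res_alpha=0.5),
        dict(epsilon=0.0),
        dict(m=0),
        dict(truncation=-1.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProfileConfig(**kwargs)
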