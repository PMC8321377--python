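import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.filters import sobel

from skinpost.homogeneity import (HomogeneityParams, RegionHomogeneity,
                                  homogeneity_refine, is_homogeneous,
                                  iterate_refinement, region_stats)


def disk(h, w, cy, cx, r):
    yy, xx = np.mgrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestRegionStats:
    def test_constant_region_sigma_zero(self):
        spm = np.full((8, 8), 200, np.uint8)
        region = np.zeros((8, 8), bool)
        region[2:6, 2:6] = True
        assert region_stats(spm, region).sigma == 0.0

    def test_closed_form_sigma(self):
        spm = np.array([[100, 100], [200, 200]], dtype=np.uint8)
        stats = region_stats(spm, np.ones((2, 2), bool))
        assert stats.sigma == pytest.approx(50.0)  # population SD

    def test_square_region_counts(self):
        spm = np.zeros((20, 20), np.uint8)
        region = np.zeros((20, 20), bool)
        region[5:15, 5:15] = True
        spm[region] = 220
        stats = region_stats(spm, region)
        assert stats.n_skin == 100
        assert stats.bbox_extent == 10
        # edges only at the region boundary: fewer than half the pixels
        assert 0 < stats.n_edge < 50

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_stats(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))


class TestIsHomogeneous:
    @pytest.mark.parametrize("sigma,ne,nd,ns,expected", [
        (30.0, 10, 100, 1000, True),    # Ne/Nd = 0.1 <= 3.5
        (60.0, 10, 100, 1000, False),   # sigma conjunct fails
        (30.0, 400, 100, 40000, True),  # 4.0 > 3.5 but Ne/Ns = 0.01 <= 0.02
        (30.0, 400, 100, 1000, False),  # both ratios fail
    ])
    def test_direct_substitution(self, sigma, ne, nd, ns, expected):
        stats = RegionHomogeneity(sigma, ne, ns, nd)
        assert is_homogeneous(stats) is expected

    def test_alternative_precedence_flag(self):
        # sigma fails but Ne/Ns passes: grouped reading rejects,
        # ((sigma AND ratio) OR ratio) accepts
        stats = RegionHomogeneity(sigma=60.0, n_edge=10, n_skin=1000,
                                  bbox_extent=100)
        assert is_homogeneous(stats, HomogeneityParams(grouped_or=True)) is False
        assert is_homogeneous(stats, HomogeneityParams(grouped_or=False)) is True


class TestRefinement:
    def test_all_zero_spm_returns_empty_first_pass(self):
        iters = list(iterate_refinement(np.zeros((32, 32), np.uint8)))
        assert len(iters) == 1
        assert not iters[0][1].any()
        assert iters[0][0] == pytest.approx(0.2)

    def test_flat_high_blob_accepted_immediately(self):
        spm = np.zeros((40, 40), np.uint8)
        blob = disk(40, 40, 20, 20, 12)  # ~441 px >= 300
        spm[blob] = 230
        iters = list(iterate_refinement(spm))
        assert len(iters) == 1
        np.testing.assert_array_equal(iters[0][1], blob)

    def test_concentric_blob_iterates_to_predicted_core(self):
        """A mixed-intensity region fails until T passes the annulus level.

        The expected iteration count and final mask come from independently
        replaying thresholds 0.2 * 1.1^k with direct numpy region checks.
        """
        spm = np.zeros((60, 60), np.uint8)
        outer = disk(60, 60, 30, 30, 20)
        inner = disk(60, 60, 30, 30, 12)
        spm[outer] = 100
        spm[inner] = 230

        params = HomogeneityParams()
        expected_iters = None
        k = 0
        while True:  # replay oracle
            t = 0.2 * 1.1 ** k
            mask = spm / 255.0 > t
            lab, n = ndi.label(mask, ndi.generate_binary_structure(2, 2))
            areas = np.bincount(lab.ravel())
            keep = [i for i in range(1, n + 1) if areas[i] >= 300]
            ok = True
            grad = sobel(spm / 255.0) * 255
            for i in keep:
                reg = lab == i
                sigma = spm[reg].std()
                ne = (grad[reg] > 128).sum()
                rows, cols = np.nonzero(reg)
                nd = max(np.ptp(rows) + 1, np.ptp(cols) + 1)
                ns = reg.sum()
                if not (sigma < 45 and (ne / nd <= 3.5 or ne / ns <= 0.02)):
                    ok = False
            if ok:
                expected_iters = k + 1
                expected_mask = np.zeros_like(mask)
                for i in keep:
                    expected_mask |= lab == i
                break
            k += 1

        iters = list(iterate_refinement(spm, params))
        assert len(iters) == expected_iters
        assert expected_iters > 1  # the scenario really does iterate
        np.testing.assert_array_equal(iters[-1][1], expected_mask)
        np.testing.assert_array_equal(homogeneity_refine(spm, params),
                                      expected_mask)

    def test_termination_and_monotone_shrinkage(self, rng):
        params = HomogeneityParams(min_area=20)
        for _ in range(25):
            spm = rng.integers(0, 256, (48, 48)).astype(np.uint8)
            iters = list(iterate_refinement(spm, params))  # terminates
            masks = [m for _, m in iters]
            for earlier, later in zip(masks, masks[1:]):
                assert (later <= earlier).all()

    def test_returned_regions_satisfy_criterion(self, rng):
        params = HomogeneityParams(min_area=20)
        for _ in range(10):
            spm = (rng.random((48, 48)) * 255).astype(np.uint8)
            spm[10:30, 10:30] = 210  # give it something to accept
            final = homogeneity_refine(spm, params)
            lab, n = ndi.label(final, ndi.generate_binary_structure(2, 2))
            for i in range(1, n + 1):
                reg = lab == i
                assert reg.sum() >= params.min_area
                stats = region_stats(spm, reg,
                                     sobel_threshold=params.sobel_threshold)
                assert is_homogeneous(stats, params)

    def test_t_cap_forces_empty_mask(self):
        spm = np.full((20, 20), 255, np.uint8)
        spm[0, 0] = 0  # avoid the degenerate constant path
        params = HomogeneityParams(min_area=10, t_cap=0.5, sigma_max=-1.0)
        final = homogeneity_refine(spm, params)
        assert not final.any()
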