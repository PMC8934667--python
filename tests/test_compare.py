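"""Ratio matrices, scalograms, 4C/z profiles, wings, distance law."""

import numpy as np
import pytest

import topohic as th
from topohic.compare import decay_ratio_curve, default_wing_geometry


def norm_map(vals, bin_size=5000, mask=None, genome=None):
    n = vals.shape[0]
    g = genome or th.Genome("g", n * bin_size, circular=True)
    return th.ContactMap(g, bin_size, vals, mask, state="normalized")


def toeplitz_decay(n, gamma=1.0, s0=2.0):
    idx = np.arange(n)
    k = np.abs(idx[:, None] - idx[None, :])
    k = np.minimum(k, n - k)
    return (s0 + k) ** -gamma


class TestRatioMap:
    def test_identity_zero(self, rng):
        a = norm_map(toeplitz_decay(20))
        r = th.ratio_map(a, a)
        assert np.all(r.values == 0)

    def test_doubling_gives_one(self):
        a = norm_map(toeplitz_decay(10))
        b = norm_map(2 * toeplitz_decay(10))
        r = th.ratio_map(b, a, pseudocount=0)
        assert np.allclose(r.values, 1.0)

    def test_pseudocount_arithmetic(self):
        # mutant 0 vs control 0.01 at p = 0.01: log2(0.01 / 0.02) = -1
        a = norm_map(np.full((4, 4), 0.0))
        b = norm_map(np.full((4, 4), 0.01))
        r = th.ratio_map(a, b, pseudocount=0.01)
        assert np.allclose(r.values, -1.0)

    def test_antisymmetric_under_swap(self, rng):
        a = norm_map(toeplitz_decay(15))
        vals = toeplitz_decay(15) * (1 + 0.2 * rng.random((15, 15)))
        vals = (vals + vals.T) / 2
        b = norm_map(vals)
        r1, r2 = th.ratio_map(a, b), th.ratio_map(b, a)
        assert np.allclose(r1.values, -r2.values)

    def test_mask_union_is_nan(self):
        mask = np.zeros(10, dtype=bool)
        mask[2] = True
        v = toeplitz_decay(10)
        v[2, :] = 0
        v[:, 2] = 0
        a = norm_map(v, mask=mask)
        b = norm_map(toeplitz_decay(10))
        r = th.ratio_map(a, b)
        assert np.isnan(r.values[2]).all()
        assert np.isfinite(r.values[3, 4])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            th.ratio_map(norm_map(toeplitz_decay(10)), norm_map(toeplitz_decay(12)))


class TestScalogram:
    def test_self_is_zero(self):
        a = norm_map(toeplitz_decay(100))
        s = th.distance_ratio_plot(a, a, d_min=5000, d_max=100_000)
        assert np.all(s.values == 0)

    def test_multiplicative_band_localized(self):
        # a x2 band at separations 10-20 bins shows up as exactly 1 in the
        # matching distance columns and 0 elsewhere
        n, bs = 200, 5000
        base = toeplitz_decay(n)
        idx = np.arange(n)
        k = np.abs(idx[:, None] - idx[None, :])
        k = np.minimum(k, n - k)
        boosted = base * np.where((k >= 10) & (k <= 20), 2.0, 1.0)
        s = th.distance_ratio_plot(norm_map(boosted), norm_map(base),
                                   d_min=bs, d_max=40 * bs, step=bs,
                                   pseudocount=0)
        cols = s.column_means()
        in_band = (s.distances >= 10 * bs) & (s.distances <= 20 * bs)
        assert np.allclose(cols[in_band], 1.0)
        assert np.allclose(cols[~in_band], 0.0)

    def test_anchor_row_enrichment_is_local(self):
        n = 120
        base = toeplitz_decay(n)
        mod = base.copy()
        mod[60, :] *= 3.0
        mod[:, 60] *= 3.0
        s = th.distance_ratio_plot(norm_map(mod), norm_map(base),
                                   d_min=5000, d_max=100_000, pseudocount=0)
        nonzero_rows = np.unique(np.nonzero(np.abs(s.values) > 1e-9)[0])
        # only the anchor row and rows within d_max of it are affected
        assert 60 in nonzero_rows
        assert np.all(np.minimum(np.abs(nonzero_rows - 60),
                                 n - np.abs(nonzero_rows - 60)) <= 20)

    def test_column_means_match_decay_ratio(self):
        # for a distance-multiplicative difference, the scalogram column
        # means equal the log ratio of genome-wide mean decay curves
        n = 150
        base = toeplitz_decay(n)
        idx = np.arange(n)
        k = np.abs(idx[:, None] - idx[None, :])
        k = np.minimum(k, n - k)
        mod = base * (1 + 0.5 * np.exp(-((k - 12) / 4.0) ** 2))
        a, b = norm_map(mod), norm_map(base)
        s = th.distance_ratio_plot(a, b, d_min=5000, d_max=100_000, pseudocount=0)
        d, curve = decay_ratio_curve(a, b, d_min=5000, d_max=100_000)
        assert np.allclose(s.column_means(), curve, atol=1e-9)

    def test_dmax_beyond_half_length_errors(self):
        a = norm_map(toeplitz_decay(20))  # genome 100 kb
        with pytest.raises(ValueError, match="half"):
            th.distance_ratio_plot(a, a, d_max=50_000)


class TestVirtual4C:
    def test_symmetry(self, rng):
        v = toeplitz_decay(30) * (1 + 0.1 * rng.random((30, 30)))
        v = (v + v.T) / 2
        a = norm_map(v)
        p_i = th.virtual_4c(a, 7 * 5000 + 1)
        p_j = th.virtual_4c(a, 19 * 5000 + 1)
        assert p_i.values[19] == pytest.approx(p_j.values[7])

    def test_uniform_offdiag_flat(self):
        v = np.ones((10, 10))
        prof = th.virtual_4c(norm_map(v), 0)
        assert np.allclose(prof.values, 1.0)

    def test_scn_profile_sums_to_one(self, rng):
        from tests.conftest import random_symmetric_counts
        v = random_symmetric_counts(rng, 40)
        nrm = th.scn_normalize(th.ContactMap(th.Genome("g", 200_000), 5000, v))
        prof = th.virtual_4c(nrm, 100_000)
        assert np.nansum(prof.values) == pytest.approx(1.0, abs=1e-4)

    def test_span_anchor_and_masked_anchor(self):
        mask = np.zeros(10, dtype=bool)
        mask[3] = True
        v = toeplitz_decay(10)
        v[3, :] = 0
        v[:, 3] = 0
        a = norm_map(v, mask=mask)
        prof = th.virtual_4c(a, (0, 10_000))  # bins 0-1
        assert prof.values.shape == (10,)
        assert np.isnan(prof.values[3])
        with pytest.raises(ValueError, match="masked"):
            th.virtual_4c(a, 3 * 5000 + 2)


class TestZscoreWindow:
    def test_hand_example(self):
        # query contacts c = (1,1,1,1,6): mean 2, population sd 2
        n = 10
        v = np.zeros((n, n))
        v[0, 5:10] = [1, 1, 1, 1, 6]
        v[5:10, 0] = v[0, 5:10]
        a = norm_map(v, bin_size=100)
        prof = th.zscore_window(a, (0, 100), (500, 1000))
        assert np.allclose(prof.values, [-0.5, -0.5, -0.5, -0.5, 2.0])
        assert np.nanmean(prof.values) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(prof.values) == pytest.approx(1.0)

    def test_constant_degenerate(self):
        a = norm_map(np.ones((10, 10)), bin_size=100)
        with pytest.raises(ValueError, match="degenerate"):
            th.zscore_window(a, (0, 100), (500, 1000))

    def test_overlap_rejected(self):
        a = norm_map(np.ones((10, 10)), bin_size=100)
        with pytest.raises(ValueError, match="disjoint"):
            th.zscore_window(a, (0, 300), (200, 600))


class TestWingEnrichment:
    def test_identity_ratio_zero(self):
        g = th.Genome("g", 500_000, circular=True,
                      anchors={"dif": 250_000, "oriC": 20_000},
                      spans={"terminus": (200_000, 300_000)})
        a = norm_map(toeplitz_decay(100), genome=g)
        r = th.ratio_map(a, a)
        ws = th.wing_enrichment(r, guard=100_000)
        assert ws.mean_log2 == pytest.approx(0.0)
        assert ws.fold == pytest.approx(1.0)

    def test_planted_recovery_and_dif_dip(self, sim_params_small):
        p = sim_params_small
        wt = th.expected_map(p, "wt")
        mut = th.expected_map(p, "mutant")
        r = th.ratio_map(mut, wt, pseudocount=0)
        ws = th.wing_enrichment(r, guard=p.wings.guard, anchor_width=p.wings.anchor_width)
        assert ws.fold == pytest.approx(p.wings.alpha, rel=0.10)
        dif_bin = p.dif // p.bin_size
        prof = ws.anchor_profile
        assert prof[dif_bin] < prof[dif_bin - 1]
        assert prof[dif_bin] < prof[dif_bin + 1]

    def test_empty_after_exclusion_errors(self):
        g = th.Genome("g", 500_000, circular=True,
                      anchors={"dif": 250_000, "oriC": 20_000},
                      spans={"terminus": (200_000, 300_000)})
        a = norm_map(toeplitz_decay(100), genome=g)
        r = th.ratio_map(a, a)
        with pytest.raises(ValueError):
            th.wing_enrichment(r, guard=260_000)  # beyond max separation


class TestDistanceLaw:
    def test_exact_power_law(self):
        n = 100
        idx = np.arange(n)
        k = np.minimum(np.abs(idx[:, None] - idx[None, :]),
                       n - np.abs(idx[:, None] - idx[None, :]))
        v = np.where(k > 0, 1.0 / np.maximum(k, 1), 0.0)
        a = norm_map(v, bin_size=1000)
        i, j = np.triu_indices(n, k=1)
        fit = th.distance_law_test(a, (i, j))
        assert fit.slope == pytest.approx(-1.0, abs=0.01)

    def test_constant_slope_zero(self):
        a = norm_map(np.ones((50, 50)), bin_size=1000)
        i, j = np.triu_indices(50, k=1)
        fit = th.distance_law_test(a, (i, j))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_range(self):
        a = norm_map(np.ones((50, 50)), bin_size=1000)
        i = np.zeros(20, dtype=int)
        j = np.arange(10, 30)  # separations 10-20 bins: < 4-fold
        with pytest.raises(ValueError, match="dynamic range"):
            th.distance_law_test(a, (i, j))


class TestExcessMap:
    def test_planted_hub_is_flat_background_decays(self, sim_params_small):
        from topohic.simulate import (PrecatenaneParams, TerminusParams,
                                      _wing_cell_indices)
        q = sim_params_small
        # a lone distance-independent stripe over the plain decay background
        p = th.SimParams(
            genome_length=q.genome_length, bin_size=q.bin_size, dif=q.dif,
            oriC=q.oriC, wings=q.wings,
            precatenane=PrecatenaneParams(beta=0.0),
            terminus=TerminusParams(span=q.terminus.span, depletion=1.0,
                                    dif_border=1.0, short_boost=0.0))
        wt = th.expected_map(p, "wt")
        mut = th.expected_map(p, "mutant")
        ex = th.excess_map(mut, wt)
        n = wt.n_bins
        wi, wj = _wing_cell_indices(p, n)
        sep = np.minimum(np.abs(wi - wj), n - np.abs(wi - wj)) * p.bin_size
        # the additive stripe covers the whole wing, so the slope can be
        # read from 50 kb out (a 5-fold separation range on this genome)
        keep = sep > 50_000
        wing_fit = th.distance_law_test(ex, (wi[keep], wj[keep]))
        bg_fit = th.distance_law_test(wt, (wi[keep], wj[keep]))
        assert abs(wing_fit.slope) < 0.1
        assert bg_fit.slope < -0.3
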