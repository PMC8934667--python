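"""The synthetic-data generator: planted features, sampling, determinism."""

import numpy as np
import pytest

import topohic as th
from topohic.simulate import (PrecatenaneParams, TerminusParams, WingParams,
                              _wing_cell_indices)


class TestExpectedMap:
    def test_wt_is_pure_decay_toeplitz(self, sim_params_small):
        wt = th.expected_map(sim_params_small, "wt")
        n = wt.n_bins
        idx = np.arange(n)
        k = np.minimum(np.abs(idx[:, None] - idx[None, :]),
                       n - np.abs(idx[:, None] - idx[None, :]))
        p = sim_params_small
        ref = (p.decay.s0 + k * p.bin_size) ** -p.decay.gamma
        ref /= ref.mean()
        assert np.allclose(wt.values, ref)
        assert wt.values.mean() == pytest.approx(1.0)

    def test_mutant_band_outside_terminus_only(self, sim_params_small):
        p = sim_params_small
        p = th.SimParams(genome_length=p.genome_length, bin_size=p.bin_size,
                         dif=p.dif, oriC=p.oriC, terminus=TerminusParams(
                             span=p.terminus.span, depletion=1.0,
                             dif_border=1.0, short_boost=0.0),
                         precatenane=p.precatenane, wings=None)
        wt, mut = th.expected_map(p, "wt"), th.expected_map(p, "mutant")
        r = th.ratio_map(mut, wt, pseudocount=0)
        n = wt.n_bins
        idx = np.arange(n)
        k = np.minimum(np.abs(idx[:, None] - idx[None, :]),
                       n - np.abs(idx[:, None] - idx[None, :]))
        s = k * p.bin_size
        in_band = (s >= p.precatenane.d_lo) & (s <= p.precatenane.d_hi)
        tb = wt.bins_in_span(p.terminus.span)
        out_t = np.ones(n, dtype=bool)
        out_t[tb] = False
        both_out = out_t[:, None] & out_t[None, :]
        # both maps are unit-mean scaled, so the ratio is the boost up to a
        # constant: band cells sit one fixed log2 step above all others
        band_vals = r.values[in_band & both_out]
        off_vals = r.values[~(in_band & both_out)]
        assert band_vals.std() < 1e-9
        assert off_vals.std() < 1e-9
        assert band_vals.mean() - off_vals.mean() == pytest.approx(
            np.log2(1 + p.precatenane.beta))

    def test_terminus_depletion_negative(self, sim_params_small):
        p = sim_params_small
        wt, mut = th.expected_map(p, "wt"), th.expected_map(p, "mutant")
        r = th.ratio_map(mut, wt, pseudocount=0)
        tb = wt.bins_in_span(p.terminus.span)
        n = wt.n_bins
        ii, jj = np.meshgrid(tb, tb, indexing="ij")
        sep = np.minimum(np.abs(ii - jj), n - np.abs(ii - jj)) * p.bin_size
        mid = sep > p.terminus.short_range
        assert r.values[ii, jj][mid].mean() < 0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            th.SimParams(genome_length=100_000)  # default terminus outside
        with pytest.raises(ValueError):
            th.SimParams(genome_length=500_000, dif=250_000, oriC=20_000,
                         terminus=TerminusParams(span=(200_000, 300_000)),
                         wings=WingParams(alpha=0.5))


class TestSampleCounts:
    def test_reproducible(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "wt")
        a = th.sample_counts(exp, 10_000, seed=3)
        b = th.sample_counts(exp, 10_000, seed=3)
        assert np.array_equal(a.values, b.values)
        c = th.sample_counts(exp, 10_000, seed=4)
        assert not np.array_equal(a.values, c.values)

    def test_total_and_symmetry(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "wt")
        cnt = th.sample_counts(exp, 50_000, seed=1)
        assert cnt.check_symmetric()
        assert cnt.total == pytest.approx(50_000, rel=0.02)

    def test_zero_rows_stay_zero(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "wt")
        exp.values[7, :] = 0
        exp.values[:, 7] = 0
        cnt = th.sample_counts(exp, 50_000, seed=1)
        assert not cnt.values[7].any()

    def test_bad_total(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "wt")
        with pytest.raises(ValueError):
            th.sample_counts(exp, 0, seed=1)


class TestSamplePairs:
    def test_roundtrip_exact(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "mutant")
        recs = list(th.sample_pairs(exp, total_pairs=20_000, seed=9))
        cmap, _ = th.build_matrix(recs, exp.genome, exp.bin_size)
        rng = np.random.default_rng(9)
        iu, ju = np.triu_indices(exp.n_bins)
        p = exp.values[iu, ju]
        counts = rng.multinomial(20_000, p / p.sum())
        ref = np.zeros_like(exp.values)
        ref[iu, ju] = counts
        ref[ju, iu] = counts
        assert np.array_equal(cmap.values, ref)

    def test_mapq_noise_retention(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "wt")
        recs = list(th.sample_pairs(exp, total_pairs=20_000, seed=2,
                                    mapq_noise=0.2))
        kept, stats = th.filter_pairs(iter(recs), mapq_min=31)
        list(kept)
        # binomial: 0.8 +- ~3 sd at n = 20000
        assert stats.retained_fraction == pytest.approx(0.8, abs=0.01)

    def test_deterministic(self, sim_params_small):
        exp = th.expected_map(sim_params_small, "wt")
        a = list(th.sample_pairs(exp, total_pairs=500, seed=5))
        b = list(th.sample_pairs(exp, total_pairs=500, seed=5))
        assert a == b


class TestSimulateFoci:
    def test_deterministic(self):
        p = th.FociSimParams(n_cells=50, seed=11)
        a = th.simulate_foci(p, "wt")
        b = th.simulate_foci(p, "wt")
        assert a.equals(b)

    def test_zero_excess_equalizes_conditions(self):
        p = th.FociSimParams(n_cells=400, coloc_excess=0.0, seed=3)
        fw = th.coloc_fraction(
            th.interfocal_distances(th.simulate_foci(p, "wt"), "ter", "left").closest)[0]
        fm = th.coloc_fraction(
            th.interfocal_distances(th.simulate_foci(
                th.FociSimParams(n_cells=400, coloc_excess=0.0, seed=4),
                "mutant"), "ter", "left").closest)[0]
        assert abs(fw - fm) < 0.06

    def test_planted_coloc_recovered(self):
        p = th.FociSimParams(n_cells=600, seed=21)
        for condition, planted in (("wt", 0.09), ("mutant", 0.18)):
            t = th.simulate_foci(p, condition)
            res = th.interfocal_distances(t, "ter", "left")
            frac, (lo, hi) = th.coloc_fraction(res.closest)
            assert lo <= planted <= hi

    def test_schema(self):
        t = th.simulate_foci(th.FociSimParams(n_cells=10, seed=1))
        assert set(t.columns) == {"cell_id", "cell_length_um", "tag",
                                  "x_um", "y_um", "axial"}
        assert t.groupby(["cell_id", "tag"]).size().max() <= 2
        assert ((t["axial"] >= 0) & (t["axial"] <= 1)).all()


class TestPlantedFeatureScaling:
    def test_recovery_error_shrinks_with_depth(self, sim_params_small):
        """Wing-fold recovery error decreases as sequencing depth grows."""
        p = sim_params_small
        wt, mut = th.expected_map(p, "wt"), th.expected_map(p, "mutant")
        errs = []
        for depth, seed in ((10**5, 41), (10**7, 42)):
            cw = th.scn_normalize(th.mask_sparse_bins(
                th.sample_counts(wt, depth, seed=seed)))
            cm = th.scn_normalize(th.mask_sparse_bins(
                th.sample_counts(mut, depth, seed=seed + 100)))
            ws = th.wing_enrichment(th.ratio_map(cm, cw), guard=p.wings.guard,
                                    anchor_width=p.wings.anchor_width)
            errs.append(abs(ws.fold - p.wings.alpha))
        assert errs[1] < errs[0]
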