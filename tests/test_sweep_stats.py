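"""EHH curves, iHH integration, iHS and xp-EHH scans."""

import numpy as np
import pytest

from sweepscan import (EhhCurve, ScanConfig, SweepSimParams, ehh_curve,
                       ihs_scan, integrate_ihh, simulate_wf, xpehh_scan)

from conftest import ehh_oracle, make_matrix, random_matrix


def curve(points, status="cutoff_reached"):
    """EhhCurve from (distance_cM, ehh, bp) triples."""
    d, e, bp = zip(*points)
    return EhhCurve(None, "downstream", d, e, bp, status)


POINT = curve([(0.0, 1.0, 0)])  # degenerate second direction


class TestEhhCurve:
    def test_distance_zero_is_one(self, tiny_matrix):
        c = ehh_curve(tiny_matrix, 2, [0, 1, 2], "downstream")
        assert c.distances[0] == 0.0 and c.ehh[0] == 1.0

    def test_one_identical_pair_of_three(self):
        # carriers extend with alleles (0,0,1): 1 identical pair of 3 -> 1/3
        m = make_matrix([[1, 0], [1, 0], [1, 1], [0, 0], [0, 1], [0, 1]])
        c = ehh_curve(m, 0, [0, 1, 2], "downstream")
        assert c.ehh[1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        m = make_matrix(np.tile([1, 1, 0, 1, 0], (4, 1)))
        c = ehh_curve(m, 2, [0, 1, 2, 3], "downstream")
        assert np.all(c.ehh == 1.0)
        assert c.status == "edge_reached"

    def test_monotone_non_increasing(self, rng):
        for _ in range(25):
            m = random_matrix(rng)
            core = int(rng.integers(0, m.n_sites))
            col = m.alleles[:, core]
            carriers = np.flatnonzero(col == col[0])
            if carriers.size < 2:
                continue
            for direction in ("upstream", "downstream"):
                c = ehh_curve(m, core, carriers, direction)
                assert np.all(np.diff(c.ehh) <= 1e-15)

    def test_matches_bruteforce_oracle(self, rng):
        cfg = ScanConfig(ehh_cutoff=1e-9)  # walk as far as possible
        for _ in range(40):
            m = random_matrix(rng)
            core = int(rng.integers(0, m.n_sites))
            col = m.alleles[:, core]
            carriers = np.flatnonzero(col == 1)
            if carriers.size < 2:
                continue
            c = ehh_curve(m, core, carriers, "downstream", cfg)
            for k in range(1, len(c.ehh)):
                assert c.ehh[k] == pytest.approx(
                    ehh_oracle(m.alleles, carriers, core, core + k), abs=0)

    def test_too_few_carriers_uncomputable(self, tiny_matrix):
        c = ehh_curve(tiny_matrix, 0, [0], "downstream")
        assert c.status == "uncomputable"


class TestIntegrateIhh:
    def test_hand_trapezoid(self):
        # {(0,1),(10 kb,0.5),(20 kb,0.05)} at 1 cM/Mb -> 10250 bp-equivalents
        c = curve([(0.0, 1.0, 0), (0.01, 0.5, 10_000), (0.02, 0.05, 20_000)])
        ihh, status = integrate_ihh(c, POINT)
        assert ihh == pytest.approx(0.01025)
        assert status == "ok"

    def test_flat_rectangle(self):
        c = curve([(0.0, 1.0, 0), (0.01, 1.0, 10_000)])
        ihh, _ = integrate_ihh(c, POINT)
        assert ihh == pytest.approx(0.01)

    def test_gap_scaling_halves_wide_span(self):
        # 40 kb between markers with gap_scale 20 kb -> that area times 0.5
        c = curve([(0.0, 1.0, 0), (0.04, 0.5, 40_000)])
        ihh, _ = integrate_ihh(c, POINT)
        assert ihh == pytest.approx(0.5 * (1 + 0.5) / 2 * 0.04)

    def test_edge_reached_flags_truncated(self):
        c = curve([(0.0, 1.0, 0), (0.01, 0.5, 10_000)], status="edge_reached")
        _, status = integrate_ihh(c, POINT)
        assert status == "truncated"

    def test_gap_discarded_propagates(self):
        c = curve([(0.0, 1.0, 0)], status="gap_discarded")
        ihh, status = integrate_ihh(c, POINT)
        assert status == "gap_discarded" and ihh == 0.0


class TestIhsScan:
    def test_mirror_classes_score_zero(self):
        # derived and ancestral carrier classes with identical structure
        block = np.array([[1, 0, 1, 0, 1],
                          [1, 0, 1, 1, 1],
                          [1, 1, 1, 0, 0]], dtype=np.uint8)
        mirror = block.copy()
        mirror[:, 2] = 0   # identical flanks, opposite core allele at site 2
        m = make_matrix(np.vstack([block, mirror]))
        df = ihs_scan(m, ScanConfig(maf_min=0.01, trunc_ok=True))
        row = df[df["pos"] == 3000].iloc[0]
        assert row["raw"] == pytest.approx(0.0, abs=1e-12)

    def test_log_ratio_arithmetic(self):
        assert np.log(10250 / 5125) == pytest.approx(np.log(2))

    def test_scale_equivariance(self, rng):
        # multiplying all inter-marker distances by c scales iHH by c and
        # leaves iHS unchanged (distances via an explicit genetic map)
        m = random_matrix(rng, n_hap=16, n_sites=30)
        g1 = np.cumsum(rng.random(30)) * 0.01
        m1 = make_matrix(m.alleles, positions=m.positions, genetic_pos=g1)
        m2 = make_matrix(m.alleles, positions=m.positions, genetic_pos=g1 * 3)
        cfg = ScanConfig(maf_min=0.01, trunc_ok=True, max_gap_bp=10**9)
        df1 = ihs_scan(m1, cfg)
        df2 = ihs_scan(m2, cfg)
        ok = (df1["status"] == "ok") & (df2["status"] == "ok")
        np.testing.assert_allclose(df2.loc[ok, "ihh_d"],
                                   3 * df1.loc[ok, "ihh_d"], rtol=1e-9)
        np.testing.assert_allclose(df2.loc[ok, "raw"], df1.loc[ok, "raw"],
                                   rtol=1e-9, atol=1e-12)

    def test_low_maf_and_empty_matrix(self, tiny_matrix):
        alleles = np.zeros((40, 2), dtype=np.uint8)
        alleles[:, 0] = np.arange(40) % 2
        alleles[0, 1] = 1
        df = ihs_scan(make_matrix(alleles))
        assert df["status"].tolist()[1] == "maf"
        with pytest.raises(ValueError):
            ihs_scan(tiny_matrix.take_sites(np.array([], dtype=int)))

    def test_planted_sweep_exceeds_neutral_background(self):
        """|raw iHS| at a hard-sweep site beats the 95th percentile of
        |raw iHS| at frequency-matched neutral sites (fixed seed)."""
        params = SweepSimParams(N=200, L=60_000, mu=5e-7, r=2e-6, s=0.1,
                                target_freq=0.6, sample_n=60, seed=11,
                                init_model="coalescent")
        m = simulate_wf(params)
        df = ihs_scan(m, ScanConfig(trunc_ok=True))
        sweep = df[df["pos"] == params.sweep_pos]
        assert len(sweep) == 1 and sweep["status"].iloc[0] == "ok"
        f = sweep["freq_derived"].iloc[0]
        neutral = df[(df["status"] == "ok") & (df["pos"] != params.sweep_pos)
                     & (df["freq_derived"].between(f - 0.15, f + 0.15))]
        assert len(neutral) >= 10
        thresh = np.quantile(np.abs(neutral["raw"]), 0.95)
        assert abs(sweep["raw"].iloc[0]) > thresh


class TestXpehhScan:
    def test_identical_populations_score_zero(self, rng):
        m = random_matrix(rng, n_hap=14, n_sites=40)
        df = xpehh_scan(m, m, ScanConfig(maf_min=0.01, trunc_ok=True))
        ok = df["status"] == "ok"
        assert ok.any()
        np.testing.assert_allclose(df.loc[ok, "raw"], 0.0, atol=1e-12)

    def test_antisymmetry_under_population_swap(self, rng):
        a = random_matrix(rng, n_hap=12, n_sites=40)
        b = random_matrix(rng, n_hap=10, n_sites=40)
        cfg = ScanConfig(maf_min=0.01, trunc_ok=True)
        ab = xpehh_scan(a, b, cfg)
        ba = xpehh_scan(b, a, cfg)
        ok = (ab["status"] == "ok") & (ba["status"] == "ok")
        assert ok.any()
        np.testing.assert_allclose(ab.loc[ok, "raw"], -ba.loc[ok, "raw"],
                                   atol=1e-12)
        assert (ab["status"] == ba["status"]).all()

    def test_site_intersection_by_position(self, rng):
        a = random_matrix(rng, n_hap=10, n_sites=20)
        b = a.take_sites(np.arange(5, 15))
        df = xpehh_scan(a, b, ScanConfig(maf_min=0.01, trunc_ok=True))
        assert len(df) == 10

    def test_too_few_haplotypes_skipped(self, rng):
        a = random_matrix(rng, n_hap=10, n_sites=12)
        b = a.take_haplotypes([0])
        df = xpehh_scan(a, b)
        assert (df["status"] == "too_few_haplotypes").all()
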