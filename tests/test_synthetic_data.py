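"""Forward Wright-Fisher simulator: ground truth, determinism, round trips."""

import numpy as np
import pytest

from sweepscan import (ScanConfig, SweepSimParams, ihs_scan, read_phased_vcf,
                       simulate_split, simulate_wf, standardize_scores,
                       write_fixture_vcf, write_panel)
from sweepscan.haplotype_io import read_panel

from conftest import make_matrix


class TestSimulateWf:
    def test_no_mutation_no_sites(self):
        m = simulate_wf(SweepSimParams(N=20, L=10_000, mu=0.0, r=1e-8,
                                       sample_n=10, seed=1, burn_in=50))
        assert m.n_sites == 0

    def test_deterministic_given_seed(self):
        params = SweepSimParams(N=30, L=20_000, mu=1e-6, r=1e-6,
                                sample_n=12, seed=9, burn_in=150)
        m1 = simulate_wf(params)
        m2 = simulate_wf(params)
        np.testing.assert_array_equal(m1.alleles, m2.alleles)
        np.testing.assert_array_equal(m1.positions, m2.positions)
        m3 = simulate_wf(SweepSimParams(N=30, L=20_000, mu=1e-6, r=1e-6,
                                        sample_n=12, seed=10, burn_in=150))
        assert m3.n_sites != m1.n_sites or not np.array_equal(
            m3.alleles, m1.alleles)

    def test_no_recombination_gives_perfect_phylogeny(self):
        """With r=0 every haplotype is a founder copy plus private
        mutations, so carrier sets of any two sites are nested or
        disjoint (the classic four-gamete condition never fails)."""
        m = simulate_wf(SweepSimParams(N=25, L=30_000, mu=2e-6, r=0.0,
                                       sample_n=16, seed=4, burn_in=200))
        assert m.n_sites >= 2
        A = m.alleles.astype(bool)
        for i in range(m.n_sites):
            for j in range(i + 1, m.n_sites):
                a, b = A[:, i], A[:, j]
                gametes = {(x, y) for x, y in zip(a, b)}
                assert len(gametes) <= 3  # four-gamete test

    def test_sweep_conditioning_reaches_target(self):
        params = SweepSimParams(N=50, L=30_000, mu=1e-6, r=1e-6, s=0.1,
                                target_freq=0.6, sample_n=30, seed=5,
                                init_model="coalescent")
        m = simulate_wf(params)
        sel = m.positions == params.sweep_pos
        assert sel.any()
        f = float(m.alleles[:, sel].mean())
        # population frequency conditioned at 0.6; sample freq is noisy
        assert 0.35 <= f <= 0.85

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SweepSimParams(N=5)
        with pytest.raises(ValueError):
            SweepSimParams(N=20, sample_n=100)
        with pytest.raises(ValueError):
            SweepSimParams(N=20, s=2.0)

    def test_neutral_scores_rarely_extreme(self):
        """In-sample standardized neutral iHS exceeds |2.75| for at most
        2% of scored sites."""
        params = SweepSimParams(N=300, L=150_000, mu=4e-7, r=1e-6,
                                sample_n=50, seed=21, init_model="coalescent")
        m = simulate_wf(params)
        df = ihs_scan(m, ScanConfig(trunc_ok=True))
        df = standardize_scores(df, "ihs")
        std = df["std"].dropna()
        assert len(std) >= 150
        assert (std.abs() > 2.75).mean() <= 0.02


class TestSimulateSplit:
    def test_no_divergence_at_split_zero(self):
        params = SweepSimParams(N=60, L=60_000, mu=5e-7, r=1e-6, split_T=0,
                                sample_n=30, seed=6, init_model="coalescent")
        m1, m2 = simulate_split(params)
        p1, p2 = m1.alleles.mean(0), m2.alleles.mean(0)
        from sweepscan import hudson_fst_multilocus
        f = hudson_fst_multilocus(p1, m1.n_haplotypes, p2, m2.n_haplotypes)
        assert abs(f) < 0.03

    def test_union_site_set_and_matching_positions(self):
        params = SweepSimParams(N=40, L=40_000, mu=1e-6, r=1e-6, split_T=10,
                                sample_n=20, seed=7, init_model="coalescent")
        m1, m2 = simulate_split(params)
        np.testing.assert_array_equal(m1.positions, m2.positions)
        combined = np.vstack([m1.alleles, m2.alleles])
        sums = combined.sum(axis=0)
        assert (sums > 0).all() and (sums < combined.shape[0]).all()

    def test_same_seed_identical(self):
        params = SweepSimParams(N=40, L=40_000, mu=1e-6, r=1e-6, split_T=10,
                                sample_n=20, seed=8, init_model="coalescent")
        a1, a2 = simulate_split(params)
        b1, b2 = simulate_split(params)
        np.testing.assert_array_equal(a1.alleles, b1.alleles)
        np.testing.assert_array_equal(a2.alleles, b2.alleles)


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path, rng):
        params = SweepSimParams(N=30, L=20_000, mu=1.5e-6, r=1e-6,
                                sample_n=12, seed=13, burn_in=150)
        m = simulate_wf(params)
        vcf = tmp_path / "fix.vcf"
        panel = tmp_path / "fix.panel.tsv"
        write_fixture_vcf(m, str(vcf))
        write_panel(m, str(panel))
        (m2,), log = read_phased_vcf(str(vcf), str(panel))
        np.testing.assert_array_equal(m2.alleles, m.alleles)
        np.testing.assert_array_equal(m2.positions, m.positions)
        assert list(m2.haplotype_owner) == list(m.haplotype_owner)
        assert log.n_dropped_sites == 0
        assert m2.ancestral_known.all()  # AA tag present at every site

    def test_round_trip_with_flipped_ancestral(self, tmp_path):
        m = make_matrix([[0, 1], [1, 0], [1, 1], [0, 0]])
        m.ancestral_is_ref[1] = False  # derived allele is REF at site 2
        write_fixture_vcf(m, str(tmp_path / "f.vcf"))
        write_panel(m, str(tmp_path / "p.tsv"))
        (m2,), _ = read_phased_vcf(str(tmp_path / "f.vcf"),
                                   str(tmp_path / "p.tsv"))
        np.testing.assert_array_equal(m2.alleles, m.alleles)
        assert not m2.ancestral_is_ref[1]

    def test_hemizygous_sample_round_trip(self, tmp_path):
        m = make_matrix([[0, 1], [1, 0], [1, 1]])
        m.haplotype_owner = np.array(["ind0", "ind0", "ind1"], dtype=object)
        write_fixture_vcf(m, str(tmp_path / "x.vcf"))
        write_panel(m, str(tmp_path / "p.tsv"))
        (m2,), _ = read_phased_vcf(str(tmp_path / "x.vcf"),
                                   str(tmp_path / "p.tsv"))
        np.testing.assert_array_equal(m2.alleles, m.alleles)

    def test_owner_with_three_rows_rejected(self, tmp_path):
        m = make_matrix([[0], [1], [1]])
        m.haplotype_owner = np.array(["ind0"] * 3, dtype=object)
        with pytest.raises(ValueError, match="3 haplotype rows"):
            write_fixture_vcf(m, str(tmp_path / "bad.vcf"))

    def test_panel_matches_fixture(self, tmp_path):
        params = SweepSimParams(N=20, L=10_000, mu=1e-6, r=0.0, sample_n=8,
                                seed=2, burn_in=100)
        m = simulate_wf(params, population="EUR")
        write_panel(m, str(tmp_path / "panel.tsv"))
        panel = read_panel(str(tmp_path / "panel.tsv"))
        assert set(panel.values()) == {"EUR"}
        assert len(panel) == 4  # 8 haplotypes -> 4 diploid samples


def test_sweep_power_ordering():
    """Detection rate of a planted s=0.1 sweep strictly exceeds the rate
    at matched neutral sites (s=0) over 50 replicates each; detection is
    |raw iHS| above the 95th percentile of frequency-matched neutral
    scores pooled across replicates."""
    from scipy.stats import binomtest

    def focal_scores(s, seed0, n_rep):
        hits = []
        pool_abs = []
        pool_freq = []
        focals = []
        for k in range(n_rep):
            params = SweepSimParams(N=300, L=60_000, mu=4e-7, r=2e-6, s=s,
                                    target_freq=0.6 if s > 0 else None,
                                    sample_n=60, seed=seed0 + k,
                                    init_model="coalescent")
            m = simulate_wf(params)
            df = ihs_scan(m, ScanConfig(trunc_ok=True))
            ok = df[df["status"] == "ok"]
            if s > 0:
                focal = ok[ok["pos"] == params.sweep_pos]
            else:
                band = ok[ok["freq_derived"].between(0.4, 0.8)]
                if band.empty:
                    focal = band
                else:
                    focal = band.iloc[[int(np.argmin(
                        np.abs(band["pos"] - params.sweep_pos)))]]
            neutral = ok[ok["pos"] != params.sweep_pos]
            pool_abs.extend(np.abs(neutral["raw"]))
            pool_freq.extend(neutral["freq_derived"])
            focals.append(focal)
        pool_abs = np.asarray(pool_abs)
        pool_freq = np.asarray(pool_freq)
        for focal in focals:
            if focal.empty:
                hits.append(False)
                continue
            f = focal["freq_derived"].iloc[0]
            matched = pool_abs[np.abs(pool_freq - f) <= 0.1]
            thresh = np.quantile(matched, 0.95)
            hits.append(abs(focal["raw"].iloc[0]) > thresh)
        return np.asarray(hits)

    sweep_hits = focal_scores(0.1, 7000, 50)
    null_hits = focal_scores(0.0, 8000, 50)
    p0 = max(null_hits.mean(), 0.05)
    res = binomtest(int(sweep_hits.sum()), 50, p0, alternative="greater")
    assert sweep_hits.mean() > null_hits.mean()
    assert res.pvalue < 0.01
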