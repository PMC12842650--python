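"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: EHH by
enumerating carrier pairs and testing prefix identity, Hardy-Weinberg by
full enumeration of the conditional heterozygote distribution with exact
binomial coefficients, LD by direct 2x2 haplotype counting, and
Weir-Cockerham by longhand variance components.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from sweepscan import HaplotypeMatrix, ScanConfig


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def ehh_oracle(alleles: np.ndarray, carrier_rows, core: int, target: int
               ) -> float:
    """EHH at marker ``target``: carrier pairs identical at every marker
    from ``core`` through ``target`` (inclusive), over all carrier pairs."""
    rows = list(carrier_rows)
    lo, hi = min(core, target), max(core, target)
    span = alleles[np.asarray(rows), lo:hi + 1]
    n = len(rows)
    ident = 0
    for i, j in combinations(range(n), 2):
        if np.array_equal(span[i], span[j]):
            ident += 1
    return ident / (n * (n - 1) / 2)


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration of heterozygote counts.

    Conditional on n diploids and the minor-allele count, P(h) is
    proportional to n! 2^h / (h! n1! n2!) with n1, n2 the homozygote
    counts; the p-value sums P over all h no more probable than observed.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        probs[h] = (math.factorial(n) * 2 ** h
                    / (math.factorial(h) * math.factorial(hom_minor)
                       * math.factorial(hom_major)))
    norm = sum(probs.values())
    p_obs = probs[n_Aa] / norm
    return min(1.0, sum(p for p in (v / norm for v in probs.values())
                        if p <= p_obs * (1 + 1e-12)))


def ld_2x2_oracle(a: np.ndarray, b: np.ndarray) -> dict:
    """LD coefficients from explicit 2x2 haplotype counts."""
    n = len(a)
    n11 = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    pA = sum(a) / n
    pB = sum(b) / n
    pAB = n11 / n
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return {
        "pAB": pAB, "D": D,
        "d_prime": D / dmax if dmax > 0 else 0.0,
        "r2": D * D / (pA * (1 - pA) * pB * (1 - pB)),
    }


def wc_oracle(counts1: tuple, counts2: tuple) -> float:
    """Longhand Weir-Cockerham a/(a+b+c) for two diploid populations."""
    pops = [counts1, counts2]
    r = 2
    n_i = [sum(c) for c in pops]
    p_i = [(2 * c[2] + c[1]) / (2 * n) for c, n in zip(pops, n_i)]
    h_i = [c[1] / n for c, n in zip(pops, n_i)]
    n_bar = sum(n_i) / r
    n_c = (sum(n_i) - sum(x * x for x in n_i) / sum(n_i)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                               - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a / (a + b + c)


# ---------------------------------------------------------------------------
# Matrix construction helpers
# ---------------------------------------------------------------------------

def make_matrix(alleles, positions=None, populations=None, chrom="1",
                genetic_pos=None) -> HaplotypeMatrix:
    """HaplotypeMatrix from a plain 0/1 array with sensible metadata."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_sites = alleles.shape
    if positions is None:
        positions = 1000 * (np.arange(n_sites) + 1)
    positions = np.asarray(positions, dtype=np.int64)
    if populations is None:
        populations = ["POP1"] * n_hap
    owners = [f"ind{i // 2}" for i in range(n_hap)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=positions,
        site_ids=np.array([f"s{p}" for p in positions], dtype=object),
        alleles=alleles,
        haplotype_owner=np.array(owners, dtype=object),
        population=np.array(list(populations), dtype=object),
        genetic_pos=genetic_pos,
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["G"] * n_sites, dtype=object),
    )


def random_matrix(rng: np.random.Generator, n_hap=None, n_sites=None,
                  **kwargs) -> HaplotypeMatrix:
    n_hap = n_hap or int(rng.integers(4, 21))
    n_sites = n_sites or int(rng.integers(3, 51))
    # reject monomorphic-everywhere draws for usable fixtures
    alleles = rng.integers(0, 2, size=(n_hap, n_sites))
    return make_matrix(alleles, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def sweep_study():
    """50 planted-sweep split replicates through the full pipeline.

    Study conditions: a hard sweep (genic s = 0.1) planted in population A
    at the moment of a split from population B, conditioned on reaching
    derived frequency 0.75 (inside the 0.4-0.8 band); N = 1000 diploids
    (2Ns = 200, the strongest sweep the desk-scale forward model supports),
    a 100 kb region with human-like scaled diversity, 80 sampled
    haplotypes per population.  Scores are standardized and ranked against
    the pool of all replicates, mirroring genome-wide normalization, and
    candidates are called at the pipeline's default thresholds.
    """
    from sweepscan import SweepSimParams, simulate_split
    from sweepscan.pipeline import finalize_scans, raw_two_population_scan

    raws, params = [], []
    for k in range(50):
        p = SweepSimParams(N=1000, L=100_000, mu=2e-7, r=1e-6, s=0.1,
                           target_freq=0.75, sample_n=80, seed=k,
                           init_model="coalescent")
        mA, mB = simulate_split(p, pop_names=("A", "B"))
        raws.append(raw_two_population_scan(mA, mB, scan_ref_ihs=False))
        params.append(p)
    reps = finalize_scans(raws)
    return {"reps": reps, "params": params}


@pytest.fixture
def config() -> ScanConfig:
    return ScanConfig()


@pytest.fixture
def tiny_matrix() -> HaplotypeMatrix:
    """6 haplotypes x 5 sites, hand-written, all polymorphic."""
    return make_matrix([
        [0, 0, 1, 0, 1],
        [0, 0, 1, 0, 1],
        [0, 1, 1, 0, 0],
        [1, 1, 0, 1, 0],
        [1, 0, 0, 1, 0],
        [1, 0, 0, 1, 1],
    ])
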