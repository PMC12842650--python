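"""Core containers shared by every stage of the selection scan.

The central object is :class:`HaplotypeMatrix`: a phased, biallelic,
fully-called haplotype sample for one chromosome, with alleles recoded so
that 0 is the ancestral and 1 the derived state.  Every statistic in the
package (EHH, iHS, xp-EHH, FST, LD) is a function of this matrix plus a
:class:`ScanConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "ScanConfig",
    "EhhCurve",
    "SweepSimParams",
    "CM_PER_BP_DEFAULT",
]

# Uniform-map fallback: 1 cM/Mb, the genome-wide human average.
CM_PER_BP_DEFAULT = 1e-6


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome label (as written in the VCF, e.g. ``"4"``).
    positions
        1-based physical coordinate per site, strictly increasing.
    site_ids
        Variant identifier per site (rsID or a synthetic id).
    alleles
        ``(n_haplotypes, n_sites)`` array of 0/1; 0 = ancestral allele,
        1 = derived allele.  No missing values.
    haplotype_owner
        Sample identifier per haplotype row (two rows per diploid sample,
        one per hemizygous sample).
    population
        Population label per haplotype row.
    genetic_pos
        Optional map position per site in cM, non-decreasing.  When absent,
        distances fall back to physical bp at ``CM_PER_BP_DEFAULT``.
    ancestral_known
        Per-site flag: True where the ancestral allele was resolved from an
        explicit source, False where REF was assumed ancestral.
    ref_allele, alt_allele
        REF/ALT strings from the VCF (kept for table output and round-trip
        writing).  The *derived* allele string at site ``j`` is ``alt[j]``
        when the ancestral allele equals REF, else ``ref[j]``.
    ancestral_is_ref
        True where the ancestral allele equals the VCF REF allele.
    """

    chrom: str
    positions: np.ndarray
    site_ids: np.ndarray
    alleles: np.ndarray
    haplotype_owner: np.ndarray
    population: np.ndarray
    genetic_pos: Optional[np.ndarray] = None
    ancestral_known: Optional[np.ndarray] = None
    ref_allele: Optional[np.ndarray] = None
    alt_allele: Optional[np.ndarray] = None
    ancestral_is_ref: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.uint8))
        self.haplotype_owner = np.asarray(self.haplotype_owner, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        n_hap, n_sites = self.alleles.shape
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length does not match allele columns")
        if self.site_ids.shape != (n_sites,):
            raise ValueError("site_ids length does not match allele columns")
        if self.haplotype_owner.shape != (n_hap,) or self.population.shape != (n_hap,):
            raise ValueError("per-haplotype labels do not match allele rows")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing within a chromosome")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele entries must be 0 or 1")
        if self.genetic_pos is not None:
            self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
            if self.genetic_pos.shape != (n_sites,):
                raise ValueError("genetic_pos length does not match allele columns")
            if n_sites > 1 and np.any(np.diff(self.genetic_pos) < 0):
                raise ValueError("genetic_pos must be non-decreasing")
        if self.ancestral_known is None:
            self.ancestral_known = np.ones(n_sites, dtype=bool)
        else:
            self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)
        if self.ref_allele is not None:
            self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        if self.alt_allele is not None:
            self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        if self.ancestral_is_ref is None:
            self.ancestral_is_ref = np.ones(n_sites, dtype=bool)
        else:
            self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def map_positions(self) -> np.ndarray:
        """Map coordinate per site in cM (genetic map, or 1 cM/Mb fallback)."""
        if self.genetic_pos is not None:
            return self.genetic_pos
        return self.positions * CM_PER_BP_DEFAULT

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per site over all haplotypes."""
        return self.alleles.mean(axis=0)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(str(p), None)
        return list(seen)

    def rows_for_population(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.population == pop)

    # -- subsetting ------------------------------------------------------
    def take_sites(self, index) -> "HaplotypeMatrix":
        """New matrix restricted to the given site index/boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        def _opt(a):
            return None if a is None else a[index]
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[index],
            site_ids=self.site_ids[index],
            alleles=self.alleles[:, index],
            haplotype_owner=self.haplotype_owner,
            population=self.population,
            genetic_pos=_opt(self.genetic_pos),
            ancestral_known=self.ancestral_known[index],
            ref_allele=_opt(self.ref_allele),
            alt_allele=_opt(self.alt_allele),
            ancestral_is_ref=self.ancestral_is_ref[index],
        )

    def take_haplotypes(self, index) -> "HaplotypeMatrix":
        """New matrix restricted to the given haplotype rows."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            alleles=self.alleles[index, :],
            haplotype_owner=self.haplotype_owner[index],
            population=self.population[index],
        )

    def subset_population(self, pop: str) -> "HaplotypeMatrix":
        rows = self.rows_for_population(pop)
        if rows.size == 0:
            raise ValueError(f"no haplotypes labelled {pop!r}")
        return self.take_haplotypes(rows)

    def derived_allele_strings(self) -> np.ndarray:
        """Derived-allele string per site (requires ref/alt metadata)."""
        if self.ref_allele is None or self.alt_allele is None:
            raise ValueError("matrix carries no REF/ALT metadata")
        return np.where(self.ancestral_is_ref, self.alt_allele, self.ref_allele)

    def ancestral_allele_strings(self) -> np.ndarray:
        if self.ref_allele is None or self.alt_allele is None:
            raise ValueError("matrix carries no REF/ALT metadata")
        return np.where(self.ancestral_is_ref, self.ref_allele, self.alt_allele)


@dataclass
class ScanConfig:
    """Tunable parameters for the whole scan pipeline.

    Defaults follow common selection-scan practice: Selscan's EHH truncation
    cutoff (0.05), gap handling (down-weight spans beyond 20 kb, discard
    beyond 200 kb) and MAF floor (0.05); 100 derived-frequency bins for iHS
    standardization; |iHS| > 2.75 and |xp-EHH| > 2.806 significance
    thresholds (empirical p < 0.01); >=20 hits per non-overlapping 100 kb
    window for region calls; HWE exact-test alpha 1e-6; FST outlier alpha
    0.05; LD decay with 0.01 thinning, 200 kb range, 5 kb bins; r2 > 0.95
    for candidate-query linkage.
    """

    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    gap_scale_bp: int = 20_000
    maf_min: float = 0.05
    ihs_threshold: float = 2.75
    xpehh_threshold: float = 2.806
    window_size_bp: int = 100_000
    window_min_hits: int = 20
    hwe_alpha: float = 1e-6
    fst_outlier_alpha: float = 0.05
    ld_r2_link: float = 0.95
    ld_thin: float = 0.01
    ld_max_bp: int = 200_000
    ld_bin_bp: int = 5_000
    norm_bins: int = 100
    trunc_ok: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ehh_cutoff < 1):
            raise ValueError("ehh_cutoff must be in (0,1)")
        if self.window_min_hits < 1:
            raise ValueError("window_min_hits must be >= 1")
        for name in ("max_gap_bp", "gap_scale_bp", "maf_min", "ihs_threshold",
                     "xpehh_threshold", "window_size_bp", "hwe_alpha",
                     "fst_outlier_alpha", "ld_r2_link", "ld_thin", "ld_max_bp",
                     "ld_bin_bp", "norm_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EhhCurve:
    """One-directional EHH decay curve from a core site.

    ``distances`` are map units (cM) from the core, starting at 0 where
    EHH = 1 by definition; ``bp_positions`` carries the physical coordinate
    of each point (used for gap scaling during integration).  ``status`` is
    one of ``cutoff_reached`` / ``edge_reached`` / ``gap_discarded`` /
    ``uncomputable``.
    """

    core_site: object
    direction: str
    distances: np.ndarray
    ehh: np.ndarray
    bp_positions: np.ndarray
    status: str

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.ehh = np.asarray(self.ehh, dtype=float)
        self.bp_positions = np.asarray(self.bp_positions, dtype=np.int64)


@dataclass
class SweepSimParams:
    """Forward Wright-Fisher simulation settings.

    Rates are per-bp per-generation.  ``s`` is a genic selection
    coefficient: a haplotype carrying the sweep allele is sampled as a
    parent with weight ``1 + s``.  ``target_freq`` conditions the sweep: the
    simulation stops when the sweep allele reaches that population
    frequency, restarting from the post-burn-in state whenever the allele
    is lost (bounded number of restarts).
    """

    N: int = 100
    L: int = 1_000_000
    mu: float = 1e-8
    r: float = 1e-8
    s: float = 0.0
    sweep_pos: Optional[int] = None
    target_freq: Optional[float] = None
    split_T: int = 0
    burn_in: Optional[int] = None
    sample_n: int = 40
    seed: int = 0
    max_restarts: int = 1000
    max_sweep_generations: Optional[int] = None
    init_model: str = "founders"

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if not (0 <= self.s <= 1):
            raise ValueError("s must be in [0,1]")
        if self.sweep_pos is None:
            self.sweep_pos = self.L // 2
        if not (1 <= self.sweep_pos <= self.L):
            raise ValueError("sweep_pos must lie in [1, L]")
        if self.sample_n > 2 * self.N:
            raise ValueError("sample_n cannot exceed 2N haplotypes")
        if self.init_model not in ("founders", "coalescent"):
            raise ValueError("init_model must be 'founders' or 'coalescent'")
        if self.burn_in is None:
            # identical founders need ~10N generations to reach mutation-drift
            # equilibrium; a coalescent-equilibrium start needs none
            self.burn_in = 0 if self.init_model == "coalescent" else 10 * self.N
        if self.max_sweep_generations is None:
            self.max_sweep_generations = 100 * self.N
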