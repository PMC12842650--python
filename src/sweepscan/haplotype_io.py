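"""Phased-VCF input, ancestral-allele recoding and site filtering.

Loads phased diploid (or hemizygous) genotypes plus a sample->population
panel into :class:`~sweepscan.datatypes.HaplotypeMatrix` objects, one per
chromosome, with alleles recoded to 0 = ancestral / 1 = derived.  Ancestral
states are resolved, in priority order, from an explicit TSV, from the VCF
INFO ``AA`` tag, or by assuming REF is ancestral (flagged per site).

Site-level statistics (per-population derived frequencies, MAF, a
Hardy-Weinberg exact test per population) feed the filters applied before
any haplotype statistic is computed: EHH-family scores need complete,
phased, biallelic data, and sites out of Hardy-Weinberg equilibrium at
p < 1e-6 in any population are treated as genotyping artefacts and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import HaplotypeMatrix, ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_panel",
    "read_ancestral_tsv",
    "read_genetic_map",
    "read_phased_vcf",
    "VcfLoadLog",
    "hwe_exact_test",
    "compute_site_stats",
    "site_filter",
    "write_site_stats",
]


@dataclass
class VcfLoadLog:
    """Counts and identities of records dropped during VCF loading."""

    multiallelic: list = field(default_factory=list)
    missing_or_unphased: list = field(default_factory=list)
    ancestral_mismatch: list = field(default_factory=list)
    non_increasing: list = field(default_factory=list)
    skipped_samples: list = field(default_factory=list)

    @property
    def n_dropped_sites(self) -> int:
        return (len(self.multiallelic) + len(self.missing_or_unphased)
                + len(self.ancestral_mismatch) + len(self.non_increasing))


def read_panel(panel_path: str) -> dict[str, str]:
    """Read a ``sample<TAB>population`` panel (header required)."""
    df = pd.read_csv(panel_path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample" not in cols or "population" not in cols:
        raise ValueError("panel must have 'sample' and 'population' columns")
    df.columns = cols
    return dict(zip(df["sample"], df["population"]))


def read_ancestral_tsv(path: str) -> dict[tuple[str, int], str]:
    """Read an ancestral-allele table ``chrom<TAB>pos<TAB>allele``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "allele"],
                     dtype={"chrom": str, "pos": np.int64, "allele": str},
                     comment="#")
    return {(c, int(p)): a.upper() for c, p, a in
            zip(df["chrom"], df["pos"], df["allele"])}


def read_genetic_map(path: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a genetic map ``chrom<TAB>pos_bp<TAB>cM`` into interp tables."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "cm"],
                     dtype={"chrom": str, "pos": np.int64, "cm": float},
                     comment="#")
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        out[str(chrom)] = (grp["pos"].to_numpy(), grp["cm"].to_numpy())
    return out


def _resolve_ancestral(chrom: str, pos: int, ref: str, alt: str,
                       aa_info: Optional[str],
                       ancestral_map: Optional[dict]) -> tuple[Optional[str], bool]:
    """Pick the ancestral allele string; None means unresolvable (drop site).

    Priority: explicit TSV > INFO AA tag > REF fallback (known=False).
    The 1000 Genomes AA tag may carry extra fields ("a|||"): only the first
    field is used, case-folded to upper.
    """
    if ancestral_map is not None:
        aa = ancestral_map.get((chrom, pos))
        if aa is not None:
            if aa in (ref, alt):
                return aa, True
            return None, True
    if aa_info:
        aa = str(aa_info).split("|")[0].strip().upper()
        if aa in (ref, alt):
            return aa, True
        if aa not in ("", ".", "-", "N"):
            return None, True
        # uninformative tag -> fall through to REF
    return ref, False


def read_phased_vcf(
    vcf_path: str,
    panel_path: Optional[str] = None,
    ancestral_tsv: Optional[str] = None,
    genetic_map: Optional[str] = None,
) -> tuple[list[HaplotypeMatrix], VcfLoadLog]:
    """Load a phased VCF into one HaplotypeMatrix per chromosome.

    Every retained site is biallelic with a fully-called, phased GT for
    every panel sample; sites violating this are dropped and logged.  Sites
    whose resolved ancestral allele matches neither REF nor ALT are dropped.
    Samples absent from the panel are skipped with a warning; panel samples
    absent from the VCF raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    vcf_samples = list(vcf.samples)
    if panel_path is not None:
        panel = read_panel(panel_path)
    else:
        panel = {s: "ALL" for s in vcf_samples}
    log = VcfLoadLog()
    for s in vcf_samples:
        if s not in panel:
            logger.warning("sample %s not in panel; skipped", s)
            log.skipped_samples.append(s)
    keep = [i for i, s in enumerate(vcf_samples) if s in panel]
    if not keep:
        raise ValueError("no VCF sample appears in the panel")
    missing_panel = set(panel) - set(vcf_samples)
    if panel_path is not None and missing_panel:
        logger.warning("%d panel samples absent from VCF", len(missing_panel))
    samples = [vcf_samples[i] for i in keep]

    ancestral_map = read_ancestral_tsv(ancestral_tsv) if ancestral_tsv else None
    gmap = read_genetic_map(genetic_map) if genetic_map else None

    # per-chromosome accumulators
    chroms: list[str] = []
    acc: dict[str, dict] = {}

    for var in vcf:
        chrom = var.CHROM
        if chrom not in acc:
            chroms.append(chrom)
            acc[chrom] = {"pos": [], "ids": [], "cols": [], "ref": [], "alt": [],
                          "known": [], "anc_is_ref": [], "ploidy": None}
        a = acc[chrom]
        if len(var.ALT) != 1 or not var.ALT[0] or var.ALT[0] == ".":
            log.multiallelic.append(var.ID or f"{chrom}:{var.POS}")
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        aa, known = _resolve_ancestral(chrom, var.POS, ref, alt,
                                       var.INFO.get("AA"), ancestral_map)
        if aa is None:
            log.ancestral_mismatch.append(var.ID or f"{chrom}:{var.POS}")
            continue
        gts = var.genotypes  # [a0, a1, phased] or [a0, phased] for haploid
        hap: list[int] = []
        ploidy: list[int] = []
        ok = True
        for i in keep:
            g = gts[i]
            alleles, phased = g[:-1], g[-1]
            if any(x < 0 for x in alleles):
                ok = False
                break
            if len(alleles) == 2 and not phased:
                # a homozygous diploid call carries no phase ambiguity
                if alleles[0] != alleles[1]:
                    ok = False
                    break
            if len(alleles) > 2:
                ok = False
                break
            hap.extend(int(x) for x in alleles)
            ploidy.append(len(alleles))
        if not ok:
            log.missing_or_unphased.append(var.ID or f"{chrom}:{var.POS}")
            continue
        if a["ploidy"] is None:
            a["ploidy"] = ploidy
        elif a["ploidy"] != ploidy:
            log.missing_or_unphased.append(var.ID or f"{chrom}:{var.POS}")
            continue
        if a["pos"] and var.POS <= a["pos"][-1]:
            log.non_increasing.append(var.ID or f"{chrom}:{var.POS}")
            continue
        col = np.asarray(hap, dtype=np.uint8)
        anc_is_ref = aa == ref
        if not anc_is_ref:
            col = 1 - col
        a["pos"].append(var.POS)
        a["ids"].append(var.ID if var.ID not in (None, ".") else f"{chrom}:{var.POS}")
        a["cols"].append(col)
        a["ref"].append(ref)
        a["alt"].append(alt)
        a["known"].append(known)
        a["anc_is_ref"].append(anc_is_ref)

    matrices: list[HaplotypeMatrix] = []
    for chrom in chroms:
        a = acc[chrom]
        if not a["cols"]:
            continue
        owners: list[str] = []
        pops: list[str] = []
        for s, p in zip(samples, a["ploidy"]):
            owners.extend([s] * p)
            pops.extend([panel[s]] * p)
        alleles = np.stack(a["cols"], axis=1)
        gpos = None
        if gmap is not None and chrom in gmap:
            mp, mc = gmap[chrom]
            gpos = np.interp(np.asarray(a["pos"], dtype=float), mp, mc)
        matrices.append(HaplotypeMatrix(
            chrom=chrom,
            positions=np.asarray(a["pos"], dtype=np.int64),
            site_ids=np.asarray(a["ids"], dtype=object),
            alleles=alleles,
            haplotype_owner=np.asarray(owners, dtype=object),
            population=np.asarray(pops, dtype=object),
            genetic_pos=gpos,
            ancestral_known=np.asarray(a["known"], dtype=bool),
            ref_allele=np.asarray(a["ref"], dtype=object),
            alt_allele=np.asarray(a["alt"], dtype=object),
            ancestral_is_ref=np.asarray(a["anc_is_ref"], dtype=bool),
        ))
    if not matrices:
        raise ValueError(f"no usable phased biallelic sites in {vcf_path}")
    return matrices, log


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test on diploid genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one
    (PLINK-style, no mid-p correction).  Monomorphic sites return 1.
    """
    if n_AA < 0 or n_Aa < 0 or n_aa < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype must be observed")
    n_a = 2 * n_aa + n_Aa          # count of the 'a' allele
    n_A = 2 * n_AA + n_Aa
    n_minor = min(n_a, n_A)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) = log [ n! 2^h / (h! ((n_minor-h)/2)! ((n_major... )/2)!) ] - log C
    n_major = 2 * n - n_minor
    log_p = (hets * np.log(2.0)
             - gammaln(hets + 1)
             - gammaln((n_minor - hets) / 2 + 1)
             - gammaln((n_major - hets) / 2 + 1))
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    h_obs = n_Aa
    p_obs = probs[np.flatnonzero(hets == h_obs)[0]]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _diploid_genotype_counts(matrix: HaplotypeMatrix, rows: np.ndarray,
                             col: np.ndarray) -> Optional[tuple[int, int, int]]:
    """Pair haplotype rows of the same owner into diploid genotype counts.

    Returns None when the rows do not pair into diploids (hemizygous data),
    in which case no HWE test applies.
    """
    owners = matrix.haplotype_owner[rows]
    order = np.argsort(owners, kind="stable")
    rows = rows[order]
    owners = owners[order]
    if rows.size % 2 != 0:
        return None
    o1, o2 = owners[0::2], owners[1::2]
    if not np.all(o1 == o2):
        return None
    g = col[rows[0::2]].astype(np.int64) + col[rows[1::2]].astype(np.int64)
    return (int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))


def compute_site_stats(matrix: HaplotypeMatrix) -> pd.DataFrame:
    """Per-site statistics: frequencies, MAF and per-population HWE.

    ``hwe_p`` is the minimum exact-test p over populations (so a site fails
    an alpha threshold iff it fails in at least one population); hemizygous
    populations contribute no HWE test.
    """
    pops = matrix.populations()
    freq_all = matrix.derived_freq()
    out = pd.DataFrame({
        "site_id": matrix.site_ids,
        "chrom": matrix.chrom,
        "pos": matrix.positions,
        "derived_freq": freq_all,
    })
    for pop in pops:
        rows = matrix.rows_for_population(pop)
        out[f"derived_freq_{pop}"] = matrix.alleles[rows, :].mean(axis=0)
    out["maf"] = np.minimum(freq_all, 1.0 - freq_all)
    hwe = np.ones(matrix.n_sites)
    for pop in pops:
        rows = matrix.rows_for_population(pop)
        for j in range(matrix.n_sites):
            counts = _diploid_genotype_counts(matrix, rows, matrix.alleles[:, j])
            if counts is None:
                continue
            hwe[j] = min(hwe[j], hwe_exact_test(*counts))
    out["hwe_p"] = hwe
    out["pass_biallelic"] = True   # multiallelic records never reach the matrix
    out["pass_complete"] = True    # incomplete sites are dropped at load time
    return out


def site_filter(matrix: HaplotypeMatrix, site_stats: pd.DataFrame,
                config: ScanConfig, for_scan: bool = True) -> HaplotypeMatrix:
    """Apply HWE (and, for scan use, MAF) filters; preserves site order.

    ``for_scan=False`` keeps low-MAF sites (the differentiation stage uses
    all HWE-passing sites; the EHH scans additionally need MAF >= maf_min).
    """
    if len(site_stats) != matrix.n_sites:
        raise ValueError("site_stats does not match the matrix")
    mask = (site_stats["hwe_p"].to_numpy() >= config.hwe_alpha)
    mask &= site_stats["pass_biallelic"].to_numpy()
    mask &= site_stats["pass_complete"].to_numpy()
    if for_scan:
        mask &= site_stats["maf"].to_numpy() >= config.maf_min
    if not mask.any():
        raise ValueError("no sites survive filtering")
    return matrix.take_sites(mask)


def write_site_stats(site_stats: pd.DataFrame, path: str) -> None:
    site_stats.to_csv(path, sep="\t", index=False, float_format="%.6g")
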