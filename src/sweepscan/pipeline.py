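"""End-to-end orchestration: raw scans -> standardization -> candidates.

Glue used by the CLI and by validation studies.  The staged functions keep
raw and standardized scores separate so that scores from many chromosomes
(or many simulation replicates) can be pooled before standardization and
empirical ranking, mirroring genome-wide normalization.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .candidate_calling import call_candidates
from .datatypes import HaplotypeMatrix, ScanConfig
from .differentiation import fst_outliers, pairwise_fst_table
from .significance import attach_empirical_pvalues, standardize_scores
from .sweep_stats import ihs_scan, xpehh_scan

__all__ = ["raw_two_population_scan", "finalize_scans", "two_population_scan"]


def raw_two_population_scan(mat_test: HaplotypeMatrix,
                            mat_ref: HaplotypeMatrix,
                            config: Optional[ScanConfig] = None,
                            scan_ref_ihs: bool = True) -> dict:
    """Raw (unstandardized) iHS in each population, xp-EHH, and FST.

    Returns ``{"ihs": {pop: frame}, "xpehh": {(test, ref): frame},
    "fst": frame}``; FST records carry no outlier flags yet.
    ``scan_ref_ihs=False`` scans iHS only in the test population (the
    common design when one population is the designated scan target).
    """
    config = config or ScanConfig()
    pop_t = str(mat_test.population[0])
    pop_r = str(mat_ref.population[0])
    ihs = {pop_t: ihs_scan(mat_test, config)}
    if scan_ref_ihs:
        ihs[pop_r] = ihs_scan(mat_ref, config)
    xp = {(pop_t, pop_r): xpehh_scan(mat_test, mat_ref, config)}
    merged = HaplotypeMatrix(
        chrom=mat_test.chrom,
        positions=mat_test.positions,
        site_ids=mat_test.site_ids,
        alleles=np.vstack([mat_test.alleles, mat_ref.alleles]),
        haplotype_owner=np.concatenate([mat_test.haplotype_owner,
                                        mat_ref.haplotype_owner]),
        population=np.concatenate([mat_test.population, mat_ref.population]),
        genetic_pos=mat_test.genetic_pos,
        ancestral_known=mat_test.ancestral_known,
        ref_allele=mat_test.ref_allele,
        alt_allele=mat_test.alt_allele,
        ancestral_is_ref=mat_test.ancestral_is_ref,
    )
    fst = pairwise_fst_table(merged, pairs=[(pop_t, pop_r)])
    return {"ihs": ihs, "xpehh": xp, "fst": fst, "matrix": merged}


def finalize_scans(scans: Sequence[dict],
                   config: Optional[ScanConfig] = None) -> list[dict]:
    """Standardize and rank pooled raw scans from one or more replicates.

    Scores are standardized and empirically ranked against the pooled
    distribution over all replicates (the in-silico analogue of genome-wide
    normalization); FST outliers are ranked against the pooled per-pair
    background.  Returns one dict per input, with ``std``/``p_emp``/
    ``outlier`` columns filled and a ``candidates`` frame added.
    """
    config = config or ScanConfig()
    pops = list(scans[0]["ihs"].keys())
    pairs = list(scans[0]["xpehh"].keys())

    pooled_ihs = {p: pd.concat([s["ihs"][p] for s in scans],
                               ignore_index=True) for p in pops}
    std_ihs = {p: standardize_scores(pooled_ihs[p], "ihs", config.norm_bins)
               for p in pops}
    std_ihs = {p: attach_empirical_pvalues(df) for p, df in std_ihs.items()}
    pooled_xp = {pr: pd.concat([s["xpehh"][pr] for s in scans],
                               ignore_index=True) for pr in pairs}
    std_xp = {pr: attach_empirical_pvalues(
        standardize_scores(pooled_xp[pr], "xpehh")) for pr in pairs}
    pooled_fst = pd.concat([s["fst"] for s in scans], ignore_index=True)
    bg = pooled_fst["fst_hudson"].to_numpy()
    pooled_fst = fst_outliers(pooled_fst, bg, config.fst_outlier_alpha)

    # split the pooled frames back into replicates (order preserved)
    out = []
    offs_ihs = {p: 0 for p in pops}
    offs_xp = {pr: 0 for pr in pairs}
    off_fst = 0
    for s in scans:
        rep = {"ihs": {}, "xpehh": {}}
        for p in pops:
            n = len(s["ihs"][p])
            rep["ihs"][p] = std_ihs[p].iloc[offs_ihs[p]:offs_ihs[p] + n
                                            ].reset_index(drop=True)
            offs_ihs[p] += n
        for pr in pairs:
            n = len(s["xpehh"][pr])
            rep["xpehh"][pr] = std_xp[pr].iloc[offs_xp[pr]:offs_xp[pr] + n
                                               ].reset_index(drop=True)
            offs_xp[pr] += n
        n = len(s["fst"])
        rep["fst"] = pooled_fst.iloc[off_fst:off_fst + n].reset_index(drop=True)
        off_fst += n
        rep["candidates"] = call_candidates(
            rep["ihs"], rep["xpehh"], rep["fst"], config,
            matrix=s.get("matrix"))
        out.append(rep)
    return out


def two_population_scan(mat_test: HaplotypeMatrix, mat_ref: HaplotypeMatrix,
                        config: Optional[ScanConfig] = None) -> dict:
    """Full single-dataset pipeline (standardized within the dataset)."""
    raw = raw_two_population_scan(mat_test, mat_ref, config)
    return finalize_scans([raw], config)[0]
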