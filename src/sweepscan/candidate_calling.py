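"""Multi-evidence intersection producing the final candidate-SNP tables.

A site is a candidate for recent positive selection when three independent
lines of evidence agree: an extreme within-population iHS (|standardized
score| above threshold in some population P), a concordant cross-population
xp-EHH signal (|score| above threshold in a pair involving P, signed toward
P), and a pairwise-FST differentiation outlier.  The default "strict" mode
requires the xp-EHH pair to involve the iHS-significant population with the
sign pointing at it; a permissive mode accepts any extreme xp-EHH pair.

The beneficial (selected) allele is the allele whose extended haplotypes
drive the signal: the derived allele when the driving iHS is positive
(extended derived haplotypes under this package's sign convention), the
ancestral allele otherwise.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import HaplotypeMatrix, ScanConfig

__all__ = ["call_candidates", "export_tables", "read_candidates",
           "CANDIDATE_COLUMNS"]

CANDIDATE_COLUMNS = [
    "site_id", "pos", "gene", "beneficial_allele", "alternate_allele",
    "ihs_pop", "ihs_std", "xpehh_pair", "xpehh_std", "fst_pair", "fst",
    "ihs_sig", "xpehh_sig", "fst_sig", "candidate",
]


def _sig_ihs(ihs_scans: Mapping[str, pd.DataFrame], site_id,
             threshold: float) -> list[tuple[str, float]]:
    """(population, std) for every population where |iHS| exceeds threshold."""
    out = []
    for pop, df in ihs_scans.items():
        row = df[df["site_id"] == site_id]
        if row.empty:
            continue
        std = float(row["std"].iloc[0])
        if np.isfinite(std) and abs(std) > threshold:
            out.append((pop, std))
    return out


def _sig_xpehh(xpehh_scans: Mapping[tuple[str, str], pd.DataFrame], site_id,
               threshold: float, pops: Optional[set] = None,
               strict: bool = True) -> list[tuple[tuple[str, str], float]]:
    """Pairs with an extreme xp-EHH at the site.

    In strict mode the score's sign must point at one of ``pops``:
    positive scores indicate selection in the test (first) population,
    negative in the reference (second).
    """
    out = []
    for (test, ref), df in xpehh_scans.items():
        row = df[df["site_id"] == site_id]
        if row.empty:
            continue
        std = float(row["std"].iloc[0])
        if not (np.isfinite(std) and abs(std) > threshold):
            continue
        if strict:
            favoured = test if std > 0 else ref
            if pops is not None and favoured not in pops:
                continue
        out.append(((test, ref), std))
    return out


def call_candidates(
    ihs_scans: Mapping[str, pd.DataFrame],
    xpehh_scans: Mapping[tuple[str, str], pd.DataFrame],
    fst_records: pd.DataFrame,
    config: Optional[ScanConfig] = None,
    matrix: Optional[HaplotypeMatrix] = None,
    gene_map: Optional[Mapping] = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Intersect iHS, xp-EHH and FST evidence into candidate records.

    ``ihs_scans`` maps population -> standardized iHS frame; ``xpehh_scans``
    maps (test, ref) -> standardized xp-EHH frame; ``fst_records`` carries
    per-pair FST with ``outlier`` flags.  ``matrix`` (optional) supplies
    allele strings for the beneficial/alternate columns; ``gene_map``
    (optional) maps site_id -> gene/region label.  Sites appearing only in
    xp-EHH input are skipped with a warning.
    """
    import logging
    config = config or ScanConfig()
    logger = logging.getLogger(__name__)

    ihs_sites: list = []
    seen = set()
    for df in ihs_scans.values():
        for sid, pos in zip(df["site_id"], df["pos"]):
            if sid not in seen:
                seen.add(sid)
                ihs_sites.append((sid, int(pos)))
    for df in xpehh_scans.values():
        orphans = set(df["site_id"]) - seen
        if orphans:
            logger.warning("%d xp-EHH sites absent from iHS input; skipped",
                           len(orphans))

    allele_lookup = {}
    if matrix is not None and matrix.ref_allele is not None:
        derived = matrix.derived_allele_strings()
        ancestral = matrix.ancestral_allele_strings()
        for sid, d, a in zip(matrix.site_ids, derived, ancestral):
            allele_lookup[sid] = (d, a)

    records = []
    for sid, pos in ihs_sites:
        hits_ihs = _sig_ihs(ihs_scans, sid, config.ihs_threshold)
        ihs_sig = bool(hits_ihs)
        sig_pops = {p for p, _ in hits_ihs}
        hits_xp = _sig_xpehh(xpehh_scans, sid, config.xpehh_threshold,
                             pops=sig_pops if strict else None, strict=strict)
        xpehh_sig = bool(hits_xp)
        site_fst = fst_records[fst_records["site_id"] == sid]
        fst_hits = site_fst[site_fst["outlier"].astype(bool)]
        fst_sig = not fst_hits.empty
        candidate = ihs_sig and xpehh_sig and fst_sig

        if hits_ihs:
            pop, std = max(hits_ihs, key=lambda t: abs(t[1]))
        else:
            # best-scoring population, for reporting only
            pop, std = None, np.nan
            for p, df in ihs_scans.items():
                row = df[df["site_id"] == sid]
                if row.empty:
                    continue
                v = float(row["std"].iloc[0])
                if np.isfinite(v) and (not np.isfinite(std) or abs(v) > abs(std)):
                    pop, std = p, v
        ben, alt = "", ""
        if sid in allele_lookup:
            d, a = allele_lookup[sid]
            if np.isfinite(std) and std < 0:
                ben, alt = a, d   # extended ancestral haplotypes
            else:
                ben, alt = d, a
        if hits_xp:
            (xp_pair, xp_std) = max(hits_xp, key=lambda t: abs(t[1]))
            xp_pair_s = f"{xp_pair[0]}-{xp_pair[1]}"
        else:
            xp_pair_s, xp_std = "", np.nan
        if not fst_hits.empty:
            best = fst_hits.loc[fst_hits["fst_hudson"].idxmax()]
            fst_pair = f"{best['pop1']}-{best['pop2']}"
            fst_val = float(best["fst_hudson"])
        elif not site_fst.empty:
            best = site_fst.loc[site_fst["fst_hudson"].idxmax()]
            fst_pair = f"{best['pop1']}-{best['pop2']}"
            fst_val = float(best["fst_hudson"])
        else:
            fst_pair, fst_val = "", np.nan
        records.append({
            "site_id": sid, "pos": pos,
            "gene": (gene_map or {}).get(sid, ""),
            "beneficial_allele": ben, "alternate_allele": alt,
            "ihs_pop": pop if pop is not None else "",
            "ihs_std": std, "xpehh_pair": xp_pair_s, "xpehh_std": xp_std,
            "fst_pair": fst_pair, "fst": fst_val,
            "ihs_sig": ihs_sig, "xpehh_sig": xpehh_sig, "fst_sig": fst_sig,
            "candidate": candidate,
        })
    return pd.DataFrame.from_records(records, columns=CANDIDATE_COLUMNS)


def export_tables(candidates: pd.DataFrame, freq_table: pd.DataFrame,
                  candidates_path: str, frequencies_path: str,
                  candidates_only: bool = True) -> None:
    """Write the candidate and per-population frequency tables as TSV.

    FST is rendered with two decimals (clamped zeros appear as "0.00") and
    frequencies as three-decimal proportions, matching the conventional
    published layout.
    """
    df = candidates[candidates["candidate"]] if candidates_only else candidates
    df = df.copy()
    df["fst"] = df["fst"].map(lambda v: "" if not np.isfinite(v) else f"{v:.2f}")
    for col in ("ihs_std", "xpehh_std"):
        df[col] = df[col].map(lambda v: "" if not np.isfinite(v) else f"{v:.3f}")
    df.to_csv(candidates_path, sep="\t", index=False)
    ft = freq_table.copy()
    for col in ft.columns:
        if str(col).startswith("freq_"):
            ft[col] = ft[col].map(lambda v: f"{v:.3f}")
    ft.to_csv(frequencies_path, sep="\t", index=False)


def read_candidates(path: str) -> pd.DataFrame:
    """Re-parse an exported candidate TSV (inverse of :func:`export_tables`)."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    for col in ("ihs_sig", "xpehh_sig", "fst_sig", "candidate"):
        df[col] = df[col].astype(bool)
    return df
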