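"""EHH curves, integrated haplotype homozygosity, raw iHS and raw xp-EHH.

EHH at a marker x, for a set of "carrier" haplotypes sharing a core allele,
is the fraction of carrier pairs identical at every site from the core
through x.  Walking markers outward from the core, haplotypes split into
identity groups; EHH = sum_g C(n_g,2) / C(n,2), which is non-increasing by
construction.  iHH is the trapezoidal area under the EHH decay curve versus
map distance, summed over both directions and truncated where EHH falls
below a cutoff; spans over large physical gaps are down-weighted, and sites
spanning assembly-scale gaps are discarded.

raw iHS = ln(iHH_derived / iHH_ancestral).  Sign convention: positive means
unusually extended *derived* haplotypes.  (The classic literature statistic
is oriented the other way; only |iHS| enters the significance thresholds.)

raw xp-EHH = ln(iHH_test / iHH_ref), with both populations integrated over
the same marker span — the span where the *pooled* two-population EHH decays
to the cutoff — so that swapping test and reference exactly negates the
score.  Positive values mean longer haplotypes (stronger recent selection)
in the test population.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import EhhCurve, HaplotypeMatrix, ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ehh_curve",
    "integrate_ihh",
    "ihs_scan",
    "xpehh_scan",
    "IHS_COLUMNS",
    "XPEHH_COLUMNS",
]

IHS_COLUMNS = ["site_id", "pos", "freq_derived", "ihh_d", "ihh_a",
               "raw", "std", "p_emp", "status"]
XPEHH_COLUMNS = ["site_id", "pos", "freq_derived", "ihh_test", "ihh_ref",
                 "raw", "std", "p_emp", "status"]


def _group_sizes_to_ehh(labels: np.ndarray, n: int) -> float:
    """Homozygosity of a partition: sum C(n_g,2) / C(n,2)."""
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _refine(labels: np.ndarray, n_groups: int, col: np.ndarray,
            n: int) -> tuple[np.ndarray, int, float]:
    """Split identity groups by one more marker; return (labels, k, ehh).

    Equivalent to relabelling ``labels*2 + col`` densely, without the sort
    ``np.unique`` would do.
    """
    key = labels * 2 + col
    counts = np.bincount(key, minlength=2 * n_groups)
    ehh = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    remap = np.cumsum(counts > 0) - 1
    return remap[key], int(remap[-1]) + 1, ehh


def _carriersT(alleles: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Carrier submatrix in (n_sites, n_carriers) layout for fast walking."""
    return np.ascontiguousarray(alleles[rows].T.astype(np.int64))


def _walk(sub: np.ndarray, core: int, step: int,
          mpos: np.ndarray, bpos: np.ndarray, config: ScanConfig,
          stop_index: Optional[int] = None,
          stop_at_cutoff: bool = True) -> EhhCurve:
    """Extend an EHH curve from ``core`` in direction ``step`` (+1/-1).

    ``sub`` is the carrier submatrix from :func:`_carriersT`.  Identity
    groups start unified and are split only by the markers walked over:
    for carrier-conditioned curves (iHS) the carriers already share the
    core allele, and for unconditional curves (xp-EHH) the homozygosity
    decay of the *flanking* haplotypes is what is compared between
    populations — the core's own alleles never split the groups, matching
    the convention of the standard scan software.  ``stop_index`` freezes
    the span (used to integrate both populations of an xp-EHH pair over
    the same markers).
    """
    n_sites, n = sub.shape
    direction = "downstream" if step > 0 else "upstream"
    if n < 2:
        return EhhCurve(None, direction, [0.0], [1.0], [bpos[core]], "uncomputable")
    labels = np.zeros(n, dtype=np.int64)
    n_groups = 1
    dists = [0.0]
    ehhs = [1.0]
    bps = [int(bpos[core])]
    status = "edge_reached"
    j = core + step
    last_bp = int(bpos[core])
    while 0 <= j < n_sites:
        gap = abs(int(bpos[j]) - last_bp)
        if gap > config.max_gap_bp:
            status = "gap_discarded"
            break
        labels, n_groups, e = _refine(labels, n_groups, sub[j], n)
        dists.append(abs(float(mpos[j]) - float(mpos[core])))
        ehhs.append(e)
        bps.append(int(bpos[j]))
        last_bp = int(bpos[j])
        if stop_index is not None and j == stop_index:
            status = "span_end"
            break
        if stop_at_cutoff and e < config.ehh_cutoff:
            status = "cutoff_reached"
            break
        j += step
    return EhhCurve(None, direction, dists, ehhs, bps, status)


def ehh_curve(matrix: HaplotypeMatrix, core_site, carrier_rows: Sequence[int],
              direction: str, config: Optional[ScanConfig] = None) -> EhhCurve:
    """EHH decay curve for one core site and carrier set.

    ``core_site`` is a site id or integer column index; ``direction`` is
    ``"upstream"`` (decreasing position) or ``"downstream"``.
    """
    config = config or ScanConfig()
    if isinstance(core_site, (int, np.integer)):
        core = int(core_site)
    else:
        hits = np.flatnonzero(matrix.site_ids == core_site)
        if hits.size == 0:
            raise KeyError(f"unknown site {core_site!r}")
        core = int(hits[0])
    step = -1 if direction == "upstream" else 1
    rows = np.asarray(carrier_rows, dtype=np.int64)
    if rows.size < 2:
        return EhhCurve(matrix.site_ids[core], direction, [0.0], [1.0],
                        [matrix.positions[core]], "uncomputable")
    curve = _walk(_carriersT(matrix.alleles, rows), core, step,
                  matrix.map_positions(), matrix.positions, config)
    curve.core_site = matrix.site_ids[core]
    return curve


def integrate_ihh(curve_up: EhhCurve, curve_down: EhhCurve,
                  config: Optional[ScanConfig] = None) -> tuple[float, str]:
    """Trapezoidal iHH over both directions, with gap down-weighting.

    Returns ``(ihh, status)`` where status is ``ok``, ``truncated`` (a
    curve hit the chromosome edge before decaying to the cutoff),
    ``gap_discarded`` or ``uncomputable``.  The terminal trapezoid — the
    one ending at the first point with EHH <= cutoff — is included; a span
    with bp gap g > gap_scale_bp contributes its area scaled by
    gap_scale_bp / g.
    """
    config = config or ScanConfig()
    total = 0.0
    status = "ok"
    for curve in (curve_up, curve_down):
        if curve.status == "uncomputable":
            return 0.0, "uncomputable"
        if curve.status == "gap_discarded":
            return 0.0, "gap_discarded"
        if curve.status == "edge_reached":
            status = "truncated"
        d, e, bp = curve.distances, curve.ehh, curve.bp_positions
        for i in range(1, len(d)):
            area = 0.5 * (e[i - 1] + e[i]) * (d[i] - d[i - 1])
            g = abs(int(bp[i]) - int(bp[i - 1]))
            if g > config.gap_scale_bp:
                area *= config.gap_scale_bp / g
            total += area
    return total, status


def _site_ihh(matrix: HaplotypeMatrix, core: int, rows: np.ndarray,
              config: ScanConfig) -> tuple[float, str]:
    mpos = matrix.map_positions()
    sub = _carriersT(matrix.alleles, rows)
    up = _walk(sub, core, -1, mpos, matrix.positions, config)
    down = _walk(sub, core, +1, mpos, matrix.positions, config)
    return integrate_ihh(up, down, config)


def ihs_scan(matrix: HaplotypeMatrix,
             config: Optional[ScanConfig] = None) -> pd.DataFrame:
    """Raw iHS per site: ln(iHH over derived carriers / iHH over ancestral).

    Sites are skipped (with a status flag, no score) when MAF < maf_min,
    either allele has < 2 carriers, a curve spans a gap > max_gap_bp, or —
    unless ``config.trunc_ok`` — a curve reaches the chromosome edge before
    decaying below the EHH cutoff.
    """
    config = config or ScanConfig()
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    freqs = matrix.derived_freq()
    rows_all = np.arange(matrix.n_haplotypes)
    records = []
    for j in range(matrix.n_sites):
        f = float(freqs[j])
        rec = {"site_id": matrix.site_ids[j], "pos": int(matrix.positions[j]),
               "freq_derived": f, "ihh_d": np.nan, "ihh_a": np.nan,
               "raw": np.nan, "std": np.nan, "p_emp": np.nan}
        if min(f, 1 - f) < config.maf_min:
            rec["status"] = "maf"
            records.append(rec)
            continue
        col = matrix.alleles[:, j]
        rows_d = rows_all[col == 1]
        rows_a = rows_all[col == 0]
        if rows_d.size < 2 or rows_a.size < 2:
            rec["status"] = "too_few_carriers"
            records.append(rec)
            continue
        ihh_d, st_d = _site_ihh(matrix, j, rows_d, config)
        ihh_a, st_a = _site_ihh(matrix, j, rows_a, config)
        status = "ok"
        for st in (st_d, st_a):
            if st == "gap_discarded":
                status = "gap_discarded"
            elif st == "uncomputable" and status == "ok":
                status = "uncomputable"
            elif st == "truncated" and status == "ok":
                status = "truncated"
        if status == "truncated" and config.trunc_ok:
            status = "ok"
        rec["ihh_d"], rec["ihh_a"] = ihh_d, ihh_a
        if status == "ok" and ihh_d > 0 and ihh_a > 0:
            rec["raw"] = float(np.log(ihh_d / ihh_a))
            rec["status"] = "ok"
        else:
            rec["status"] = status if status != "ok" else "zero_ihh"
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=IHS_COLUMNS)


def _shared_site_index(a: HaplotypeMatrix, b: HaplotypeMatrix
                       ) -> tuple[np.ndarray, np.ndarray]:
    if a.chrom != b.chrom:
        raise ValueError("cross-population scan requires matching chromosomes")
    common, ia, ib = np.intersect1d(a.positions, b.positions,
                                    return_indices=True)
    return ia, ib


def xpehh_scan(matrix_test: HaplotypeMatrix, matrix_ref: HaplotypeMatrix,
               config: Optional[ScanConfig] = None) -> pd.DataFrame:
    """Raw xp-EHH per shared site: ln(iHH_test / iHH_ref).

    Sites are matched between the populations by chrom+position.  At each
    core site the unconditional EHH of the pooled sample fixes the
    integration span (where pooled EHH decays below the cutoff); each
    population's unconditional EHH is then integrated over exactly that
    span, making the statistic antisymmetric under population swap.
    """
    config = config or ScanConfig()
    ia, ib = _shared_site_index(matrix_test, matrix_ref)
    if ia.size == 0:
        raise ValueError("no shared sites between populations")
    sub_t = matrix_test.take_sites(ia)
    sub_r = matrix_ref.take_sites(ib)
    pooled_alleles = np.vstack([sub_t.alleles, sub_r.alleles])
    mpos = sub_t.map_positions()
    bpos = sub_t.positions
    pooledT = _carriersT(pooled_alleles, np.arange(pooled_alleles.shape[0]))
    testT = _carriersT(sub_t.alleles, np.arange(sub_t.n_haplotypes))
    refT = _carriersT(sub_r.alleles, np.arange(sub_r.n_haplotypes))
    records = []
    for j in range(sub_t.n_sites):
        f_test = float(sub_t.alleles[:, j].mean())
        rec = {"site_id": sub_t.site_ids[j], "pos": int(bpos[j]),
               "freq_derived": f_test, "ihh_test": np.nan, "ihh_ref": np.nan,
               "raw": np.nan, "std": np.nan, "p_emp": np.nan}
        if sub_t.n_haplotypes < 2 or sub_r.n_haplotypes < 2:
            rec["status"] = "too_few_haplotypes"
            records.append(rec)
            continue
        pooled_f = float(pooled_alleles[:, j].mean())
        if min(pooled_f, 1 - pooled_f) < config.maf_min:
            rec["status"] = "maf"
            records.append(rec)
            continue
        # pooled curve fixes the span in each direction
        up_p = _walk(pooledT, j, -1, mpos, bpos, config)
        down_p = _walk(pooledT, j, +1, mpos, bpos, config)
        status = "ok"
        for c in (up_p, down_p):
            if c.status == "gap_discarded":
                status = "gap_discarded"
            elif c.status == "edge_reached" and status == "ok":
                status = "truncated"
        if status == "truncated" and config.trunc_ok:
            status = "ok"
        if status != "ok":
            rec["status"] = status
            records.append(rec)
            continue
        stop_up = j - (len(up_p.distances) - 1)
        stop_down = j + (len(down_p.distances) - 1)
        ihh = {}
        for key, sub in (("test", testT), ("ref", refT)):
            up = _walk(sub, j, -1, mpos, bpos, config,
                       stop_index=stop_up, stop_at_cutoff=False)
            down = _walk(sub, j, +1, mpos, bpos, config,
                         stop_index=stop_down, stop_at_cutoff=False)
            ihh[key], _ = integrate_ihh(up, down, config)
        rec["ihh_test"], rec["ihh_ref"] = ihh["test"], ihh["ref"]
        if ihh["test"] > 0 and ihh["ref"] > 0:
            rec["raw"] = float(np.log(ihh["test"] / ihh["ref"]))
            rec["status"] = "ok"
        else:
            rec["status"] = "zero_ihh"
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=XPEHH_COLUMNS)
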