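"""Per-SNP population differentiation: allele frequencies and pairwise FST.

Two per-site two-population estimators are provided.  The Hudson estimator
is a pure function of the two derived-allele frequencies and haplotype
counts,

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1),

so it can be evaluated directly from published frequency tables.  The
Weir-Cockerham variance-components estimator a/(a+b+c) is computed from
genotype counts (with observed heterozygosity), or from haplotype counts
via the haploid reduction a/(a+b).  Negative estimates are clamped to zero,
the convention used when reporting per-SNP FST tables.  Outlier calling is
a one-sided (high-tail) empirical rank against a genome- or
simulation-wide background distribution for the same population pair.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import HaplotypeMatrix, ScanConfig

__all__ = [
    "pop_allele_freqs",
    "hudson_fst",
    "hudson_fst_multilocus",
    "wc_fst",
    "wc_fst_haploid",
    "fst_outliers",
    "pairwise_fst_table",
    "FST_COLUMNS",
]

FST_COLUMNS = ["site_id", "pos", "pop1", "pop2", "p1", "p2", "n1", "n2",
               "fst_hudson", "fst_wc", "clamped", "p_emp", "outlier"]


def pop_allele_freqs(matrix: HaplotypeMatrix) -> pd.DataFrame:
    """Derived-allele frequency and haplotype count per population per site."""
    pops = matrix.populations()
    if not pops:
        raise ValueError("matrix has no population labels")
    out = pd.DataFrame({"site_id": matrix.site_ids, "pos": matrix.positions})
    for pop in pops:
        rows = matrix.rows_for_population(pop)
        if rows.size == 0:
            raise ValueError(f"population {pop!r} has zero haplotypes")
        out[f"freq_{pop}"] = matrix.alleles[rows, :].mean(axis=0)
        out[f"n_{pop}"] = rows.size
    return out


def hudson_fst(p1, n1, p2, n2):
    """Hudson two-population FST from allele frequencies; clamped to [0,1].

    Accepts scalars or arrays.  Both populations monomorphic for the same
    allele (denominator 0) give 0.  Symmetric in the two populations.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0,1]")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("haplotype counts must be >= 2")
    # corrections grouped so the estimator is exactly symmetric in floats
    num = (p1 - p2) ** 2 - (p1 * (1 - p1) / (n1 - 1)
                            + p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(fst, 0.0, 1.0) if fst.ndim else float(np.clip(fst, 0.0, 1.0))


def hudson_fst_multilocus(p1, n1, p2, n2) -> float:
    """Multi-locus Hudson FST: sum of numerators over sum of denominators.

    The standard way to combine Hudson per-site components across loci.
    Unlike the mean of per-site ratios (which rare variants with tiny
    denominators pull toward zero), the ratio of sums is unbiased for the
    drift expectation 1 - (1 - 1/2N)^T under a clean split.  Not clamped.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = (p1 - p2) ** 2 - (p1 * (1 - p1) / (n1 - 1)
                            + p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total = den.sum()
    if total <= 0:
        raise ValueError("no polymorphic loci to combine")
    return float(num.sum() / total)


def wc_fst(genotype_counts: Sequence[tuple[int, int, int]]) -> float:
    """Weir-Cockerham per-site FST from diploid genotype counts.

    ``genotype_counts`` is one ``(n_AA, n_Aa, n_aa)`` triple per population
    (A = ancestral, a = derived; the estimator is label-symmetric).  Returns
    a/(a+b+c) clamped to [0,1]; identical populations give 0 after clamping.
    """
    counts = [tuple(int(x) for x in c) for c in genotype_counts]
    r = len(counts)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([sum(c) for c in counts], dtype=float)
    if np.any(n_i < 1):
        raise ValueError("each population needs at least one individual")
    p_i = np.array([(2 * c[2] + c[1]) / (2 * n) for c, n in zip(counts, n_i)])
    h_i = np.array([c[1] / n for c, n in zip(counts, n_i)])  # obs het freq
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    if n_bar <= 1 or n_c == 0:
        return 0.0
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                               - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    denom = a + b + c
    if denom == 0:
        return 0.0
    return float(np.clip(a / denom, 0.0, 1.0))


def wc_fst_haploid(p: Sequence[float], n: Sequence[int]) -> float:
    """Haploid Weir-Cockerham reduction a/(a+b) from haplotype frequencies.

    Used when FST is computed directly on phased haplotype counts (no
    heterozygosity term); clamped to [0,1].
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    r = p.size
    if r < 2:
        raise ValueError("need at least two populations")
    if np.any(n < 2):
        raise ValueError("haplotype counts must be >= 2")
    n_bar = n.mean()
    n_c = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2)
                         / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    denom = a + b
    if denom == 0:
        return 0.0
    return float(np.clip(a / denom, 0.0, 1.0))


def fst_outliers(records: pd.DataFrame, background: np.ndarray,
                 alpha: float = 0.05) -> pd.DataFrame:
    """One-sided (high-tail) empirical p and outlier flag per FST record.

    p(f) = #{x >= f} / N over the background distribution of per-site FST
    for the same population pair; outlier iff p < alpha.
    """
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    if bg.size == 0:
        raise ValueError("empty background FST distribution")
    bg.sort()
    out = records.copy()
    f = out["fst_hudson"].to_numpy(dtype=float)
    below = np.searchsorted(bg, f, side="left")
    p = (bg.size - below) / bg.size
    out["p_emp"] = p
    out["outlier"] = p < alpha
    return out


def pairwise_fst_table(matrix: HaplotypeMatrix,
                       pairs: Optional[Sequence[tuple[str, str]]] = None,
                       sites: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-site Hudson + Weir-Cockerham FST for population pairs.

    ``pairs`` defaults to all unordered population pairs in the matrix;
    ``sites`` optionally restricts to a set of site ids.  The W&C column is
    computed from diploid genotypes where haplotypes pair into individuals,
    falling back to the haploid reduction otherwise.  ``p_emp``/``outlier``
    are left unset (use :func:`fst_outliers` with a background).
    """
    from .haplotype_io import _diploid_genotype_counts

    pops = matrix.populations()
    if pairs is None:
        pairs = list(combinations(pops, 2))
    if sites is not None:
        wanted = set(sites)
        idx = np.flatnonzero([sid in wanted for sid in matrix.site_ids])
        unknown = wanted - set(matrix.site_ids[idx])
        if unknown:
            raise KeyError(f"unknown site ids: {sorted(map(str, unknown))}")
    else:
        idx = np.arange(matrix.n_sites)
    rows_by_pop = {p: matrix.rows_for_population(p) for p in pops}
    records = []
    for pop1, pop2 in pairs:
        r1, r2 = rows_by_pop[pop1], rows_by_pop[pop2]
        n1, n2 = r1.size, r2.size
        for j in idx:
            col = matrix.alleles[:, j]
            p1 = float(col[r1].mean())
            p2 = float(col[r2].mean())
            fh = hudson_fst(p1, n1, p2, n2)
            g1 = _diploid_genotype_counts(matrix, r1, col)
            g2 = _diploid_genotype_counts(matrix, r2, col)
            if g1 is not None and g2 is not None:
                fw = wc_fst([g1, g2])
            else:
                fw = wc_fst_haploid([p1, p2], [n1, n2])
            raw_num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                       - p2 * (1 - p2) / (n2 - 1))
            records.append({
                "site_id": matrix.site_ids[j], "pos": int(matrix.positions[j]),
                "pop1": pop1, "pop2": pop2, "p1": p1, "p2": p2,
                "n1": n1, "n2": n2, "fst_hudson": fh, "fst_wc": fw,
                "clamped": raw_num < 0, "p_emp": np.nan, "outlier": False,
            })
    return pd.DataFrame.from_records(records, columns=FST_COLUMNS)
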