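"""Score standardization, empirical p-values and window-based region calls.

Raw iHS depends systematically on derived-allele frequency, so scores are
z-standardized within equal-width derived-frequency bins (100 bins over
[0,1] by default, matching the usual genome-wide normalization); xp-EHH is
standardized in a single bin.  The bin moments use the population
denominator n.  Empirical p-values are two-sided ranks of |score| against
the full standardized distribution, because the significance thresholds
(|iHS| > 2.75, |xp-EHH| > 2.806, both empirical p < 0.01) are symmetric.

Region detection tiles each chromosome with non-overlapping 100 kb windows
anchored at coordinate 0 and flags windows containing at least 20 scored
SNPs with |iHS| above the threshold.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ScanConfig

__all__ = [
    "standardize_scores",
    "empirical_pvalues",
    "attach_empirical_pvalues",
    "detect_windows",
    "write_windows_bed",
]


def standardize_scores(records: pd.DataFrame, mode: str = "ihs",
                       norm_bins: int = 100) -> pd.DataFrame:
    """Fill the ``std`` column by within-bin z-scoring of ``raw``.

    ``mode="ihs"`` bins records by derived frequency into ``norm_bins``
    equal-width bins on [0,1]; ``mode="xpehh"`` uses one bin.  Bins with
    fewer than two scores or zero spread leave their records unscored with
    status ``unstd_bin``.  Returns a copy with ``std`` and ``bin`` columns
    filled; the input must contain at least one scorable record.
    """
    if mode not in ("ihs", "xpehh"):
        raise ValueError("mode must be 'ihs' or 'xpehh'")
    out = records.copy()
    raw = out["raw"].to_numpy(dtype=float)
    scorable = (out["status"] == "ok").to_numpy() & np.isfinite(raw)
    if not scorable.any():
        raise ValueError("no scorable records to standardize")
    if mode == "ihs":
        freq = out["freq_derived"].to_numpy(dtype=float)
        bins = np.clip((freq * norm_bins).astype(int), 0, norm_bins - 1)
    else:
        bins = np.zeros(len(out), dtype=int)
    out["bin"] = bins
    std = np.full(len(out), np.nan)
    status = out["status"].to_numpy(dtype=object)
    for b in np.unique(bins[scorable]):
        sel = scorable & (bins == b)
        vals = raw[sel]
        if sel.sum() < 2:
            status[sel] = "unstd_bin"
            continue
        mean = vals.mean()
        sd = vals.std(ddof=0)  # population denominator, as in genome-wide norm
        if sd == 0:
            status[sel] = "unstd_bin"
            continue
        std[sel] = (vals - mean) / sd
    out["std"] = std
    out["status"] = status
    return out


def empirical_pvalues(all_scores: np.ndarray, query_scores: np.ndarray
                      ) -> np.ndarray:
    """Two-sided empirical rank p: #{|x| >= |q|} / N over the reference set.

    The minimum attainable p is 1/N (a query at the reference maximum);
    a query of 0 has p = 1.
    """
    ref = np.abs(np.asarray(all_scores, dtype=float))
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("empty reference score distribution")
    ref.sort()
    q = np.abs(np.asarray(query_scores, dtype=float))
    # count of ref strictly below |q|, so N - that = #{ref >= |q|}
    below = np.searchsorted(ref, q, side="left")
    p = (ref.size - below) / ref.size
    return np.where(np.isfinite(q), p, np.nan)


def attach_empirical_pvalues(records: pd.DataFrame,
                             reference: Optional[pd.DataFrame] = None
                             ) -> pd.DataFrame:
    """Fill ``p_emp`` from the standardized scores of ``reference``.

    ``reference`` defaults to the records themselves (genome-wide scan);
    pass a pooled multi-chromosome frame to rank against the whole genome.
    """
    ref = records if reference is None else reference
    ref_scores = ref["std"].to_numpy(dtype=float)
    ref_scores = ref_scores[np.isfinite(ref_scores)]
    out = records.copy()
    q = out["std"].to_numpy(dtype=float)
    p = np.full(len(out), np.nan)
    finite = np.isfinite(q)
    if finite.any():
        p[finite] = empirical_pvalues(ref_scores, q[finite])
    out["p_emp"] = p
    return out


def detect_windows(records: pd.DataFrame,
                   config: Optional[ScanConfig] = None,
                   chrom: Optional[str] = None) -> pd.DataFrame:
    """Flag non-overlapping windows dense in extreme standardized iHS.

    Windows of ``window_size_bp`` tile the chromosome from coordinate 0; a
    window is flagged iff it holds >= ``window_min_hits`` records with
    |std| > ``ihs_threshold``.  Windows with no scored site are omitted.
    Output columns: chrom, start, end (0-based half-open), n_scored,
    n_hits, flagged.
    """
    config = config or ScanConfig()
    cols = ["chrom", "start", "end", "n_scored", "n_hits", "flagged"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    df = records
    if "chrom" not in df.columns:
        df = df.assign(chrom=chrom if chrom is not None else ".")
    rows = []
    for ch, grp in df.groupby("chrom", sort=False):
        std = grp["std"].to_numpy(dtype=float)
        scored = np.isfinite(std)
        if not scored.any():
            continue
        pos = grp["pos"].to_numpy(dtype=np.int64)[scored]
        hit = np.abs(std[scored]) > config.ihs_threshold
        widx = pos // config.window_size_bp
        for w in np.unique(widx):
            sel = widx == w
            n_scored = int(sel.sum())
            n_hits = int(hit[sel].sum())
            rows.append({
                "chrom": ch,
                "start": int(w) * config.window_size_bp,
                "end": (int(w) + 1) * config.window_size_bp,
                "n_scored": n_scored,
                "n_hits": n_hits,
                "flagged": n_hits >= config.window_min_hits,
            })
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], ignore_index=True)


def write_windows_bed(windows: pd.DataFrame, path: str,
                      flagged_only: bool = True) -> None:
    """Write (flagged) windows as BED: chrom, start, end, n_hits."""
    df = windows[windows["flagged"]] if flagged_only else windows
    df[["chrom", "start", "end", "n_hits"]].to_csv(
        path, sep="\t", header=False, index=False)
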