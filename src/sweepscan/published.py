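"""Published study inputs shipped with the package.

The candidate table pairs each SNP reported under positive selection in
the aggression-gene study with its beneficial/alternate alleles, the
reporting population, and the derived-beneficial-allele frequency per
1000 Genomes superpopulation.  Haplotype counts are twice the diploid
sample sizes of the superpopulation panels (AFR 311, EUR 297, SAS 284,
EAS 306 individuals).  These frequencies and counts are *inputs*: pairwise
FST between superpopulations is recomputed from them with the Hudson
estimator, never copied.

The gene list covers the nine aggression query genes and the genes the
scan flagged; the study's additional 74 protein-interaction partners are
not reproduced here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["HAPLOTYPE_COUNTS", "candidate_table", "query_genes"]

# chromosomes sampled per superpopulation (2 x diploid panel size)
HAPLOTYPE_COUNTS = {"AFR": 622, "EUR": 594, "SAS": 568, "EAS": 612}


def _read(name: str) -> pd.DataFrame:
    with resources.files("sweepscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def candidate_table() -> pd.DataFrame:
    """Candidate SNPs with per-superpopulation beneficial-allele frequencies."""
    return _read("aggression_candidates.tsv")


def query_genes() -> pd.DataFrame:
    """Aggression query genes and the genes flagged by the scan."""
    return _read("query_genes.tsv")
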