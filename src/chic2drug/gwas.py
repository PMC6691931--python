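"""Comparison of CHi-C candidate genes with the reported GWAS gene labels.

Each SNP association is placed in one category:

- ``no_chic_genes`` — the filter identified no genes at all;
- ``0``   — genes were identified but the reported gene is not among them;
- ``1``   — the reported gene is the only gene identified;
- ``2-5`` — the reported gene is among 2-5 identified genes;
- ``6+``  — the reported gene is among 6 or more identified genes.

A locus reported with several gene names counts as recovered if any of them
is among the candidates. Loci without a reported gene are categorised with
the comparison marked not applicable and excluded from category counts.
"""
from __future__ import annotations

from collections import Counter

import pandas as pd

from .model import LocusCategory, normalize_symbol

ALL = "all"


def categorize_locus(
    index_snp_id: str,
    disease: str,
    candidates: set[str],
    reported_genes: tuple[str, ...],
) -> LocusCategory:
    candidates = {normalize_symbol(g) for g in candidates}
    reported = tuple(normalize_symbol(g) for g in reported_genes if g.strip())
    n = len(candidates)
    if not reported:
        return LocusCategory(index_snp_id, disease, reported, n, None)
    if n == 0:
        category = LocusCategory.NO_CHIC
    elif not candidates & set(reported):
        category = "0"
    elif n == 1:
        category = "1"
    elif n <= 5:
        category = "2-5"
    else:
        category = "6+"
    return LocusCategory(index_snp_id, disease, reported, n, category)


def categorize_loci(
    loci_candidates: dict[tuple[str, str], set[str]],
    reported: dict[tuple[str, str], tuple[str, ...]],
) -> list[LocusCategory]:
    """Categorise every locus that has a reported-gene entry; loci with
    candidates but no reported entry get a not-applicable category."""
    keys = sorted(set(loci_candidates) | set(reported))
    return [
        categorize_locus(
            snp, disease, loci_candidates.get((snp, disease), set()),
            reported.get((snp, disease), ()),
        )
        for snp, disease in keys
    ]


def summarize_categories(loci: list[LocusCategory]) -> pd.DataFrame:
    """Category counts per disease plus an overall row.

    Not-applicable loci are excluded. Counts per disease sum to the number
    of categorisable loci for that disease.
    """
    counts: dict[str, Counter] = {}
    for locus in loci:
        if locus.category is None:
            continue
        counts.setdefault(locus.disease, Counter())[locus.category] += 1
    rows = []
    overall = Counter()
    for disease in sorted(counts):
        overall.update(counts[disease])
    for disease, counter in [*sorted(counts.items()), (ALL, overall)]:
        row = {"disease": disease}
        row.update({cat: counter.get(cat, 0) for cat in LocusCategory.CATEGORIES})
        row["n_loci"] = sum(counter.values())
        rows.append(row)
    return pd.DataFrame(rows, columns=["disease", *LocusCategory.CATEGORIES, "n_loci"])
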