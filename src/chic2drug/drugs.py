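"""Drug-target identification and the current-use vs repositioning split.

Candidate genes are joined to a DrugBank-like drug-target table. A drug is
"currently used" for a disease when one of the disease's name variants
matches the drug's free-text indication field; every other identified drug
is a repositioning candidate. Matching is case-insensitive substring by
default; a token-subset mode additionally tolerates word insertions and
reordering ("juvenile arthritis" matching "juvenile idiopathic arthritis").
"""
from __future__ import annotations

import re
from collections import defaultdict

import pandas as pd

from .model import DiseaseTermSet, DrugCall, DrugTargetRecord, normalize_symbol

MATCH_MODES = ("substring", "token_subset")


def map_drug_targets(
    candidates_by_disease: dict[str, set[str]],
    drug_table: list[DrugTargetRecord],
    groups: set[str] | None = None,
) -> dict[str, list[DrugCall]]:
    """For each disease, the drugs whose targets intersect its candidate
    genes, each drug once with the full set of candidate genes it hits.
    ``groups`` optionally restricts to drugs with a given approval status
    (e.g. {"approved"})."""
    by_drug: dict[str, list[DrugTargetRecord]] = defaultdict(list)
    for rec in drug_table:
        if groups is not None and not (rec.groups & groups):
            continue
        by_drug[rec.drug_id].append(rec)
    out: dict[str, list[DrugCall]] = {}
    for disease, genes in sorted(candidates_by_disease.items()):
        genes = {normalize_symbol(g) for g in genes}
        calls = []
        for drug_id in sorted(by_drug):
            records = by_drug[drug_id]
            hit = {r.gene_id for r in records} & genes
            if hit:
                calls.append(DrugCall(drug_id, records[0].drug_name, disease, hit))
        out[disease] = calls
    return out


def _tokens(text: str) -> set[str]:
    return set(re.findall(r"[a-z0-9]+", text.lower()))


def term_matches(term: str, indication: str, mode: str = "substring") -> bool:
    if mode == "substring":
        return term.lower() in indication.lower()
    if mode == "token_subset":
        term_tokens = _tokens(term)
        return bool(term_tokens) and term_tokens <= _tokens(indication)
    raise ValueError(f"unknown match mode {mode!r}; expected one of {MATCH_MODES}")


def classify_current_use(
    drug_calls: dict[str, list[DrugCall]],
    disease_terms: list[DiseaseTermSet],
    drug_table: list[DrugTargetRecord],
    mode: str = "substring",
) -> dict[str, list[DrugCall]]:
    """Set ``currently_used`` on every drug call by matching the disease's
    name variants against the drug's indication text."""
    terms_by_disease = {ts.disease: ts.terms for ts in disease_terms}
    indication_by_drug: dict[str, str] = {}
    for rec in drug_table:
        # indication is a drug-level field; rows of one drug agree or the
        # longest text wins
        prev = indication_by_drug.get(rec.drug_id, "")
        if len(rec.indication_text) > len(prev):
            indication_by_drug[rec.drug_id] = rec.indication_text
    for disease, calls in drug_calls.items():
        terms = terms_by_disease.get(disease, ())
        for call in calls:
            indication = indication_by_drug.get(call.drug_id, "")
            call.matched_term = next(
                (t for t in terms if term_matches(t, indication, mode)), None
            )
            call.currently_used = call.matched_term is not None
    return drug_calls


def summarize_targets(
    drug_calls: dict[str, list[DrugCall]],
    candidates_by_disease: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-disease and overall counts: candidate genes, genes that are drug
    targets, drugs, currently-used drugs and repositionable drugs. The
    identity n_drugs = n_current + n_repositionable holds by construction."""
    rows = []
    diseases = sorted(set(candidates_by_disease) | set(drug_calls))
    all_genes: set[str] = set()
    all_targets: set[str] = set()
    all_drugs: set[str] = set()
    all_current: set[str] = set()
    for disease in diseases:
        genes = candidates_by_disease.get(disease, set())
        calls = drug_calls.get(disease, [])
        target_genes = set().union(*(c.target_genes for c in calls)) if calls else set()
        current = {c.drug_id for c in calls if c.currently_used}
        drugs = {c.drug_id for c in calls}
        rows.append(
            {
                "disease": disease,
                "n_genes": len(genes),
                "n_target_genes": len(target_genes),
                "n_drugs": len(drugs),
                "n_current": len(current),
                "n_repositionable": len(drugs - current),
            }
        )
        all_genes |= genes
        all_targets |= target_genes
        all_drugs |= drugs
        all_current |= current
    rows.append(
        {
            "disease": "all",
            "n_genes": len(all_genes),
            "n_target_genes": len(all_targets),
            "n_drugs": len(all_drugs),
            "n_current": len(all_current),
            "n_repositionable": len(all_drugs - all_current),
        }
    )
    return pd.DataFrame(
        rows,
        columns=["disease", "n_genes", "n_target_genes", "n_drugs",
                 "n_current", "n_repositionable"],
    )


def drug_calls_table(drug_calls: dict[str, list[DrugCall]]) -> pd.DataFrame:
    rows = []
    for disease in sorted(drug_calls):
        for call in drug_calls[disease]:
            rows.append(
                {
                    "disease": disease,
                    "drug_id": call.drug_id,
                    "drug_name": call.drug_name,
                    "target_genes": ",".join(sorted(call.target_genes)),
                    "currently_used": str(call.currently_used),
                    "matched_term": call.matched_term or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["disease", "drug_id", "drug_name", "target_genes",
                 "currently_used", "matched_term"],
    )
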