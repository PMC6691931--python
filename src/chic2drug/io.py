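"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
- BED (0-based half-open): restriction fragments, chromatin-state segments
  (state label in the name column), gene annotation (symbol, strand; the TSS
  is the 5' end of the record).
- ibed-like TSV: interaction calls with columns
  baitChr baitStart baitEnd baitID oeChr oeStart oeEnd oeID score cellType.
- headered TSV: SNPs/LD proxies, expression, drug targets, reported genes.
- GMT: pathway_id TAB name TAB gene1 TAB gene2 ...
- YAML: disease-term sets.

All writers emit a deterministic sort and column order so reruns are
byte-identical.
"""
from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    ChromatinSegment,
    DiseaseTermSet,
    DrugTargetRecord,
    ExpressionRecord,
    FragmentMap,
    GeneRecord,
    GenomicInterval,
    Interaction,
    ParseError,
    PathwaySet,
    PipelineError,
    RestrictionFragment,
    SnpRecord,
    ValidationError,
    normalize_symbol,
)

IBED_COLUMNS = [
    "baitChr", "baitStart", "baitEnd", "baitID",
    "oeChr", "oeStart", "oeEnd", "oeID", "score", "cellType",
]


def _bed_rows(path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >=4 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
            yield lineno, fields[0], start, end, fields[3:]


def read_bed(path, kind: str, cell_type: str | None = None):
    """Read a BED file as ``fragments`` (a FragmentMap), ``segments``
    (list of ChromatinSegment; requires ``cell_type``) or ``genes``
    (list of GeneRecord)."""
    if kind == "fragments":
        return read_fragments(path)
    if kind == "segments":
        if cell_type is None:
            raise ValueError("cell_type is required for kind='segments'")
        return read_segments(path, cell_type)
    if kind == "genes":
        return read_genes(path)
    raise ValueError(f"unknown BED kind {kind!r}")


def read_fragments(path) -> FragmentMap:
    frags = []
    for lineno, chrom, start, end, rest in _bed_rows(path):
        try:
            frags.append(RestrictionFragment(GenomicInterval(chrom, start, end), rest[0]))
        except ValidationError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return FragmentMap(frags)


def write_fragments(fragment_map: FragmentMap, path) -> None:
    with open(path, "w") as out:
        for frag in fragment_map:
            iv = frag.interval
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag.fragment_id}\n")


def read_segments(path, cell_type: str) -> list[ChromatinSegment]:
    segs = []
    for lineno, chrom, start, end, rest in _bed_rows(path):
        try:
            segs.append(
                ChromatinSegment(GenomicInterval(chrom, start, end), rest[0], cell_type)
            )
        except ValidationError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    segs.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    _check_segments_disjoint(segs, path)
    return segs


def _check_segments_disjoint(segs, path):
    for a, b in zip(segs, segs[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise ValidationError(
                f"{path}: overlapping segments for one cell type at "
                f"{a.interval.chrom}:{b.interval.start}"
            )


def write_segments(segments: list[ChromatinSegment], path) -> None:
    ordered = sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
    with open(path, "w") as out:
        for seg in ordered:
            iv = seg.interval
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.state}\n")


def read_genes(path) -> list[GeneRecord]:
    """BED6 gene annotation; the TSS is the strand-aware 5' end."""
    genes = []
    for lineno, chrom, start, end, rest in _bed_rows(path):
        if len(rest) < 3:
            raise ParseError(path, lineno, "gene BED needs name, score and strand columns")
        symbol, strand = normalize_symbol(rest[0]), rest[2]
        try:
            body = GenomicInterval(chrom, start, end)
            tss_pos = start if strand == "+" else end - 1
            genes.append(
                GeneRecord(symbol, GenomicInterval(chrom, tss_pos, tss_pos + 1), body, strand)
            )
        except ValidationError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    genes.sort(key=lambda g: (g.body.chrom, g.body.start, g.gene_id))
    return genes


def write_genes(genes: list[GeneRecord], path) -> None:
    ordered = sorted(genes, key=lambda g: (g.body.chrom, g.body.start, g.gene_id))
    with open(path, "w") as out:
        for g in ordered:
            b = g.body
            out.write(f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_interactions(path, fragment_map: FragmentMap) -> list[Interaction]:
    """Read ibed-like interaction calls, resolving both ends against the
    fragment map and deduplicating symmetric pairs to canonical order
    (lower genomic coordinate first)."""
    out: dict[tuple[str, str, str], Interaction] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if header[: len(IBED_COLUMNS)] != IBED_COLUMNS:
            raise ParseError(path, 1, f"expected ibed header {IBED_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                bait = fragment_map.resolve(row[0], int(row[1]), int(row[2]))
                oe = fragment_map.resolve(row[4], int(row[5]), int(row[6]))
                score, cell_type = float(row[8]), row[9]
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, f"malformed interaction row: {exc}") from None
            if bait.fragment_id != row[3] or oe.fragment_id != row[7]:
                raise ParseError(
                    path, lineno,
                    f"fragment id mismatch against map: {row[3]}/{row[7]}",
                )
            if bait.interval > oe.interval:
                bait, oe = oe, bait
            try:
                inter = Interaction(bait, oe, score, cell_type)
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            key = (bait.fragment_id, oe.fragment_id, cell_type)
            prev = out.get(key)
            if prev is None or inter.score > prev.score:
                out[key] = inter
    return sorted(
        out.values(),
        key=lambda i: (i.bait.interval, i.other_end.interval, i.cell_type),
    )


def write_interactions(interactions: list[Interaction], path) -> None:
    ordered = sorted(
        interactions, key=lambda i: (i.bait.interval, i.other_end.interval, i.cell_type)
    )
    with open(path, "w") as out:
        out.write("\t".join(IBED_COLUMNS) + "\n")
        for i in ordered:
            b, o = i.bait, i.other_end
            out.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t{b.fragment_id}\t"
                f"{o.interval.chrom}\t{o.interval.start}\t{o.interval.end}\t{o.fragment_id}\t"
                f"{i.score:g}\t{i.cell_type}\n"
            )


def read_gmt(path) -> list[PathwaySet]:
    pathways = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line has no genes")
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(path, lineno, "GMT line has no genes")
            pathways.append(PathwaySet(fields[0], fields[1], genes))
    return pathways


def write_gmt(pathways: list[PathwaySet], path) -> None:
    with open(path, "w") as out:
        for pw in sorted(pathways, key=lambda p: p.pathway_id):
            out.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    return df


def read_snps(path) -> list[SnpRecord]:
    df = _read_tsv(path, ["snp_id", "chrom", "pos", "r2", "index_snp_id", "disease"])
    snps = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            snps.append(
                SnpRecord(
                    row.snp_id, row.chrom, int(row.pos), float(row.r2),
                    row.index_snp_id, row.disease,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return snps


def write_snps(snps: list[SnpRecord], path) -> None:
    rows = sorted(snps, key=lambda s: (s.disease, s.index_snp_id, s.chrom, s.pos, s.snp_id))
    with open(path, "w") as out:
        out.write("snp_id\tchrom\tpos\tr2\tindex_snp_id\tdisease\n")
        for s in rows:
            out.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.r2:g}\t{s.index_snp_id}\t{s.disease}\n")


def read_expression(path, threshold: float) -> list[ExpressionRecord]:
    """Expression table; ``expressed`` is value >= threshold."""
    df = _read_tsv(path, ["gene_id", "cell_type", "value"])
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            value = float(row.value)
            records.append(
                ExpressionRecord(
                    normalize_symbol(row.gene_id), row.cell_type, value,
                    expressed=value >= threshold,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return records


def write_expression(records: list[ExpressionRecord], path) -> None:
    rows = sorted(records, key=lambda r: (r.gene_id, r.cell_type))
    with open(path, "w") as out:
        out.write("gene_id\tcell_type\tvalue\n")
        for r in rows:
            out.write(f"{r.gene_id}\t{r.cell_type}\t{r.value:g}\n")


def read_drug_targets(path) -> list[DrugTargetRecord]:
    df = _read_tsv(path, ["drug_id", "drug_name", "gene_id", "groups", "indication"])
    seen: set[tuple[str, str]] = set()
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        gene = normalize_symbol(row.gene_id)
        key = (row.drug_id, gene)
        if key in seen:
            raise ParseError(path, lineno, f"duplicate drug/gene pair {key}")
        seen.add(key)
        groups = frozenset(g for g in row.groups.split("|") if g)
        records.append(DrugTargetRecord(row.drug_id, row.drug_name, gene, groups, row.indication))
    return records


def write_drug_targets(records: list[DrugTargetRecord], path) -> None:
    rows = sorted(records, key=lambda r: (r.drug_id, r.gene_id))
    with open(path, "w") as out:
        out.write("drug_id\tdrug_name\tgene_id\tgroups\tindication\n")
        for r in rows:
            out.write(
                f"{r.drug_id}\t{r.drug_name}\t{r.gene_id}\t"
                f"{'|'.join(sorted(r.groups))}\t{r.indication_text}\n"
            )


def read_reported_genes(path) -> dict[tuple[str, str], tuple[str, ...]]:
    """Reported GWAS gene labels per (index SNP, disease). A locus may carry
    several comma-separated names; a blank field means no reported gene."""
    df = _read_tsv(path, ["index_snp_id", "disease", "reported_genes"])
    out: dict[tuple[str, str], tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        names = tuple(
            normalize_symbol(g) for g in row.reported_genes.split(",") if g.strip()
        )
        out[(row.index_snp_id, row.disease)] = names
    return out


def write_reported_genes(reported: dict[tuple[str, str], tuple[str, ...]], path) -> None:
    with open(path, "w") as out:
        out.write("index_snp_id\tdisease\treported_genes\n")
        for (snp, disease), genes in sorted(reported.items()):
            out.write(f"{snp}\t{disease}\t{','.join(genes)}\n")


def read_disease_terms(path) -> list[DiseaseTermSet]:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise PipelineError(f"{path}: disease-term YAML must map disease -> list of terms")
    return [
        DiseaseTermSet(disease, tuple(terms)) for disease, terms in sorted(data.items())
    ]


def write_disease_terms(term_sets: list[DiseaseTermSet], path) -> None:
    data = {ts.disease: list(ts.terms) for ts in term_sets}
    with open(path, "w") as out:
        yaml.safe_dump(data, out, sort_keys=True)


def write_candidates_table(candidates, path) -> None:
    """One row per candidate x supporting interaction (the evidence trail)."""
    rows = []
    for c in candidates:
        for inter, enh_id, prom_id in c.interactions:
            rows.append(
                {
                    "disease": c.disease,
                    "index_snp_id": c.index_snp_id,
                    "gene_id": c.gene_id,
                    "cell_type": inter.cell_type,
                    "enhancer_fragment": enh_id,
                    "promoter_fragment": prom_id,
                    "score": f"{inter.score:g}",
                    "expressed_in": ",".join(sorted(c.expressed_in)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "disease", "index_snp_id", "gene_id", "cell_type",
            "enhancer_fragment", "promoter_fragment", "score", "expressed_in",
        ],
    )
    df = df.sort_values(list(df.columns)).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_candidates_table(path) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["disease", "index_snp_id", "gene_id", "cell_type",
         "enhancer_fragment", "promoter_fragment", "score", "expressed_in"],
    )


def candidate_genes_by_disease(df: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse a candidate evidence table to gene sets per disease."""
    out: dict[str, set[str]] = {}
    for disease, sub in df.groupby("disease"):
        out[disease] = {normalize_symbol(g) for g in sub["gene_id"]}
    return out
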