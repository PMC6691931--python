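"""Domain types for the CHi-C locus-to-gene-to-drug pipeline.

All genomic coordinates in memory are 0-based half-open (BED convention).
SNP positions are stored 1-based as in dbSNP-style tables and converted
where fragment overlap is computed.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A line of an input file could not be parsed."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class ValidationError(PipelineError):
    """Parsed records violate a domain invariant."""


class ResolutionError(PipelineError):
    """A coordinate could not be resolved against the loaded fragment map."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_pos(self, chrom: str, pos0: int) -> bool:
        """Whether the 0-based position lies inside the interval."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True, order=True)
class RestrictionFragment:
    """One restriction-digest fragment (the CHi-C unit of resolution)."""

    interval: GenomicInterval
    fragment_id: str


@dataclass(frozen=True)
class SnpRecord:
    """An index SNP or one of its LD proxies.

    ``pos`` is 1-based (dbSNP convention); ``r2`` is linkage disequilibrium
    with the index SNP of the locus (1.0 for the index itself).
    """

    snp_id: str
    chrom: str
    pos: int
    r2: float
    index_snp_id: str
    disease: str

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValidationError(f"r2 out of [0,1] for {self.snp_id}: {self.r2}")
        if self.snp_id == self.index_snp_id and self.r2 != 1.0:
            raise ValidationError(f"index SNP {self.snp_id} must have r2=1 with itself")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class ChromatinSegment:
    """A ChromHMM state segment for one cell type."""

    interval: GenomicInterval
    state: str
    cell_type: str


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its transcription start site (a length-1 interval)."""

    gene_id: str
    tss: GenomicInterval
    body: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")
        if len(self.tss) != 1:
            raise ValidationError(f"TSS of {self.gene_id} must be a length-1 interval")
        if not (
            self.body.chrom == self.tss.chrom
            and self.body.start <= self.tss.start < self.body.end
        ):
            raise ValidationError(f"TSS of {self.gene_id} not inside gene body")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    cell_type: str
    value: float
    expressed: bool

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError(
                f"negative expression for {self.gene_id}/{self.cell_type}"
            )


@dataclass(frozen=True)
class Interaction:
    """A CHICAGO-style interaction call between two restriction fragments."""

    bait: RestrictionFragment
    other_end: RestrictionFragment
    score: float
    cell_type: str

    def __post_init__(self):
        if self.bait.fragment_id == self.other_end.fragment_id:
            raise ValidationError(
                f"self-interaction on fragment {self.bait.fragment_id}"
            )
        if self.score < 0:
            raise ValidationError(f"negative interaction score {self.score}")

    def fragments(self) -> tuple[RestrictionFragment, RestrictionFragment]:
        return (self.bait, self.other_end)

    def partner_of(self, fragment_id: str) -> RestrictionFragment | None:
        if fragment_id == self.bait.fragment_id:
            return self.other_end
        if fragment_id == self.other_end.fragment_id:
            return self.bait
        return None


@dataclass(frozen=True)
class DrugTargetRecord:
    """One drug-gene association with approval groups and indication text."""

    drug_id: str
    drug_name: str
    gene_id: str
    groups: frozenset[str]
    indication_text: str = ""


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"pathway {self.pathway_id} has no genes")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: trimmed, upper-cased."""
    return symbol.strip().upper()


class FragmentMap:
    """The restriction-fragment partition of the genome.

    Within one chromosome fragments must be sorted, non-overlapping and
    contiguous (a restriction digest tiles the covered region without gaps).
    Lookup is by binary search on fragment starts.
    """

    def __init__(self, fragments: list[RestrictionFragment]):
        by_chrom: dict[str, list[RestrictionFragment]] = {}
        seen_ids: set[str] = set()
        for frag in fragments:
            if frag.fragment_id in seen_ids:
                raise ValidationError(f"duplicate fragment id {frag.fragment_id}")
            seen_ids.add(frag.fragment_id)
            by_chrom.setdefault(frag.interval.chrom, []).append(frag)
        for chrom, frags in by_chrom.items():
            frags.sort(key=lambda f: (f.interval.start, f.interval.end))
            for a, b in zip(frags, frags[1:]):
                if b.interval.start < a.interval.end:
                    raise ValidationError(
                        f"overlapping fragments on {chrom}: "
                        f"{a.fragment_id} and {b.fragment_id}"
                    )
                if b.interval.start > a.interval.end:
                    raise ValidationError(
                        f"gap in fragment map on {chrom} between "
                        f"{a.fragment_id} and {b.fragment_id}"
                    )
        self._by_chrom = by_chrom
        self._starts = {
            chrom: [f.interval.start for f in frags]
            for chrom, frags in by_chrom.items()
        }
        self._by_id = {f.fragment_id: f for f in fragments}

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self._by_id

    def get(self, fragment_id: str) -> RestrictionFragment:
        try:
            return self._by_id[fragment_id]
        except KeyError:
            raise ResolutionError(f"unknown fragment id {fragment_id!r}") from None

    def at(self, chrom: str, pos0: int) -> RestrictionFragment | None:
        """Fragment containing the 0-based position, or None if uncovered."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, pos0) - 1
        if i < 0:
            return None
        frag = self._by_chrom[chrom][i]
        return frag if frag.interval.contains_pos(chrom, pos0) else None

    def overlapping(self, interval: GenomicInterval) -> list[RestrictionFragment]:
        """All fragments overlapping the half-open query interval."""
        starts = self._starts.get(interval.chrom)
        if not starts:
            return []
        frags = self._by_chrom[interval.chrom]
        i = max(bisect.bisect_right(starts, interval.start) - 1, 0)
        out = []
        while i < len(frags) and frags[i].interval.start < interval.end:
            if frags[i].interval.overlaps(interval):
                out.append(frags[i])
            i += 1
        return out

    def resolve(self, chrom: str, start: int, end: int) -> RestrictionFragment:
        """The fragment with exactly these coordinates (interaction files)."""
        frag = self.at(chrom, start)
        if frag is None or frag.interval.start != start or frag.interval.end != end:
            raise ResolutionError(
                f"no fragment with coordinates {chrom}:{start}-{end} in map"
            )
        return frag


@dataclass
class LdBlock:
    """All SNPs in LD (r2 above threshold) with one index SNP, plus the
    restriction fragments any member overlaps."""

    index_snp_id: str
    disease: str
    member_snps: list[SnpRecord]
    span: GenomicInterval
    fragments: list[RestrictionFragment] = field(default_factory=list)

    @property
    def fragment_ids(self) -> set[str]:
        return {f.fragment_id for f in self.fragments}


@dataclass(frozen=True)
class FragmentStateCall:
    """Whether a fragment overlaps enhancer / promoter chromatin states in
    one cell type."""

    fragment_id: str
    cell_type: str
    has_enhancer: bool
    has_promoter: bool


@dataclass
class CandidateGene:
    """A gene retained by the enhancer-promoter interaction filter, with
    the complete evidence chain that supports it."""

    gene_id: str
    disease: str
    index_snp_id: str
    cell_types: set[str]
    # (interaction, enhancer-side fragment id, promoter-side fragment id)
    interactions: list[tuple[Interaction, str, str]]
    expressed_in: set[str]


@dataclass(frozen=True)
class DiseaseTermSet:
    """Name variants used to match a disease in drug indication text."""

    disease: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if not self.terms:
            raise ValidationError(f"no terms for disease {self.disease}")
        object.__setattr__(
            self, "terms", tuple(t.strip().lower() for t in self.terms)
        )


@dataclass
class DrugCall:
    """One drug hit by the candidate list for one disease."""

    drug_id: str
    drug_name: str
    disease: str
    target_genes: set[str]
    currently_used: bool = False
    matched_term: str | None = None


@dataclass
class EnrichmentResult:
    """Fisher's-exact over-representation of one pathway in a gene list."""

    pathway_id: str
    pathway_name: str
    disease: str
    k: int  # overlap
    K: int  # pathway size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False
    overlap_genes: frozenset[str] = frozenset()
    cell_type_label: str | None = None


@dataclass
class LocusCategory:
    """Agreement between CHi-C candidates and the reported GWAS gene."""

    index_snp_id: str
    disease: str
    reported_genes: tuple[str, ...]
    n_candidates: int
    category: str | None  # None when no reported gene is available

    NO_CHIC = "no_chic_genes"
    CATEGORIES = ("no_chic_genes", "0", "1", "2-5", "6+")


@dataclass
class RefinedCandidates:
    """Candidates restricted to significant pathways, plus the pathway-wide
    expansion of the drug-target search space."""

    disease: str
    refined_genes: set[str]
    pathway_expanded_genes: set[str]
    refined_drugs: list[DrugCall] = field(default_factory=list)
    expanded_drugs: list[DrugCall] = field(default_factory=list)
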