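"""Independent brute-force replay of the locus-to-gene filter.

Reads the generated files directly with plain string parsing and linear
scans — deliberately sharing no code with the package under test — so it
can serve as an oracle for both the pipeline and the generator's planted
ground truth.
"""
from __future__ import annotations

from pathlib import Path


def _read_lines(path):
    return [l.rstrip("\n") for l in Path(path).read_text().splitlines() if l.strip()]


def read_fragments_raw(path):
    out = []
    for line in _read_lines(path):
        chrom, start, end, fid = line.split("\t")[:4]
        out.append((chrom, int(start), int(end), fid))
    return out


def fragment_at(fragments, chrom, pos0):
    for c, s, e, fid in fragments:
        if c == chrom and s <= pos0 < e:
            return (c, s, e, fid)
    return None


def fragments_overlapping(fragments, chrom, start, end):
    return [
        (c, s, e, fid) for c, s, e, fid in fragments
        if c == chrom and s < end and start < e
    ]


def replay_filter(
    fixture_dir,
    cell_types=("GM12878", "Tcell"),
    r2_threshold=0.8,
    score_threshold=5.0,
    expression_threshold=1.0,
    enhancer_states=frozenset({"6_EnhG", "7_Enh", "12_EnhBiv"}),
    promoter_states=frozenset({"1_TssA", "2_TssAFlnk", "10_TssBiv"}),
):
    """(index_snp, disease) -> candidate gene set, by exhaustive linear scan."""
    fixture_dir = Path(fixture_dir)
    fragments = read_fragments_raw(fixture_dir / "fragments.bed")

    segments = {}
    for cell in cell_types:
        segs = []
        for line in _read_lines(fixture_dir / f"states_{cell}.bed"):
            chrom, start, end, state = line.split("\t")[:4]
            segs.append((chrom, int(start), int(end), state))
        segments[cell] = segs

    genes = []
    for line in _read_lines(fixture_dir / "genes.bed"):
        chrom, start, end, name, _, strand = line.split("\t")[:6]
        start, end = int(start), int(end)
        tss = start if strand == "+" else end - 1
        genes.append((name.upper(), chrom, tss))

    expression = {}
    for line in _read_lines(fixture_dir / "expression.tsv")[1:]:
        gene, cell, value = line.split("\t")
        expression[(gene.upper(), cell)] = float(value)

    interactions = []
    for line in _read_lines(fixture_dir / "interactions.tsv")[1:]:
        f = line.split("\t")
        interactions.append(
            ((f[0], int(f[1]), int(f[2])), (f[4], int(f[5]), int(f[6])), float(f[8]), f[9])
        )

    loci = {}
    for line in _read_lines(fixture_dir / "snps.tsv")[1:]:
        snp_id, chrom, pos, r2, index_id, disease = line.split("\t")
        if float(r2) >= r2_threshold:
            loci.setdefault((index_id, disease), []).append((chrom, int(pos) - 1))

    def has_state(frag, cell, states):
        c, s, e, _ = frag
        return any(
            sc == c and ss < e and s < se and state in states
            for sc, ss, se, state in segments[cell]
        )

    def expressed(gene):
        return any(
            expression.get((gene, cell), 0.0) >= expression_threshold
            for cell in cell_types
        )

    result = {}
    for key, positions in loci.items():
        block_frags = set()
        for chrom, pos0 in positions:
            frag = fragment_at(fragments, chrom, pos0)
            if frag is not None:
                block_frags.add(frag)
        found = set()
        for end_a, end_b, score, cell in interactions:
            if score < score_threshold or cell not in cell_types:
                continue
            frag_a = fragment_at(fragments, end_a[0], end_a[1])
            frag_b = fragment_at(fragments, end_b[0], end_b[1])
            for block_side, other_side in ((frag_a, frag_b), (frag_b, frag_a)):
                if block_side not in block_frags:
                    continue
                if not has_state(block_side, cell, enhancer_states):
                    continue
                if not has_state(other_side, cell, promoter_states):
                    continue
                _, os_, oe_, _ = other_side
                for gene, gchrom, tss in genes:
                    if gchrom == other_side[0] and os_ <= tss < oe_ and expressed(gene):
                        found.add(gene)
        result[key] = found
    return result
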