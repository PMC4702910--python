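"""Shared test utilities: hand-built transcripts, reads and oracles."""

from __future__ import annotations

from typing import List, Sequence, Tuple

from splicequant import TranscriptModel
from splicequant.simulate import _sam_record, sam_text

Interval = Tuple[int, int]


def mk_tx(
    tid: str,
    exons: Sequence[Interval],
    strand: str = "+",
    gene: str = "G1",
    symbol: str = "GENE",
    chrom: str = "chrT",
    cds: Sequence[Interval] | None = None,
) -> TranscriptModel:
    exons = sorted(tuple(iv) for iv in exons)
    t = TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        exons=list(exons),
        cds=list(exons) if cds is None else sorted(tuple(iv) for iv in cds),
    )
    t.validate()
    return t


def sam_from_blocks(
    chrom: str, reads: Sequence[Tuple[str, Sequence[Interval]]], length: int = 100_000
) -> str:
    """Coordinate-sorted SAM from (qname, genomic blocks) pairs."""
    return sam_text(chrom, length, [_sam_record(q, chrom, b) for q, b in reads])


def fragmentation_oracle(exon_sets: Sequence[Sequence[Interval]]) -> List[Interval]:
    """Brute-force exon-part atoms: consecutive boundary pairs covered by
    at least one exon.  Independent of the graph builder."""
    ivs = [iv for ivs in exon_sets for iv in ivs]
    boundaries = sorted({b for iv in ivs for b in iv})
    atoms = []
    for a, b in zip(boundaries, boundaries[1:]):
        if any(s <= a and b <= e for s, e in ivs):
            atoms.append((a, b))
    return atoms
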