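"""Read counting, novel-junction discovery, normalization and PSI.

Counting rules
--------------
* A primary, mapped record contributes 1 to an exon part's count for each
  part its aligned blocks overlap by at least ``min_anchor`` bases
  (blocks are CIGAR runs merged over M/D/=/X and split at N).
* It contributes 1 to a splice's count when a pair of consecutive blocks
  matches the splice's intron exactly and both anchoring blocks are at
  least ``min_anchor`` bases long.
* ``total_aligned_reads`` is the number of primary mapped records in the
  sample, whether or not they fall on any gene.

PSI for an event is the ratio of raw include-evidence counts to total
covering counts, reported only when the total reaches ``min_coverage``
(default 8) reads; below that the value is missing, not zero.
Length-normalized observations (reads per 1000 exonic bases per million
aligned reads for parts, reads per million for splices) are computed for
export and graph shading but do not enter the PSI ratio by default.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pysam
from intervaltree import IntervalTree

from .events import SpliceEvent
from .gene_model import Interval, SpliceGraph, SpliceKey, build_splice_graph

log = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 4
DEFAULT_MIN_COVERAGE = 8


@dataclass
class SampleCounts:
    """Raw and normalized per-element read totals for one sample and gene."""

    sample_id: str
    gene_id: str
    part_reads: Dict[str, int]
    splice_reads: Dict[SpliceKey, int]
    total_aligned_reads: int = 0
    part_obs: Optional[Dict[str, float]] = None
    splice_obs: Optional[Dict[SpliceKey, float]] = None

    @classmethod
    def zeros(cls, sample_id: str, graph: SpliceGraph) -> "SampleCounts":
        return cls(
            sample_id=sample_id,
            gene_id=graph.gene_id,
            part_reads={p.part_id: 0 for p in graph.parts},
            splice_reads={k: 0 for k in graph.splices},
        )


@dataclass(frozen=True)
class PsiValue:
    event_id: str
    sample_id: str
    psi: Optional[float]
    include_reads: int
    exclude_reads: int

    @property
    def total_reads(self) -> int:
        return self.include_reads + self.exclude_reads


# ---------------------------------------------------------------------------
# alignment access
# ---------------------------------------------------------------------------

def _open_alignments(aln) -> Tuple[pysam.AlignmentFile, bool]:
    if isinstance(aln, pysam.AlignmentFile):
        return aln, False
    return pysam.AlignmentFile(str(aln), require_index=False), True


def _check_sorted(af: pysam.AlignmentFile) -> None:
    so = af.header.to_dict().get("HD", {}).get("SO")
    if so != "coordinate":
        raise ValueError(
            "alignments must be coordinate-sorted (header SO:coordinate); "
            "run `samtools sort` first"
        )


def aligned_blocks(read: pysam.AlignedSegment) -> List[Interval]:
    """Reference-space blocks of a record: M/=/X/D runs merged, split at N."""
    blocks: List[Interval] = []
    pos = read.reference_start
    cur = pos
    for op, ln in read.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += ln
        elif op == 3:           # N: reference skip delimits a junction
            if pos > cur:
                blocks.append((cur, pos))
            pos += ln
            cur = pos
        # I, S, H, P consume no reference
    if pos > cur:
        blocks.append((cur, pos))
    return blocks


def _count_into(
    counts: SampleCounts,
    graph: SpliceGraph,
    blocks: Sequence[Interval],
    intron_index: Mapping[Interval, SpliceKey],
    min_anchor: int,
) -> None:
    for part in graph.parts:
        ov = sum(
            max(0, min(be, part.end) - max(bs, part.start)) for bs, be in blocks
        )
        if ov >= min_anchor:
            counts.part_reads[part.part_id] += 1
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        key = intron_index.get((e1, s2))
        if key is not None and (e1 - s1) >= min_anchor and (e2 - s2) >= min_anchor:
            counts.splice_reads[key] += 1


def count_sample(
    aln,
    graphs: Sequence[SpliceGraph],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    sample_id: Optional[str] = None,
) -> Dict[str, SampleCounts]:
    """Single pass over a coordinate-sorted SAM/BAM, counting exon-part
    and junction evidence for every gene; returns counts keyed by
    gene_id.  Records on chromosomes absent from all graphs are skipped
    silently but still counted toward ``total_aligned_reads``."""
    af, own = _open_alignments(aln)
    _check_sorted(af)
    if sample_id is None:
        name = getattr(aln, "filename", None) or getattr(af, "filename", b"sample")
        if isinstance(name, bytes):
            name = name.decode()
        sample_id = Path(str(name)).stem

    trees: Dict[str, IntervalTree] = {}
    counts: Dict[str, SampleCounts] = {}
    introns: Dict[str, Mapping[Interval, SpliceKey]] = {}
    for g in graphs:
        s, e = g.span
        trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
        counts[g.gene_id] = SampleCounts.zeros(sample_id, g)
        introns[g.gene_id] = g.intron_index

    total = 0
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            blocks = aligned_blocks(read)
            if not blocks:
                continue
            for iv in tree.overlap(blocks[0][0], blocks[-1][1]):
                g: SpliceGraph = iv.data
                _count_into(counts[g.gene_id], g, blocks, introns[g.gene_id], min_anchor)
    finally:
        if own:
            af.close()
    for sc in counts.values():
        sc.total_aligned_reads = total
    return counts


def count_reads(
    aln, graph: SpliceGraph, min_anchor: int = DEFAULT_MIN_ANCHOR,
    sample_id: Optional[str] = None,
) -> SampleCounts:
    """Count exon-body and junction reads for a single gene."""
    return count_sample(aln, [graph], min_anchor=min_anchor, sample_id=sample_id)[
        graph.gene_id
    ]


# ---------------------------------------------------------------------------
# novel junction discovery
# ---------------------------------------------------------------------------

def _valid_donor_boundary(graph: SpliceGraph, pos: int) -> bool:
    return any(p.start < pos <= p.end for p in graph.parts)


def _valid_acceptor_boundary(graph: SpliceGraph, pos: int) -> bool:
    return any(p.start <= pos < p.end for p in graph.parts)


def discover_novel_junctions(
    aln,
    graph: SpliceGraph,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_reads: int = 1,
) -> SpliceGraph:
    """Find split-read junctions absent from the annotation-derived graph.

    A junction is accepted only when both of its boundaries lie on
    existing part boundaries or strictly inside existing parts (splitting
    them); junctions with either end outside all known exonic territory
    are discarded — novel exons are never inferred.  Accepted junctions
    are added as ``novel=True`` splices and the gene is re-fragmented so
    base→part uniqueness still holds.  Returns a new graph; the input is
    untouched.
    """
    af, own = _open_alignments(aln)
    try:
        _check_sorted(af)
        gs_, ge_ = graph.span
        observed: Counter = Counter()
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != graph.chrom:
                continue
            if read.reference_end is None or read.reference_end < gs_ or read.reference_start > ge_:
                continue
            blocks = aligned_blocks(read)
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if (e1 - s1) >= min_anchor and (e2 - s2) >= min_anchor:
                    observed[(e1, s2)] += 1
    finally:
        if own:
            af.close()

    known = set(graph.intron_index)
    accepted: List[Interval] = []
    for (ds, de), n in sorted(observed.items()):
        if n < min_reads or (ds, de) in known or de <= ds:
            continue
        if _valid_donor_boundary(graph, ds) and _valid_acceptor_boundary(graph, de):
            accepted.append((ds, de))
        else:
            log.info(
                "%s: junction %d-%d outside exonic territory; discarded",
                graph.gene_symbol, ds, de,
            )
    if not accepted:
        return graph

    extra = sorted({b for iv in accepted for b in iv})
    rebuilt = build_splice_graph(
        graph.transcripts,
        extra_boundaries=extra,
        novel_introns=list(graph.novel_introns()) + accepted,
    )
    return rebuilt


# ---------------------------------------------------------------------------
# normalization and PSI
# ---------------------------------------------------------------------------

def normalize_counts(counts: SampleCounts, graph: SpliceGraph) -> SampleCounts:
    """Fill normalized observations: parts as reads per 1000 exonic bases
    per million aligned reads; splices (no length term) as reads per
    million aligned reads."""
    if counts.total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive to normalize")
    per_million = counts.total_aligned_reads / 1e6
    part_obs = {
        pid: n / (graph.part(pid).length_bases / 1000.0) / per_million
        for pid, n in counts.part_reads.items()
    }
    splice_obs = {k: n / per_million for k, n in counts.splice_reads.items()}
    return replace(counts, part_obs=part_obs, splice_obs=splice_obs)


def _sum_elements(counts: SampleCounts, elements, normalized: bool) -> float:
    part_src = counts.part_obs if normalized else counts.part_reads
    splice_src = counts.splice_obs if normalized else counts.splice_reads
    total = 0.0
    for el in elements:
        if isinstance(el, str):
            total += part_src.get(el, 0)
        else:
            total += splice_src.get(el, 0)
    return total


def compute_psi(
    event: SpliceEvent,
    counts: SampleCounts,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    use_normalized: bool = False,
) -> PsiValue:
    """Percent Spliced In for one event in one sample.

    PSI = include evidence / (include + exclude evidence).  The coverage
    gate always applies to raw read totals: fewer than ``min_coverage``
    covering reads yields a missing value.  ``use_normalized`` switches
    the ratio itself (not the gate) to length-normalized observations.
    """
    inc_raw = int(_sum_elements(counts, event.include_elements, normalized=False))
    exc_raw = int(_sum_elements(counts, event.exclude_elements, normalized=False))
    total = inc_raw + exc_raw
    if total < min_coverage:
        psi = None
    elif use_normalized:
        if counts.part_obs is None:
            raise ValueError("normalize_counts must run before use_normalized PSI")
        inc = _sum_elements(counts, event.include_elements, normalized=True)
        exc = _sum_elements(counts, event.exclude_elements, normalized=True)
        psi = inc / (inc + exc) if inc + exc > 0 else None
    else:
        psi = inc_raw / total
    return PsiValue(
        event_id=event.event_id,
        sample_id=counts.sample_id,
        psi=psi,
        include_reads=inc_raw,
        exclude_reads=exc_raw,
    )


def quantify_sample(
    aln,
    graphs: Sequence[SpliceGraph],
    events: Sequence[SpliceEvent],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    sample_id: Optional[str] = None,
    use_normalized: bool = False,
) -> Tuple[Dict[str, SampleCounts], List[PsiValue]]:
    """Count one sample against a set of gene graphs and compute PSI for
    every catalogued event."""
    counts = count_sample(aln, graphs, min_anchor=min_anchor, sample_id=sample_id)
    by_gene = {g.gene_id: g for g in graphs}
    if use_normalized:
        counts = {
            gid: normalize_counts(sc, by_gene[gid]) for gid, sc in counts.items()
        }
    psis = [
        compute_psi(e, counts[e.gene_id], min_coverage=min_coverage,
                    use_normalized=use_normalized)
        for e in events
        if e.gene_id in counts
    ]
    return counts, psis


# ---------------------------------------------------------------------------
# per-sample exports
# ---------------------------------------------------------------------------

def export_counts_table(counts: Mapping[str, SampleCounts], path=None):
    """Tab-delimited per-sample counts: element, raw count, normalized obs."""
    import pandas as pd
    from .events import element_label

    rows = []
    for gid, sc in counts.items():
        for pid, n in sc.part_reads.items():
            rows.append(
                {
                    "gene_id": gid,
                    "element": pid,
                    "kind": "part",
                    "raw": n,
                    "obs": None if sc.part_obs is None else sc.part_obs[pid],
                }
            )
        for key, n in sc.splice_reads.items():
            rows.append(
                {
                    "gene_id": gid,
                    "element": element_label(key),
                    "kind": "splice",
                    "raw": n,
                    "obs": None if sc.splice_obs is None else sc.splice_obs[key],
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "element", "kind", "raw", "obs"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df


def export_psi_table(psis: Iterable[PsiValue], path=None):
    """Tab-delimited per-sample PSI: event, psi-or-NA, include, exclude."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "event_id": p.event_id,
                "psi": p.psi,
                "include_reads": p.include_reads,
                "exclude_reads": p.exclude_reads,
            }
            for p in psis
        ],
        columns=["event_id", "psi", "include_reads", "exclude_reads"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df
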