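"""Unified per-gene splice graphs from transcript annotations.

A gene's protein-coding transcript isoforms are merged into a single
directed acyclic *splice graph*: nodes are **exon parts** (maximal exonic
sub-intervals not crossed by any transcript boundary) and edges are
**splices** (donor/acceptor junctions).  Because exons from all isoforms
are fragmented at every distinct boundary, each genomic base covered by
any exon belongs to exactly one part, so an aligned read has a single
unambiguous placement on the graph.  Parts are labelled ``N`` or ``N.k``
in transcription order (``N`` is the exon-region ordinal, ``k`` the
sub-part ordinal); labels on the minus strand therefore run against
genomic coordinates.

Coordinates are 0-based half-open internally; GTF input/output is 1-based
inclusive, converted at the I/O boundary.
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import gffutils
import networkx as nx

log = logging.getLogger(__name__)

Interval = Tuple[int, int]
#: A splice is keyed by its (from_part, to_part) labels within one gene.
SpliceKey = Tuple[str, str]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line, naming the offending line number."""


@dataclass
class TranscriptModel:
    """One transcript isoform as read from annotation.

    ``exons`` and ``cds`` are genomic intervals, 0-based half-open, sorted
    by genomic coordinate and non-overlapping within the transcript.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon interval {(s, e)}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS {(cs, ce)} not contained in an exon"
                )

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class ExonPart:
    """Maximal exonic sub-interval not split by any transcript boundary."""

    part_id: str
    chrom: str
    start: int
    end: int
    coding: bool = False
    novel: bool = False  # annotation-derived parts are never novel

    @property
    def length_bases(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Splice:
    """A donor→acceptor junction between two exon parts.

    ``from_part`` precedes ``to_part`` in transcription order; donor and
    acceptor positions are genomic (donor = transcription 3' boundary of
    the upstream part, acceptor = transcription 5' boundary of the
    downstream part).
    """

    from_part: str
    to_part: str
    donor_pos: int
    acceptor_pos: int
    novel: bool = False

    @property
    def key(self) -> SpliceKey:
        return (self.from_part, self.to_part)


@dataclass
class SpliceGraph:
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    parts: List[ExonPart]                      # transcription order
    splices: Dict[SpliceKey, Splice]
    transcript_paths: Dict[str, List[str]]     # transcript_id -> part_id sequence
    transcripts: List[TranscriptModel] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def part(self, part_id: str) -> ExonPart:
        return self._part_index[part_id]

    @property
    def _part_index(self) -> Dict[str, ExonPart]:
        return {p.part_id: p for p in self.parts}

    @property
    def order(self) -> Dict[str, int]:
        """Transcription-order index of each part."""
        return {p.part_id: i for i, p in enumerate(self.parts)}

    def region_of(self, part_id: str) -> int:
        """Exon-region ordinal (the ``N`` of a ``N.k`` label)."""
        return int(part_id.split(".")[0])

    def intron(self, key: SpliceKey) -> Interval:
        """Genomic (start, end) of the intron removed by a splice."""
        a = self.part(key[0])
        b = self.part(key[1])
        left, right = (a, b) if a.start < b.start else (b, a)
        return (left.end, right.start)

    @property
    def intron_index(self) -> Dict[Interval, SpliceKey]:
        return {self.intron(k): k for k in self.splices}

    @property
    def span(self) -> Interval:
        return (min(p.start for p in self.parts), max(p.end for p in self.parts))

    def adjacent_pairs(self) -> set:
        """(a, b) pairs that are consecutive and genomically contiguous in
        some transcript path (read-through, not splices)."""
        pairs = set()
        for path in self.transcript_paths.values():
            for a, b in zip(path, path[1:]):
                if (a, b) not in self.splices:
                    pairs.add((a, b))
        return pairs

    def novel_introns(self) -> List[Interval]:
        return [self.intron(k) for k, s in self.splices.items() if s.novel]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for p in self.parts:
            g.add_node(p.part_id, start=p.start, end=p.end)
        for path in self.transcript_paths.values():
            for a, b in zip(path, path[1:]):
                kind = "splice" if (a, b) in self.splices else "adjacent"
                g.add_edge(a, b, kind=kind)
        for key, sp in self.splices.items():
            if key not in g.edges:
                g.add_edge(*key, kind="splice")
        return g

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "gene_symbol": self.gene_symbol,
            "chrom": self.chrom,
            "strand": self.strand,
            "parts": [
                [p.part_id, p.start, p.end, p.coding, p.novel] for p in self.parts
            ],
            "splices": [
                [s.from_part, s.to_part, s.donor_pos, s.acceptor_pos, s.novel]
                for s in self.splices.values()
            ],
            "transcript_paths": self.transcript_paths,
            "transcripts": [
                {
                    "transcript_id": t.transcript_id,
                    "exons": t.exons,
                    "cds": t.cds,
                }
                for t in self.transcripts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpliceGraph":
        parts = [
            ExonPart(pid, d["chrom"], s, e, coding, novel)
            for pid, s, e, coding, novel in d["parts"]
        ]
        splices = {
            (f, t): Splice(f, t, dp, ap, novel)
            for f, t, dp, ap, novel in d["splices"]
        }
        transcripts = [
            TranscriptModel(
                transcript_id=t["transcript_id"],
                gene_id=d["gene_id"],
                gene_symbol=d["gene_symbol"],
                chrom=d["chrom"],
                strand=d["strand"],
                exons=[tuple(iv) for iv in t["exons"]],
                cds=[tuple(iv) for iv in t["cds"]],
            )
            for t in d.get("transcripts", [])
        ]
        return cls(
            gene_id=d["gene_id"],
            gene_symbol=d["gene_symbol"],
            chrom=d["chrom"],
            strand=d["strand"],
            parts=parts,
            splices=splices,
            transcript_paths={k: list(v) for k, v in d["transcript_paths"].items()},
            transcripts=transcripts,
        )


# ---------------------------------------------------------------------------
# GTF input
# ---------------------------------------------------------------------------

def _validate_gtf_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GtfParseError(
                f"malformed GTF line {i}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise GtfParseError(
                f"malformed GTF line {i}: non-integer coordinates"
            ) from exc
        if end < start:
            raise GtfParseError(f"malformed GTF line {i}: end < start")


def read_gene_models(gtf_source, coding_only: bool = True) -> List[TranscriptModel]:
    """Parse transcript models from GTF (path, text, or open file).

    Only ``exon`` and ``CDS`` features are used.  With ``coding_only``
    (the default) transcripts lacking any CDS feature are dropped, so the
    downstream graphs cover protein-coding isoforms only.  Transcripts
    with inconsistent strand or chromosome across their exons are rejected
    with a logged warning.
    """
    if hasattr(gtf_source, "read"):
        text = gtf_source.read()
    elif isinstance(gtf_source, (str, os.PathLike)) and os.path.exists(str(gtf_source)):
        with open(gtf_source) as fh:
            text = fh.read()
    else:
        text = str(gtf_source)

    _validate_gtf_lines(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    raw: Dict[str, dict] = {}
    for ftype, bucket in (("exon", "exons"), ("CDS", "cds")):
        for f in db.features_of_type(ftype):
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes["gene_id"][0]
            sym = f.attributes.get("gene_name", [gid])[0]
            rec = raw.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "gene_symbol": sym,
                    "chroms": set(),
                    "strands": set(),
                    "exons": [],
                    "cds": [],
                },
            )
            rec["chroms"].add(f.seqid)
            rec["strands"].add(f.strand)
            rec[bucket].append((f.start - 1, f.end))  # GTF 1-based incl -> half-open

    models: List[TranscriptModel] = []
    for tid, rec in raw.items():
        if len(rec["strands"]) != 1 or rec["strands"] == {"."}:
            log.warning("transcript %s rejected: inconsistent or missing strand", tid)
            continue
        if len(rec["chroms"]) != 1:
            log.warning("transcript %s rejected: features on multiple chromosomes", tid)
            continue
        if not rec["exons"]:
            log.warning("transcript %s rejected: no exon features", tid)
            continue
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            gene_symbol=rec["gene_symbol"],
            chrom=next(iter(rec["chroms"])),
            strand=next(iter(rec["strands"])),
            exons=sorted(rec["exons"]),
            cds=sorted(rec["cds"]),
        )
        model.validate()
        if coding_only and not model.is_coding:
            log.info("transcript %s dropped: no CDS (coding-only mode)", tid)
            continue
        models.append(model)
    return models


def group_by_gene(models: Iterable[TranscriptModel]) -> Dict[str, List[TranscriptModel]]:
    out: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        out.setdefault(m.gene_id, []).append(m)
    return out


def write_gtf(models: Iterable[TranscriptModel], path=None) -> str:
    """Serialize transcript models back to GTF (exon + CDS features)."""
    lines = []
    for m in models:
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_name "{m.gene_symbol}";'
        )
        for ftype, ivs in (("exon", m.exons), ("CDS", m.cds)):
            for s, e in ivs:
                lines.append(
                    "\t".join(
                        [
                            m.chrom,
                            "splicequant",
                            ftype,
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            "0" if ftype == "CDS" else ".",
                            attrs,
                        ]
                    )
                )
    lines.sort(key=lambda l: (l.split("\t")[0], int(l.split("\t")[3])))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: Iterable[Interval]) -> List[Interval]:
    merged: List[List[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_splice_graph(
    transcripts: Sequence[TranscriptModel],
    extra_boundaries: Iterable[int] = (),
    novel_introns: Iterable[Interval] = (),
) -> SpliceGraph:
    """Assemble one gene's transcripts into a unified splice graph.

    Exons from all transcripts are fragmented at every distinct boundary
    (donor, acceptor, transcript start/end, plus any ``extra_boundaries``)
    so that overlapping exon variants resolve into shared and private
    parts.  ``novel_introns`` re-attaches previously discovered
    unannotated junctions (marked ``novel=True``) after a rebuild.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("cannot build a splice graph from zero transcripts")
    strands = {t.strand for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    genes = {t.gene_id for t in transcripts}
    if len(strands) != 1:
        raise ValueError(f"transcripts on mixed strands: {sorted(strands)}")
    if len(chroms) != 1:
        raise ValueError(f"transcripts on multiple chromosomes: {sorted(chroms)}")
    if len(genes) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(genes)}")
    strand = strands.pop()
    chrom = chroms.pop()

    all_exons = [iv for t in transcripts for iv in t.exons]
    cover = _merge_intervals(all_exons)
    boundaries = sorted(
        {b for iv in all_exons for b in iv} | set(extra_boundaries)
    )

    cds_cover = _merge_intervals(iv for t in transcripts for iv in t.cds)

    def overlaps_cds(s: int, e: int) -> bool:
        return any(cs < e and s < ce for cs, ce in cds_cover)

    atoms: List[Interval] = []
    for rs, re_ in cover:
        cuts = [b for b in boundaries if rs < b < re_]
        edges = [rs, *cuts, re_]
        atoms.extend(zip(edges, edges[1:]))

    parts = [
        ExonPart("?", chrom, s, e, coding=overlaps_cds(s, e)) for s, e in atoms
    ]
    if strand == "-":
        parts = parts[::-1]
    _assign_labels(parts, strand)
    by_start = {p.start: p for p in parts}

    paths: Dict[str, List[str]] = {}
    for t in transcripts:
        ids: List[str] = []
        for s, e in t.exons:
            pos = s
            while pos < e:
                p = by_start[pos]
                ids.append(p.part_id)
                pos = p.end
        if t.strand == "-":
            ids = ids[::-1]
        paths[t.transcript_id] = ids

    part_index = {p.part_id: p for p in parts}

    def make_splice(a: str, b: str, novel: bool) -> Splice:
        pa, pb = part_index[a], part_index[b]
        if strand == "+":
            return Splice(a, b, donor_pos=pa.end, acceptor_pos=pb.start, novel=novel)
        return Splice(a, b, donor_pos=pa.start, acceptor_pos=pb.end, novel=novel)

    splices: Dict[SpliceKey, Splice] = {}
    for path in paths.values():
        for a, b in zip(path, path[1:]):
            pa, pb = part_index[a], part_index[b]
            contiguous = (
                pa.end == pb.start if strand == "+" else pb.end == pa.start
            )
            if not contiguous and (a, b) not in splices:
                splices[(a, b)] = make_splice(a, b, novel=False)

    graph = SpliceGraph(
        gene_id=transcripts[0].gene_id,
        gene_symbol=transcripts[0].gene_symbol,
        chrom=chrom,
        strand=strand,
        parts=parts,
        splices=splices,
        transcript_paths=paths,
        transcripts=transcripts,
    )

    for gs, ge in novel_introns:
        _attach_novel_splice(graph, gs, ge)
    return graph


def _attach_novel_splice(graph: SpliceGraph, gs: int, ge: int) -> bool:
    """Attach an unannotated junction whose intron is (gs, ge); returns
    False when either boundary does not coincide with part boundaries."""
    left = next((p for p in graph.parts if p.end == gs), None)
    right = next((p for p in graph.parts if p.start == ge), None)
    if left is None or right is None:
        return False
    if graph.strand == "+":
        frm, to = left, right
        donor, acceptor = left.end, right.start
    else:
        frm, to = right, left
        donor, acceptor = right.start, left.end
    key = (frm.part_id, to.part_id)
    if key in graph.splices:
        return True
    graph.splices[key] = Splice(*key, donor_pos=donor, acceptor_pos=acceptor, novel=True)
    return True


def _assign_labels(parts_in_transcription_order: List[ExonPart], strand: str) -> None:
    """Label parts N / N.k: exon regions (maximal genomically contiguous
    runs) numbered in transcription order, sub-parts likewise."""
    genomic = sorted(parts_in_transcription_order, key=lambda p: p.start)
    regions: List[List[ExonPart]] = []
    for p in genomic:
        if regions and regions[-1][-1].end == p.start:
            regions[-1].append(p)
        else:
            regions.append([p])
    if strand == "-":
        regions = [r[::-1] for r in regions[::-1]]
    for n, region in enumerate(regions, start=1):
        if len(region) == 1:
            region[0].part_id = str(n)
        else:
            for k, p in enumerate(region, start=1):
                p.part_id = f"{n}.{k}"


def number_exons(graph: SpliceGraph) -> SpliceGraph:
    """(Re)assign exon-part labels in transcription order, rewriting
    splices and transcript paths consistently.  Idempotent."""
    old_ids = [p.part_id for p in graph.parts]
    _assign_labels(graph.parts, graph.strand)
    remap = dict(zip(old_ids, (p.part_id for p in graph.parts)))
    graph.splices = {
        (remap[f], remap[t]): replace(s, from_part=remap[f], to_part=remap[t])
        for (f, t), s in graph.splices.items()
    }
    graph.transcript_paths = {
        tid: [remap[p] for p in path] for tid, path in graph.transcript_paths.items()
    }
    return graph


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_exon_reference(graphs: Iterable[SpliceGraph], path=None):
    """One row per exon part with 1-based inclusive genomic coordinates,
    the cross-referencing table users match against other exon naming
    schemes."""
    import pandas as pd

    rows = [
        {
            "gene_symbol": g.gene_symbol,
            "part_id": p.part_id,
            "chrom": p.chrom,
            "start": p.start + 1,
            "end": p.end,
            "strand": g.strand,
        }
        for g in graphs
        for p in g.parts
    ]
    df = pd.DataFrame(rows, columns=["gene_symbol", "part_id", "chrom", "start", "end", "strand"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def write_graphs(graphs: Iterable[SpliceGraph], path) -> None:
    """JSON-lines serialization, one gene per line."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps(g.to_dict()) + "\n")


def read_graphs(path) -> List[SpliceGraph]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(SpliceGraph.from_dict(json.loads(line)))
    return out
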