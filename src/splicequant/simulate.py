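"""Synthetic gene models, isoform mixtures and spliced reads with known
ground truth.

The generator builds a two-isoform gene on a synthetic chromosome whose
splice graph contains exactly the requested alternative-splicing
patterns: isoform T1 carries the *include* form of every pattern (the
cassette exon, the donor/acceptor extension, the retained intron, the
transcription-order-first mutually exclusive exon, the first promoter
and the first terminator) and isoform T2 the *exclude* form.  Reads are
sampled uniformly along each isoform in proportion to its mixture
fraction, emitted as coordinate-sorted spliced SAM records with ``N``
CIGAR operations at introns, and tallied into a truth table computed in
isoform coordinate space — an arithmetic path independent of the
genome-space counting it validates.

Reads are error-free and uniquely placeable by construction; sequencing
error and coverage-bias models are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import EVENT_TYPES, SpliceEvent
from .gene_model import (
    Interval,
    SpliceGraph,
    SpliceKey,
    TranscriptModel,
    build_splice_graph,
    write_gtf,
)

_INTERNAL = ("ES", "AD", "AA", "RI", "ME")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic gene.

    ``depth`` is the expected number of junction-spanning reads per
    splice at mixture fraction 1; ``inclusion`` is the mixture fraction
    of the include-form isoform T1.
    """

    events: Tuple[str, ...] = ("ES",)
    inclusion: float = 0.5
    depth: float = 60.0
    read_length: int = 75
    exon_length: int = 150
    intron_length: int = 120
    extension_length: int = 60
    min_anchor: int = 4
    gene_id: str = "FIXG1"
    gene_symbol: str = "FIX1"
    chrom: str = "chrS"
    strand: str = "+"
    origin: int = 1000

    def __post_init__(self) -> None:
        unknown = set(self.events) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event codes: {sorted(unknown)}")
        if not 0.0 <= self.inclusion <= 1.0:
            raise ValueError("inclusion fraction must lie in [0, 1]")
        if self.exon_length < self.read_length:
            raise ValueError("exon_length must be >= read_length for body reads")
        if self.extension_length < self.min_anchor:
            raise ValueError("extension shorter than the junction anchor")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    def mixture(self) -> Dict[str, float]:
        if not self.events:
            return {f"{self.gene_id}.t1": 1.0}
        return {
            f"{self.gene_id}.t1": self.inclusion,
            f"{self.gene_id}.t2": 1.0 - self.inclusion,
        }


@dataclass
class TruthTable:
    """Exact per-element read counts and per-event inclusion truth."""

    part_counts: Dict[str, int]
    splice_counts: Dict[SpliceKey, int]
    reads_per_isoform: Dict[str, int]
    total_reads: int


@dataclass
class FixtureGene:
    spec: FixtureSpec
    transcripts: List[TranscriptModel]
    graph: SpliceGraph
    gtf: str


@dataclass
class SimulatedSample:
    sample_id: str
    sam: str
    truth: TruthTable


# ---------------------------------------------------------------------------
# gene model generation
# ---------------------------------------------------------------------------

def _layout(spec: FixtureSpec) -> Tuple[List[Interval], List[Interval]]:
    """Exon intervals (genomic, plus-strand orientation) for T1 and T2."""
    e, g, d = spec.exon_length, spec.intron_length, spec.extension_length
    t1: List[Interval] = []
    t2: List[Interval] = []
    pos = spec.origin

    def both() -> None:
        nonlocal pos
        t1.append((pos, pos + e))
        t2.append((pos, pos + e))
        pos += e + g

    if not spec.events:
        # single-transcript gene: three constitutive exons, zero events
        for _ in range(3):
            t1.append((pos, pos + e))
            pos += e + g
        return t1, []

    if "AT" in spec.events:
        t1.append((pos, pos + e))
        pos += e + g
        t2.append((pos, pos + e))
        pos += e + g
    both()  # first shared anchor
    for kind in spec.events:
        if kind not in _INTERNAL:
            continue
        if kind == "ES":
            t1.append((pos, pos + e))
            pos += e + g
        elif kind == "AD":
            t1.append((pos, pos + e + d))
            t2.append((pos, pos + e))
            pos += e + d + g
        elif kind == "AA":
            t1.append((pos, pos + e + d))
            t2.append((pos + d, pos + e + d))
            pos += e + d + g
        elif kind == "RI":
            t1.append((pos, pos + 2 * e + g))
            t2.append((pos, pos + e))
            t2.append((pos + e + g, pos + 2 * e + g))
            pos += 2 * e + 2 * g
        elif kind == "ME":
            t1.append((pos, pos + e))
            t2.append((pos + e + g, pos + 2 * e + g))
            pos += 2 * (e + g)
        both()  # shared anchor after every internal unit
    if "AL" in spec.events:
        t1.append((pos, pos + e))
        pos += e + g
        t2.append((pos, pos + e))
        pos += e + g
    return t1, t2


def _reflect(intervals: Sequence[Interval], lo: int, hi: int) -> List[Interval]:
    return sorted((lo + hi - e, lo + hi - s) for s, e in intervals)


def generate_gene_model(spec: FixtureSpec) -> FixtureGene:
    """Build the synthetic gene: transcripts, splice graph and GTF text."""
    t1, t2 = _layout(spec)
    exon_sets = [ivs for ivs in (t1, t2) if ivs]
    if spec.strand == "-":
        lo = spec.origin
        hi = max(e for ivs in exon_sets for _, e in ivs)
        exon_sets = [_reflect(ivs, lo, hi) for ivs in exon_sets]
    transcripts = [
        TranscriptModel(
            transcript_id=f"{spec.gene_id}.t{i + 1}",
            gene_id=spec.gene_id,
            gene_symbol=spec.gene_symbol,
            chrom=spec.chrom,
            strand=spec.strand,
            exons=list(ivs),
            cds=list(ivs),
        )
        for i, ivs in enumerate(exon_sets)
    ]
    for t in transcripts:
        t.validate()
    graph = build_splice_graph(transcripts)
    return FixtureGene(spec=spec, transcripts=transcripts, graph=graph,
                       gtf=write_gtf(transcripts))


def true_inclusion(event: SpliceEvent, fixture: FixtureGene,
                   mixture: Optional[Mapping[str, float]] = None) -> float:
    """Ground-truth inclusion fraction of an event under the isoform
    mixture: the mixture mass of isoforms whose path carries all include
    elements, over the mass of isoforms supporting either form."""
    mixture = dict(mixture) if mixture is not None else fixture.spec.mixture()
    graph = fixture.graph

    def path_elements(tid: str) -> set:
        path = graph.transcript_paths[tid]
        els = set(path)
        els.update(
            (a, b) for a, b in zip(path, path[1:]) if (a, b) in graph.splices
        )
        return els

    f_inc = f_exc = 0.0
    for tid, frac in mixture.items():
        els = path_elements(tid)
        if set(event.include_elements) <= els:
            f_inc += frac
        elif set(event.exclude_elements) <= els:
            f_exc += frac
    if f_inc + f_exc == 0:
        raise ValueError(f"no isoform supports event {event.event_id}")
    return f_inc / (f_inc + f_exc)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _isoform_map(t: TranscriptModel) -> List[Tuple[int, Interval]]:
    """(isoform offset, genomic exon) pairs in transcription order."""
    exons = t.exons if t.strand == "+" else t.exons[::-1]
    out = []
    off = 0
    for s, e in exons:
        out.append((off, (s, e)))
        off += e - s
    return out


def _read_blocks(t: TranscriptModel, start: int, length: int) -> List[Interval]:
    """Genomic blocks of a read occupying isoform interval [start, start+length)."""
    blocks: List[Interval] = []
    for off, (s, e) in _isoform_map(t):
        u = max(start, off)
        v = min(start + length, off + (e - s))
        if u >= v:
            continue
        if t.strand == "+":
            blocks.append((s + (u - off), s + (v - off)))
        else:
            blocks.append((e - (v - off), e - (u - off)))
    return sorted(blocks)


def _sam_record(qname: str, chrom: str, blocks: Sequence[Interval]) -> str:
    cigar = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cigar.append(f"{s - blocks[i - 1][1]}N")
        cigar.append(f"{e - s}M")
    length = sum(e - s for s, e in blocks)
    return "\t".join(
        [
            qname, "0", chrom, str(blocks[0][0] + 1), "60", "".join(cigar),
            "*", "0", "0", "A" * length, "I" * length,
        ]
    )


def sam_text(chrom: str, chrom_length: int, records: Iterable[str]) -> str:
    """Assemble a coordinate-sorted SAM file from body records."""
    body = sorted(records, key=lambda r: (int(r.split("\t")[3]), r.split("\t")[0]))
    header = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{chrom}\tLN:{chrom_length}",
    ]
    return "\n".join(header + body) + "\n"


def _chrom_length(fixture: FixtureGene) -> int:
    return max(e for t in fixture.transcripts for _, e in t.exons) + 10_000


def simulate_reads(
    fixture: FixtureGene,
    seed: int,
    sample_id: str = "S1",
    depth: Optional[float] = None,
) -> SimulatedSample:
    """Sample error-free reads from the isoform mixture.

    Read starts are uniform along each isoform; the per-isoform read
    count is deterministic, ``round(fraction * depth * n_start_positions
    / n_junction_positions)``, so a splice at mixture fraction *f* is
    expected to collect about ``f * depth`` junction-spanning reads.
    The same seed reproduces byte-identical SAM text.
    """
    spec = fixture.spec
    depth = spec.depth if depth is None else depth
    rl, a = spec.read_length, spec.min_anchor
    jw = rl - 2 * a + 1
    rng = np.random.default_rng(seed)

    part_counts = {p.part_id: 0 for p in fixture.graph.parts}
    splice_counts = {k: 0 for k in fixture.graph.splices}
    intron_index = fixture.graph.intron_index
    records: List[str] = []
    reads_per_isoform: Dict[str, int] = {}

    for t in sorted(fixture.transcripts, key=lambda t: t.transcript_id):
        frac = fixture.spec.mixture().get(t.transcript_id, 0.0)
        length = sum(e - s for s, e in t.exons)
        n_pos = length - rl + 1
        if n_pos <= 0:
            raise ValueError(f"isoform {t.transcript_id} shorter than a read")
        n = int(round(frac * depth * n_pos / jw))
        reads_per_isoform[t.transcript_id] = n
        if n == 0:
            continue
        starts = np.sort(rng.integers(0, n_pos, size=n))

        # truth bookkeeping in isoform coordinates
        imap = _isoform_map(t)
        junctions = []  # (isoform coordinate, splice key) for real introns only
        for (off1, (s1, e1)), (off2, (s2, e2)) in zip(imap, imap[1:]):
            c = off2
            if t.strand == "+":
                intron = (e1, s2)
            else:
                intron = (e2, s1)
            key = intron_index.get(intron)
            if key is not None:
                junctions.append((c, key))
        footprints = []  # (iso_start, iso_end, part_id)
        for off, (s, e) in imap:
            for p in fixture.graph.parts:
                if s <= p.start and p.end <= e:
                    rel = (p.start - s) if t.strand == "+" else (e - p.end)
                    footprints.append((off + rel, off + rel + p.length_bases, p.part_id))

        for i, st in enumerate(starts):
            st = int(st)
            records.append(
                _sam_record(f"{t.transcript_id}:{i}", t.chrom,
                            _read_blocks(t, st, rl))
            )
            for c, key in junctions:
                if st <= c - a and st + rl >= c + a:
                    splice_counts[key] += 1
            for u, v, pid in footprints:
                if min(st + rl, v) - max(st, u) >= a:
                    part_counts[pid] += 1

    truth = TruthTable(
        part_counts=part_counts,
        splice_counts=splice_counts,
        reads_per_isoform=reads_per_isoform,
        total_reads=sum(reads_per_isoform.values()),
    )
    return SimulatedSample(
        sample_id=sample_id,
        sam=sam_text(spec.chrom, _chrom_length(fixture), records),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# novel junction planting
# ---------------------------------------------------------------------------

def plant_novel_junction(
    sam: str,
    graph: SpliceGraph,
    junction: Interval,
    n_reads: int = 5,
    read_length: int = 75,
    min_anchor: int = 4,
    qname_prefix: str = "novel",
) -> str:
    """Append split reads spanning an unannotated junction.

    Both junction boundaries must lie inside known exonic territory
    (novel exons must remain undiscoverable); otherwise a ``ValueError``
    is raised.  Returns re-sorted SAM text.
    """
    gs, ge = junction
    left = next((p for p in graph.parts if p.start < gs <= p.end), None)
    right = next((p for p in graph.parts if p.start <= ge < p.end), None)
    if left is None or right is None:
        raise ValueError(
            f"junction {gs}-{ge} has an endpoint outside exonic territory"
        )
    h1 = min(read_length // 2, gs - left.start)
    h2 = min(read_length - h1, right.end - ge)
    if h1 < min_anchor or h2 < min_anchor:
        raise ValueError("junction too close to a part edge for anchored reads")

    lines = sam.rstrip("\n").split("\n")
    header = [l for l in lines if l.startswith("@")]
    body = [l for l in lines if not l.startswith("@")]
    chrom = graph.chrom
    for i in range(n_reads):
        body.append(
            _sam_record(f"{qname_prefix}:{i}", chrom, [(gs - h1, gs), (ge, ge + h2)])
        )
    body = sorted(body, key=lambda r: (int(r.split("\t")[3]), r.split("\t")[0]))
    return "\n".join(header + body) + "\n"


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

def make_sample_sheet(
    groups: Mapping[str, Tuple[int, int]], prefix: str = "S"
) -> pd.DataFrame:
    """Sample sheet for a synthetic cohort: ``groups`` maps group label to
    (n_tumor, n_normal)."""
    rows = []
    i = 0
    for group, (nt, nn) in groups.items():
        for _ in range(nt):
            rows.append({"sample_id": f"{prefix}{i:03d}", "group": group,
                         "tissue_class": "tumor"})
            i += 1
        for _ in range(nn):
            rows.append({"sample_id": f"{prefix}{i:03d}", "group": group,
                         "tissue_class": "normal"})
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "group", "tissue_class"])


def simulate_cohort_matrix(
    n_events: int,
    sample_sheet: pd.DataFrame,
    seed: int,
    missing_rate: float = 0.03,
    noise_sd: float = 0.05,
    shifted_fraction: float = 0.3,
):
    """Directly synthesize an events × samples PSI matrix with known
    group structure: each event gets a true mean per group, a fraction of
    events a tumor−normal shift, samples get truncated-normal noise and
    random missing cells.  Returns (PsiMatrix, true group means frame)."""
    from .cohort import PsiMatrix, read_sample_sheet

    rng = np.random.default_rng(seed)
    sheet = read_sample_sheet(sample_sheet)
    groups = sorted(sheet["group"].unique())
    event_ids = [f"SYN{i:04d}_ES_{i % 7 + 2}" for i in range(n_events)]

    tumor_means = rng.uniform(0.05, 0.95, size=(n_events, len(groups)))
    shift = rng.uniform(-0.4, 0.4, size=(n_events, len(groups)))
    shift *= (rng.random((n_events, 1)) < shifted_fraction)
    normal_means = np.clip(tumor_means - shift, 0.0, 1.0)

    values = np.empty((n_events, len(sheet)))
    for j, sid in enumerate(sheet.index):
        gi = groups.index(sheet.loc[sid, "group"])
        mu = tumor_means[:, gi] if sheet.loc[sid, "tissue_class"] == "tumor" else normal_means[:, gi]
        values[:, j] = np.clip(mu + rng.normal(0.0, noise_sd, size=n_events), 0.0, 1.0)
    values[rng.random(values.shape) < missing_rate] = np.nan

    df = pd.DataFrame(values, index=event_ids, columns=sheet.index)
    events = pd.DataFrame(
        {
            "gene_symbol": [e.split("_")[0] for e in event_ids],
            "event_type": [EVENT_TYPES[i % 7] for i in range(n_events)],
            "exon_labels": [e.split("_")[2] for e in event_ids],
            "novel": False,
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    truth = pd.DataFrame(tumor_means, index=event_ids, columns=groups)
    return PsiMatrix(df, events, sheet), truth
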