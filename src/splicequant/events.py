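"""Enumeration of alternative-splicing events on a splice graph.

Seven event types are catalogued: exon skip (ES), alternate 5' donor
(AD), alternate 3' acceptor (AA), retained intron (RI), mutually
exclusive exons (ME), alternate first exon (AT) and alternate last exon
(AL).  Every event carries two disjoint element sets: *include* elements
(exon parts and splices whose reads evidence the presence of the
alternative transcript element) and *exclude* elements (reads that
evidence its absence).  All potential events are emitted whether or not
any sample expresses them; quantification is a separate concern.

Elements are either part labels (``"4"``, ``"6.2"``) or splice keys
(``("2", "4")``).  Detectors work purely in transcription order, so the
same code serves both strands; flipping the strand of a gene without
moving its coordinates swaps AD with AA and AT with AL.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple, Union

import networkx as nx

from .gene_model import SpliceGraph, SpliceKey

log = logging.getLogger(__name__)

Element = Union[str, SpliceKey]
EVENT_TYPES = ("ES", "AD", "AA", "RI", "ME", "AT", "AL")

#: Cap on simple-path enumeration depth; per-gene graphs are small.
_MAX_PATH_LEN = 40


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    gene_symbol: str
    event_type: str
    include_elements: FrozenSet[Element]
    exclude_elements: FrozenSet[Element]
    anchor_parts: Tuple[str, ...]
    exon_labels: str
    novel_splices: FrozenSet[SpliceKey] = frozenset()

    @property
    def novel(self) -> bool:
        return bool(self.novel_splices)

    def elements(self) -> Set[Element]:
        return set(self.include_elements) | set(self.exclude_elements)


def element_label(el: Element) -> str:
    return el if isinstance(el, str) else f"{el[0]}-{el[1]}"


def _splice_elements(els: Iterable[Element]) -> List[SpliceKey]:
    return [e for e in els if isinstance(e, tuple)]


def _transcript_edge_graph(graph: SpliceGraph) -> nx.DiGraph:
    """Edges actually traversed by transcript paths (annotated splices and
    read-through adjacencies); novel splices are deliberately absent so
    include-paths stay transcript-supported."""
    g = nx.DiGraph()
    g.add_nodes_from(p.part_id for p in graph.parts)
    for path in graph.transcript_paths.values():
        for a, b in zip(path, path[1:]):
            g.add_edge(a, b, splice=(a, b) in graph.splices)
    return g


def _sorted_splices(graph: SpliceGraph):
    order = graph.order
    return sorted(graph.splices.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]]))


# ---------------------------------------------------------------------------
# per-type detectors
# ---------------------------------------------------------------------------

def detect_exon_skip(graph: SpliceGraph) -> List[SpliceEvent]:
    """A splice A→C bridging over one or more whole exons: an alternate
    transcript path A→B…→C exists whose first and last steps are splices
    (paths that begin or end with a read-through adjacency belong to the
    AD/AA/RI detectors instead)."""
    pg = _transcript_edge_graph(graph)
    events = []
    for (a, c), _sp in _sorted_splices(graph):
        if a not in pg or c not in pg:
            continue
        h = pg.copy()
        if h.has_edge(a, c):
            h.remove_edge(a, c)
        include: Set[Element] = set()
        found = False
        for path in nx.all_simple_paths(h, a, c, cutoff=_MAX_PATH_LEN):
            steps = list(zip(path, path[1:]))
            if not pg.edges[steps[0][0], steps[0][1]]["splice"]:
                continue
            if not pg.edges[steps[-1][0], steps[-1][1]]["splice"]:
                continue
            found = True
            include.update(path[1:-1])
            include.update(s for s in steps if s in graph.splices)
        if not found:
            continue
        labels = sorted(
            {p for p in include if isinstance(p, str)}, key=graph.order.get
        )
        events.append(
            _make_event(graph, "ES", include, {(a, c)}, (a, c), ":".join(labels))
        )
    return events


def detect_alt_donor(graph: SpliceGraph) -> List[SpliceEvent]:
    return _detect_alt_side(graph, donor_side=True)


def detect_alt_acceptor(graph: SpliceGraph) -> List[SpliceEvent]:
    return _detect_alt_side(graph, donor_side=False)


def _detect_alt_side(graph: SpliceGraph, donor_side: bool) -> List[SpliceEvent]:
    """Shared AD/AA logic.  AD: ≥2 splices converge on one acceptor part
    from different sub-part boundaries of the same donor exon region.
    AA: the mirror image on the acceptor side.  With more than two
    alternatives, events are emitted pairwise against the longest
    (most-included) form."""
    order = graph.order
    groups: Dict[Tuple[str, int], List[SpliceKey]] = defaultdict(list)
    for (a, c) in graph.splices:
        if donor_side:
            groups[(c, graph.region_of(a))].append((a, c))
        else:
            groups[(a, graph.region_of(c))].append((a, c))

    events = []
    for (shared, region), keys in sorted(groups.items(), key=lambda kv: order[kv[0][0]]):
        if len(keys) < 2:
            continue
        region_parts = [p.part_id for p in graph.parts if graph.region_of(p.part_id) == region]
        if donor_side:
            # longest form = latest donor in transcription order
            keys = sorted(keys, key=lambda k: order[k[0]])
            long = keys[-1]
            shorts = keys[:-1]
        else:
            # longest form = earliest acceptor in transcription order
            keys = sorted(keys, key=lambda k: order[k[1]])
            long = keys[0]
            shorts = keys[1:]
        for short in shorts:
            if donor_side:
                ext = [
                    p for p in region_parts
                    if order[short[0]] < order[p] <= order[long[0]]
                ]
                anchors = (short[0], shared)
            else:
                ext = [
                    p for p in region_parts
                    if order[long[1]] <= order[p] < order[short[1]]
                ]
                anchors = (shared, short[1])
            include: Set[Element] = set(ext) | {long}
            exclude: Set[Element] = {short}
            labels = ":".join(sorted(ext, key=order.get))
            events.append(
                _make_event(graph, "AD" if donor_side else "AA",
                            include, exclude, anchors, labels)
            )
    return events


def detect_retained_intron(graph: SpliceGraph) -> List[SpliceEvent]:
    """A splice X→Y whose intron is exactly tiled by exon parts that are
    genomically contiguous with X and Y: some transcript reads straight
    through the intron."""
    events = []
    by_coord = sorted(graph.parts, key=lambda p: p.start)
    for (x, y), _sp in _sorted_splices(graph):
        gs, ge = graph.intron((x, y))
        mids = [p for p in by_coord if gs <= p.start and p.end <= ge]
        if not mids:
            continue
        tiles = all(
            a.end == b.start for a, b in zip(mids, mids[1:])
        ) and mids[0].start == gs and mids[-1].end == ge
        if not tiles:
            continue
        mid_ids = [p.part_id for p in mids]
        if graph.strand == "-":
            mid_ids = mid_ids[::-1]
        events.append(
            _make_event(graph, "RI", set(mid_ids), {(x, y)}, (x, y), ":".join(mid_ids))
        )
    return events


def detect_mutually_exclusive(graph: SpliceGraph) -> List[SpliceEvent]:
    """Two internal exon parts sharing a splice-predecessor and a
    splice-successor that never co-occur on any transcript path.
    Orientation: include = the transcription-order-first alternative."""
    order = graph.order
    preds: Dict[str, Set[str]] = defaultdict(set)
    succs: Dict[str, Set[str]] = defaultdict(set)
    for (a, b) in graph.splices:
        preds[b].add(a)
        succs[a].add(b)
    path_sets = [set(p) for p in graph.transcript_paths.values()]
    internal = sorted((p for p in preds if p in succs), key=order.get)

    events = []
    for b1, b2 in itertools.combinations(internal, 2):
        if graph.region_of(b1) == graph.region_of(b2):
            continue
        if (b1, b2) in graph.splices or (b2, b1) in graph.splices:
            continue
        if not (preds[b1] & preds[b2]) or not (succs[b1] & succs[b2]):
            continue
        if any(b1 in ps and b2 in ps for ps in path_sets):
            continue
        include: Set[Element] = {b1} | {
            k for k in graph.splices if b1 in k
        }
        exclude: Set[Element] = {b2} | {
            k for k in graph.splices if b2 in k
        }
        if include & exclude:
            continue
        anchors = (min(preds[b1] & preds[b2], key=order.get),
                   max(succs[b1] & succs[b2], key=order.get))
        events.append(
            _make_event(graph, "ME", include, exclude, anchors, f"{b1}|{b2}")
        )
    return events


def detect_alt_first(graph: SpliceGraph) -> List[SpliceEvent]:
    return _detect_alt_terminal(graph, first=True)


def detect_alt_last(graph: SpliceGraph) -> List[SpliceEvent]:
    return _detect_alt_terminal(graph, first=False)


def _detect_alt_terminal(graph: SpliceGraph, first: bool) -> List[SpliceEvent]:
    """AT/AL: ≥2 distinct first (last) exon regions across transcript
    paths, each joined to the gene body by a terminal splice.  One event
    is emitted per alternative so each gets its own PSI; its exclude set
    is the competing alternatives' terminal splices."""
    order = graph.order
    alts: Dict[int, Tuple[Set[str], Set[SpliceKey]]] = {}
    for path in graph.transcript_paths.values():
        walk = path if first else path[::-1]
        seg: List[str] = [walk[0]]
        terminal_splice = None
        for a, b in zip(walk, walk[1:]):
            key = (a, b) if first else (b, a)
            if key in graph.splices:
                terminal_splice = key
                break
            seg.append(b)
        if terminal_splice is None:
            continue  # single-exon transcript: no countable junction
        region = graph.region_of(seg[0])
        parts, spls = alts.setdefault(region, (set(), set()))
        parts.update(seg)
        spls.add(terminal_splice)
    if len(alts) < 2:
        return []

    events = []
    for region in sorted(alts):
        parts, spls = alts[region]
        exclude: Set[Element] = set().union(
            *(alts[r][1] for r in alts if r != region)
        )
        include: Set[Element] = set(parts) | set(spls)
        if include & exclude:
            log.warning(
                "%s: alternative terminal exon region %d shares splices with "
                "competitors; skipped", graph.gene_symbol, region,
            )
            continue
        label = min(parts, key=order.get)
        events.append(
            _make_event(graph, "AT" if first else "AL", include, exclude,
                        tuple(sorted(parts, key=order.get)), label)
        )
    return events


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _make_event(
    graph: SpliceGraph,
    etype: str,
    include: Set[Element],
    exclude: Set[Element],
    anchors: Tuple[str, ...],
    labels: str,
) -> SpliceEvent:
    novel = frozenset(
        k for k in _splice_elements(include) + _splice_elements(exclude)
        if graph.splices[k].novel
    )
    return SpliceEvent(
        event_id=f"{graph.gene_symbol}_{etype}_{labels}",
        gene_id=graph.gene_id,
        gene_symbol=graph.gene_symbol,
        event_type=etype,
        include_elements=frozenset(include),
        exclude_elements=frozenset(exclude),
        anchor_parts=anchors,
        exon_labels=labels,
        novel_splices=novel,
    )


def detect_events(graph: SpliceGraph) -> List[SpliceEvent]:
    """Run all seven detectors and return a deterministically ordered,
    uniquely identified catalog of potential events for one gene."""
    detectors = (
        detect_exon_skip,
        detect_alt_donor,
        detect_alt_acceptor,
        detect_retained_intron,
        detect_mutually_exclusive,
        detect_alt_first,
        detect_alt_last,
    )
    events: List[SpliceEvent] = []
    for det in detectors:
        events.extend(det(graph))

    order = graph.order
    events.sort(
        key=lambda e: (
            EVENT_TYPES.index(e.event_type),
            min((order[p] for p in e.anchor_parts if p in order), default=0),
            e.event_id,
        )
    )
    seen: Dict[str, int] = {}
    unique: List[SpliceEvent] = []
    for e in events:
        n = seen.get(e.event_id, 0)
        seen[e.event_id] = n + 1
        if n:
            e = SpliceEvent(
                event_id=f"{e.event_id}_{n + 1}",
                gene_id=e.gene_id,
                gene_symbol=e.gene_symbol,
                event_type=e.event_type,
                include_elements=e.include_elements,
                exclude_elements=e.exclude_elements,
                anchor_parts=e.anchor_parts,
                exon_labels=e.exon_labels,
                novel_splices=e.novel_splices,
            )
        unique.append(e)
    for e in unique:
        if not e.include_elements or not e.exclude_elements:
            raise AssertionError(f"{e.event_id}: empty evidence set")
        if set(e.include_elements) & set(e.exclude_elements):
            raise AssertionError(f"{e.event_id}: include/exclude overlap")
    return unique


def export_event_catalog(events: Iterable[SpliceEvent], path=None):
    """Tab-delimited catalog: one row per event with its element lists."""
    import pandas as pd

    rows = [
        {
            "gene_symbol": e.gene_symbol,
            "event_id": e.event_id,
            "event_type": e.event_type,
            "exon_labels": e.exon_labels,
            "include_elements": ",".join(sorted(map(element_label, e.include_elements))),
            "exclude_elements": ",".join(sorted(map(element_label, e.exclude_elements))),
            "novel": e.novel,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol", "event_id", "event_type", "exon_labels",
            "include_elements", "exclude_elements", "novel",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
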