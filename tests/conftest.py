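import pytest

import splicequant as sq

from helpers import mk_tx, sam_from_blocks


@pytest.fixture
def write_text(tmp_path):
    def _write(text, name):
        p = tmp_path / name
        p.write_text(text)
        return str(p)

    return _write


@pytest.fixture(scope="session")
def skip_graph():
    """Four-exon gene with a cassette third exon: the canonical exon-skip
    topology (inclusion path 1-2-3-4, skip splice 2->4)."""
    t1 = mk_tx("G1.t1", [(1000, 1150), (1300, 1450), (1600, 1750), (1900, 2050)])
    t2 = mk_tx("G1.t2", [(1000, 1150), (1300, 1450), (1900, 2050)])
    return sq.build_splice_graph([t1, t2])


@pytest.fixture(scope="session")
def skip_event(skip_graph):
    [es] = [e for e in sq.detect_events(skip_graph) if e.event_type == "ES"]
    return es


def figure_skip_sam(graph, anchor_left=40):
    """Reads realizing the worked exon-skip example: two reads per
    flanking junction (each also an exon-3 body read, so include evidence
    totals 8) and two reads on the skipping junction."""
    e2, e3, e4 = graph.part("2"), graph.part("3"), graph.part("4")
    right = 75 - anchor_left
    reads = []
    for i in range(2):
        reads.append((f"j23:{i}", [(e2.end - anchor_left, e2.end), (e3.start, e3.start + right)]))
        reads.append((f"j34:{i}", [(e3.end - anchor_left, e3.end), (e4.start, e4.start + right)]))
        reads.append((f"j24:{i}", [(e2.end - anchor_left, e2.end), (e4.start, e4.start + right)]))
    return sam_from_blocks(graph.chrom, reads)


@pytest.fixture(scope="session")
def all7_fixture():
    return sq.generate_gene_model(
        sq.FixtureSpec(events=("AT", "ES", "AD", "AA", "RI", "ME", "AL"))
    )
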