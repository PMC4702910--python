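"""Cohort assembly, novel-splice reporting filter, summaries, rankings,
download round trips."""

import math

import numpy as np
import pandas as pd
import pytest

import splicequant as sq
from splicequant.events import SpliceEvent
from splicequant.quantify import PsiValue, SampleCounts


def _event(eid, gene="G1", symbol="GENE", etype="ES", novel=frozenset()):
    return SpliceEvent(
        event_id=eid,
        gene_id=gene,
        gene_symbol=symbol,
        event_type=etype,
        include_elements=frozenset({"3", ("2", "3"), ("3", "4")}),
        exclude_elements=frozenset({("2", "4")}),
        anchor_parts=("2", "4"),
        exon_labels="3",
        novel_splices=frozenset(novel),
    )


def _sheet(samples):
    return pd.DataFrame(
        [{"sample_id": s, "group": g, "tissue_class": t} for s, g, t in samples],
        columns=["sample_id", "group", "tissue_class"],
    )


def _pv(eid, sid, psi, inc=10, exc=2):
    return PsiValue(eid, sid, psi, inc, exc)


class TestAssemble:
    def test_two_by_three_matrix(self):
        catalog = [_event("E1"), _event("E2", etype="RI")]
        sheet = _sheet([("s1", "A", "tumor"), ("s2", "A", "tumor"), ("s3", "B", "tumor")])
        psi = {
            "s1": [_pv("E1", "s1", 0.5), _pv("E2", "s1", 0.25)],
            "s2": [_pv("E1", "s2", 0.75)],  # E2 missing for s2
            "s3": [_pv("E1", "s3", None), _pv("E2", "s3", 1.0)],
        }
        m = sq.assemble_psi_matrix(psi, catalog, sheet)
        assert m.values.shape == (2, 3)
        assert m.values.loc["E1", "s1"] == 0.5
        assert math.isnan(m.values.loc["E2", "s2"])
        assert math.isnan(m.values.loc["E1", "s3"])  # below-coverage PSI is missing

    def test_unknown_sample_errors(self):
        catalog = [_event("E1")]
        sheet = _sheet([("s1", "A", "tumor")])
        with pytest.raises(KeyError, match="s2"):
            sq.assemble_psi_matrix({"s2": []}, catalog, sheet)

    def test_row_means_match_raw_recomputation(self):
        catalog = [_event("E1")]
        sheet = _sheet([(f"s{i}", "A", "tumor") for i in range(5)])
        raw = {f"s{i}": [_pv("E1", f"s{i}", (i + 1) / 10)] for i in range(5)}
        m = sq.assemble_psi_matrix(raw, catalog, sheet)
        oracle = sum((i + 1) / 10 for i in range(5)) / 5
        assert m.values.loc["E1"].mean() == pytest.approx(oracle, rel=1e-12)


class TestNovelEventFilter:
    def _cohort(self, n_samples, qualifying, share_hi=0.02, share_lo=0.002):
        """One annotated event and one novel-splice event; the novel splice
        reaches the qualifying share in `qualifying` of `n_samples`."""
        t1 = sq.TranscriptModel("T1", "G1", "GENE", "chrT", "+",
                                [(0, 100), (200, 300), (400, 500)], [(0, 100)])
        graph = sq.build_splice_graph([t1])
        graph.splices[("1", "3")] = sq.Splice("1", "3", 100, 400, novel=True)
        annotated = _event("GENE_ES_A")
        novel = SpliceEvent(
            event_id="GENE_ES_N", gene_id="G1", gene_symbol="GENE",
            event_type="ES",
            include_elements=frozenset({"2", ("1", "2"), ("2", "3")}),
            exclude_elements=frozenset({("1", "3")}),
            anchor_parts=("1", "3"), exon_labels="2",
            novel_splices=frozenset({("1", "3")}),
        )
        sheet = _sheet([(f"s{i}", "A", "tumor") for i in range(n_samples)])
        psi, counts = {}, {}
        for i in range(n_samples):
            sid = f"s{i}"
            share = share_hi if i < qualifying else share_lo
            total = 1000
            nov = int(round(share * total))
            sc = SampleCounts.zeros(sid, graph)
            sc.total_aligned_reads = 10_000
            sc.part_reads["2"] = total - nov
            sc.splice_reads[("1", "3")] = nov
            counts[sid] = {"G1": sc}
            psi[sid] = [
                _pv("GENE_ES_A", sid, 0.5),
                _pv("GENE_ES_N", sid, (total - nov) / total),
            ]
        matrix = sq.assemble_psi_matrix(psi, [annotated, novel], sheet)
        return matrix, [annotated, novel], counts

    def test_qualifying_in_ten_samples_retained(self):
        matrix, catalog, counts = self._cohort(12, qualifying=10)
        out = sq.apply_novel_event_filter(matrix, catalog, counts)
        assert set(out.values.index) == {"GENE_ES_A", "GENE_ES_N"}

    def test_qualifying_in_nine_samples_dropped(self):
        matrix, catalog, counts = self._cohort(12, qualifying=9)
        out = sq.apply_novel_event_filter(matrix, catalog, counts)
        assert set(out.values.index) == {"GENE_ES_A"}

    def test_fully_annotated_event_immune(self):
        matrix, catalog, counts = self._cohort(12, qualifying=0)
        out = sq.apply_novel_event_filter(matrix, catalog, counts)
        assert "GENE_ES_A" in set(out.values.index)

    def test_relaxing_thresholds_never_removes_passers(self):
        matrix, catalog, counts = self._cohort(12, qualifying=10)
        strict = set(
            sq.apply_novel_event_filter(
                matrix, catalog, counts, min_fraction=0.01, min_samples=10
            ).values.index
        )
        for mf, ms in [(0.005, 10), (0.01, 8), (0.001, 5)]:
            relaxed = set(
                sq.apply_novel_event_filter(
                    matrix, catalog, counts, min_fraction=mf, min_samples=ms
                ).values.index
            )
            assert strict <= relaxed


class TestSummaries:
    @pytest.fixture()
    def cohort(self):
        sheet = _sheet(
            [("t1", "A", "tumor"), ("t2", "A", "tumor"),
             ("t3", "B", "tumor"), ("t4", "B", "tumor"),
             ("n1", "A", "normal"), ("n2", "B", "normal")]
        )
        catalog = [_event("E1"), _event("E2", etype="RI")]
        psi = {
            "t1": [_pv("E1", "t1", 0.8)],
            "t2": [_pv("E1", "t2", 0.6), _pv("E2", "t2", 0.1)],
            "t3": [_pv("E1", "t3", 0.2), _pv("E2", "t3", 0.3)],
            "t4": [_pv("E1", "t4", 0.4)],
            "n1": [_pv("E1", "n1", 0.5)],
            "n2": [_pv("E1", "n2", 0.3), _pv("E2", "n2", 0.9)],
        }
        return sq.assemble_psi_matrix(psi, catalog, sheet)

    def test_group_means_and_deltas(self, cohort):
        s = {x.event_id: x for x in sq.summarize_groups(cohort)}
        e1 = s["E1"]
        assert e1.group_means["A"] == pytest.approx(0.7)
        assert e1.group_means["B"] == pytest.approx(0.3)
        assert e1.group_n == {"A": 2, "B": 2}
        assert e1.tumor_normal_delta["A"] == pytest.approx(0.7 - 0.5)
        assert e1.tumor_normal_delta["B"] == pytest.approx(0.3 - 0.3)
        oracle_var = np.var([0.7, 0.3])
        assert e1.variance == pytest.approx(oracle_var, rel=1e-12)

    def test_all_missing_group_absent_from_means(self, cohort):
        s = {x.event_id: x for x in sq.summarize_groups(cohort)}
        e2 = s["E2"]
        assert e2.group_means["A"] == pytest.approx(0.1)  # single value
        assert e2.normal_means == {"B": 0.9}
        assert "A" not in e2.normal_means

    def test_summary_frame_shape(self, cohort):
        df = sq.summary_frame(sq.summarize_groups(cohort))
        assert set(df.index) == {"E1", "E2"}
        assert "mean_A" in df.columns and "delta_B" in df.columns


class TestRankings:
    def test_wide_spread_outranks_narrow(self):
        sheet = _sheet(
            [("a", "A", "tumor"), ("b", "B", "tumor")]
        )
        catalog = [_event("WIDE"), _event("NARROW", etype="RI"), _event("FLAT", etype="ME")]
        psi = {
            "a": [_pv("WIDE", "a", 0.1), _pv("NARROW", "a", 0.4), _pv("FLAT", "a", 0.5)],
            "b": [_pv("WIDE", "b", 0.9), _pv("NARROW", "b", 0.6), _pv("FLAT", "b", 0.5)],
        }
        m = sq.assemble_psi_matrix(psi, catalog, sheet)
        ranked = sq.rank_tissue_difference(sq.summarize_groups(m), ["A", "B"])
        assert list(ranked["event_id"]) == ["WIDE", "NARROW", "FLAT"]
        assert ranked["variance"].iloc[-1] == pytest.approx(0.0)

    def test_fewer_than_two_groups_error(self):
        with pytest.raises(ValueError):
            sq.rank_tissue_difference([], ["A"])

    def test_ranking_matches_brute_force_on_synthetic_cohort(self):
        sheet = sq.make_sample_sheet({"A": (15, 5), "B": (15, 5), "C": (15, 5)})
        matrix, _truth = sq.simulate_cohort_matrix(50, sheet, seed=42)
        assert matrix.values.shape == (50, 60)
        summaries = sq.summarize_groups(matrix)
        ranked = sq.rank_tissue_difference(summaries, ["A", "B", "C"])

        # brute-force oracle straight from the matrix, two-pass variance
        meta = matrix.samples
        scores = {}
        for eid in matrix.values.index:
            means = []
            for grp in ("A", "B", "C"):
                cells = [
                    matrix.values.loc[eid, sid]
                    for sid in meta.index
                    if meta.loc[sid, "group"] == grp
                    and meta.loc[sid, "tissue_class"] == "tumor"
                    and not math.isnan(matrix.values.loc[eid, sid])
                ]
                if cells:
                    means.append(sum(cells) / len(cells))
            if len(means) >= 2:
                mu = sum(means) / len(means)
                scores[eid] = sum((x - mu) ** 2 for x in means) / len(means)
            else:
                scores[eid] = None
        expected = sorted(
            scores, key=lambda e: (-(scores[e] if scores[e] is not None else -1), e)
        )
        assert list(ranked["event_id"]) == expected
        for eid in matrix.values.index:
            got = ranked.set_index("event_id").loc[eid, "variance"]
            if scores[eid] is None:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(scores[eid], rel=1e-12)

    def test_tumor_normal_shift_ordering_and_oracle(self):
        sheet = sq.make_sample_sheet({"A": (10, 6), "B": (10, 6)})
        matrix, _ = sq.simulate_cohort_matrix(30, sheet, seed=9, shifted_fraction=0.5)
        summaries = sq.summarize_groups(matrix)
        ranked = sq.rank_tumor_normal(summaries, ["A", "B"])
        scores = {
            s.event_id: max(
                (abs(d) for g, d in s.tumor_normal_delta.items() if g in ("A", "B")),
                default=None,
            )
            for s in summaries
        }
        expected = sorted(
            scores, key=lambda e: (-(scores[e] if scores[e] is not None else -1), e)
        )
        assert list(ranked["event_id"]) == expected

    def test_identical_strata_score_zero(self):
        sheet = _sheet([("t", "A", "tumor"), ("n", "A", "normal")])
        catalog = [_event("E1")]
        psi = {"t": [_pv("E1", "t", 0.4)], "n": [_pv("E1", "n", 0.4)]}
        m = sq.assemble_psi_matrix(psi, catalog, sheet)
        ranked = sq.rank_tumor_normal(sq.summarize_groups(m), ["A"])
        assert ranked["shift"].iloc[0] == pytest.approx(0.0)

    def test_no_normals_error(self):
        sheet = _sheet([("t", "A", "tumor")])
        catalog = [_event("E1")]
        m = sq.assemble_psi_matrix({"t": [_pv("E1", "t", 0.4)]}, catalog, sheet)
        with pytest.raises(ValueError, match="normal"):
            sq.rank_tumor_normal(sq.summarize_groups(m), ["A"])


class TestDownloadExport:
    @pytest.fixture()
    def matrix(self):
        sheet = sq.make_sample_sheet({"A": (4, 2), "B": (4, 2)})
        m, _ = sq.simulate_cohort_matrix(21, sheet, seed=5)
        return m

    def test_event_type_and_group_filters(self, matrix):
        df = sq.export_psi_download(matrix, event_type="ME", groups=["A"])
        assert set(matrix.events.loc[df.index, "event_type"]) == {"ME"}
        assert all(c.startswith("A:") for c in df.columns[3:])
        # tumor and adjacent normal samples of the group are both present
        assert any(":normal:" in c for c in df.columns[3:])

    def test_gene_filter_unknown_symbol_suggests(self, matrix):
        with pytest.raises(KeyError, match="SYN0003"):
            sq.export_psi_download(matrix, gene="SYN003")

    def test_round_trip_is_lossless(self, tmp_path, matrix):
        path = tmp_path / "download.tsv"
        sq.export_psi_download(matrix, path)
        back = sq.import_psi_download(path)
        assert back.values.index.equals(matrix.values.index)
        assert list(back.values.columns) == list(matrix.values.columns)
        pd.testing.assert_frame_equal(
            back.values, matrix.values, check_exact=True, check_names=False
        )
        pd.testing.assert_frame_equal(back.samples, matrix.samples, check_names=False)

    def test_no_filter_returns_whole_matrix(self, matrix):
        df = sq.export_psi_download(matrix)
        assert df.shape == (matrix.n_events, 3 + matrix.n_samples)
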