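"""Cohort-level assembly, filtering, summarization and export of PSI.

The central object is the :class:`PsiMatrix`: an events × samples table
of PSI values (missing where coverage was insufficient) with event
metadata (gene, type, exon labels) and sample metadata (group label and
tumor/normal tissue class).  On top of it sit the cohort-wide
novel-splice reporting filter, per-group summaries, two rankings
(cross-group variance and tumor-normal shift) and the tab-delimited
download format.
"""

from __future__ import annotations

import difflib
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import EVENT_TYPES, SpliceEvent
from .quantify import PsiValue, SampleCounts, _sum_elements

log = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "tissue_class")
TISSUE_CLASSES = ("tumor", "normal")


@dataclass
class PsiMatrix:
    """Events × samples PSI values plus event and sample metadata."""

    values: pd.DataFrame   # index event_id, columns sample_id, float with NaN
    events: pd.DataFrame   # index event_id: gene_symbol, event_type, exon_labels, novel
    samples: pd.DataFrame  # index sample_id: group, tissue_class

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.events.index):
            raise ValueError("event metadata does not match matrix rows")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample metadata does not match matrix columns")
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(((v < 0) | (v > 1)) & ~np.isnan(v)):
                raise ValueError("PSI values must lie in [0, 1]")

    def subset_events(self, event_ids: Sequence[str]) -> "PsiMatrix":
        idx = [e for e in self.values.index if e in set(event_ids)]
        return PsiMatrix(
            self.values.loc[idx], self.events.loc[idx], self.samples.copy()
        )

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupSummary:
    """Per-event cohort summary: unweighted group means over non-missing
    tumor samples, matching adjacent-normal means, tumor−normal deltas
    and the cross-group variance of tumor means."""

    event_id: str
    group_means: Dict[str, float]
    group_n: Dict[str, int]
    normal_means: Dict[str, float]
    normal_n: Dict[str, int]
    tumor_normal_delta: Dict[str, float]
    variance: float


def read_sample_sheet(source) -> pd.DataFrame:
    """Read the tab-delimited sample sheet (sample_id, group,
    tissue_class ∈ {tumor, normal}); returns a frame indexed by sample."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(df["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValueError(f"unknown tissue_class values: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return df.set_index("sample_id")[["group", "tissue_class"]]


def assemble_psi_matrix(
    psi_by_sample: Mapping[str, Iterable[PsiValue]],
    catalog: Sequence[SpliceEvent],
    sample_sheet,
) -> PsiMatrix:
    """Build the events × samples matrix from per-sample PSI results.

    Every catalogued event gets a row; samples without a reported PSI for
    an event carry a missing cell.  A sample absent from the sheet is an
    error (group assignment is mandatory).
    """
    sheet = read_sample_sheet(sample_sheet)
    unknown = [s for s in psi_by_sample if s not in sheet.index]
    if unknown:
        raise KeyError(f"samples missing from sample sheet: {unknown}")

    event_ids = [e.event_id for e in catalog]
    sample_ids = list(psi_by_sample)
    values = pd.DataFrame(np.nan, index=event_ids, columns=sample_ids, dtype=float)
    for sid, psis in psi_by_sample.items():
        for p in psis:
            if p.event_id in values.index and p.psi is not None:
                values.loc[p.event_id, sid] = p.psi
    events = pd.DataFrame(
        {
            "gene_symbol": [e.gene_symbol for e in catalog],
            "event_type": [e.event_type for e in catalog],
            "exon_labels": [e.exon_labels for e in catalog],
            "novel": [e.novel for e in catalog],
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    return PsiMatrix(values, events, sheet.loc[sample_ids])


def apply_novel_event_filter(
    matrix: PsiMatrix,
    catalog: Sequence[SpliceEvent],
    counts_by_sample: Mapping[str, Mapping[str, SampleCounts]],
    min_fraction: float = 0.01,
    min_samples: int = 10,
) -> PsiMatrix:
    """Cohort-level reporting rule for events that contain a novel splice.

    Such an event is kept only when, in at least ``min_samples`` samples,
    each of its novel splices carries at least ``min_fraction`` of the
    event's total covering reads; events built purely from annotated
    splices pass unconditionally.
    """
    by_id = {e.event_id: e for e in catalog}
    keep: List[str] = []
    for eid in matrix.values.index:
        event = by_id[eid]
        if not event.novel_splices:
            keep.append(eid)
            continue
        qualifying = 0
        for sid in matrix.values.columns:
            gene_counts = counts_by_sample.get(sid, {})
            sc = gene_counts.get(event.gene_id)
            if sc is None:
                continue
            total = _sum_elements(sc, event.include_elements, normalized=False)
            total += _sum_elements(sc, event.exclude_elements, normalized=False)
            if total <= 0:
                continue
            if all(
                sc.splice_reads.get(ns, 0) / total >= min_fraction
                for ns in event.novel_splices
            ):
                qualifying += 1
        if qualifying >= min_samples:
            keep.append(eid)
        else:
            log.info(
                "event %s dropped: novel splice expressed at >=%.2g share in "
                "only %d/%d samples", eid, min_fraction, qualifying, min_samples,
            )
    return matrix.subset_events(keep)


def summarize_groups(matrix: PsiMatrix) -> List[GroupSummary]:
    """Per-group mean PSI over non-missing samples, split by tumor/normal
    tissue class, with tumor−normal deltas and cross-group variance of
    tumor means (population variance; missing when <2 groups have data)."""
    meta = matrix.samples

    def _strata(tissue: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
        cols = meta.index[meta["tissue_class"] == tissue]
        sub = matrix.values[cols]
        groups = meta.loc[cols, "group"]
        means = sub.T.groupby(groups).mean().T
        ns = sub.notna().T.groupby(groups).sum().T.astype(int)
        return means, ns

    t_means, t_n = _strata("tumor")
    n_means, n_n = _strata("normal")

    out: List[GroupSummary] = []
    for eid in matrix.values.index:
        gm = {} if t_means.empty else t_means.loc[eid].dropna().to_dict()
        gn = {} if t_n.empty else t_n.loc[eid].to_dict()
        nm = {} if n_means.empty else n_means.loc[eid].dropna().to_dict()
        nn = {} if n_n.empty else n_n.loc[eid].to_dict()
        delta = {g: gm[g] - nm[g] for g in gm if g in nm}
        vals = np.array(list(gm.values()), dtype=float)
        variance = float(np.var(vals)) if len(vals) >= 2 else math.nan
        out.append(
            GroupSummary(
                event_id=eid,
                group_means=gm,
                group_n=gn,
                normal_means=nm,
                normal_n=nn,
                tumor_normal_delta=delta,
                variance=variance,
            )
        )
    return out


def summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Flat view of group summaries (one row per event)."""
    groups = sorted({g for s in summaries for g in s.group_means})
    rows = []
    for s in summaries:
        row: Dict[str, object] = {"event_id": s.event_id, "variance": s.variance}
        for g in groups:
            row[f"mean_{g}"] = s.group_means.get(g, math.nan)
            row[f"n_{g}"] = s.group_n.get(g, 0)
            row[f"normal_mean_{g}"] = s.normal_means.get(g, math.nan)
            row[f"delta_{g}"] = s.tumor_normal_delta.get(g, math.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("event_id")


def rank_tissue_difference(
    summaries: Sequence[GroupSummary], selected_groups: Sequence[str]
) -> pd.DataFrame:
    """Events ordered by descending variance of group-mean PSI across the
    selected groups; ties broken by event_id.  Events with fewer than two
    informative groups sort last."""
    selected = list(dict.fromkeys(selected_groups))
    if len(selected) < 2:
        raise ValueError("tissue-difference ranking needs >=2 selected groups")
    rows = []
    for s in summaries:
        means = [s.group_means[g] for g in selected if g in s.group_means]
        var = float(np.var(means)) if len(means) >= 2 else math.nan
        rows.append({"event_id": s.event_id, "variance": var})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["variance", "event_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def rank_tumor_normal(
    summaries: Sequence[GroupSummary],
    selected_groups: Sequence[str],
    method: str = "max",
) -> pd.DataFrame:
    """Events ordered by tumor−normal shift across the selected groups.

    The shift score aggregates |mean tumor PSI − mean normal PSI| over
    groups having both strata: ``max`` (default) or ``mean``.  Groups
    without adjacent normals contribute nothing; if no selected group has
    normals at all, that is an error.
    """
    if method not in ("max", "mean"):
        raise ValueError(f"unknown shift aggregation: {method!r}")
    selected = list(dict.fromkeys(selected_groups))
    if not any(
        g in s.tumor_normal_delta for s in summaries for g in selected
    ):
        raise ValueError("no selected group has adjacent-normal samples")
    agg = {"max": max, "mean": lambda xs: sum(xs) / len(xs)}[method]
    rows = []
    for s in summaries:
        deltas = [abs(s.tumor_normal_delta[g]) for g in selected if g in s.tumor_normal_delta]
        rows.append(
            {"event_id": s.event_id, "shift": float(agg(deltas)) if deltas else math.nan}
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["shift", "event_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# download format
# ---------------------------------------------------------------------------

_META_COLUMNS = ["gene_symbol", "event_type", "exon_labels"]


def export_psi_download(
    matrix: PsiMatrix,
    path=None,
    gene: Optional[str] = None,
    event_type: Optional[str] = None,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Write the tab-delimited PSI download: rows are events matching the
    gene/event-type filters, columns are the selected groups' samples
    (tumor and adjacent normal) headed ``group:tissue_class:sample_id``,
    cells are PSI or NA."""
    ev = matrix.events
    if gene is not None:
        known = sorted(set(ev["gene_symbol"]))
        if gene not in known:
            near = difflib.get_close_matches(gene, known, n=3)
            raise KeyError(
                f"unknown gene symbol {gene!r}"
                + (f"; did you mean {near}?" if near else "")
            )
        ev = ev[ev["gene_symbol"] == gene]
    if event_type is not None:
        if event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event_type!r}")
        ev = ev[ev["event_type"] == event_type]
    samples = matrix.samples
    if groups is not None:
        samples = samples[samples["group"].isin(set(groups))]

    body = matrix.values.loc[ev.index, samples.index].copy()
    body.columns = [
        f"{samples.loc[s, 'group']}:{samples.loc[s, 'tissue_class']}:{s}"
        for s in body.columns
    ]
    out = pd.concat([ev[_META_COLUMNS], body], axis=1)
    out.index.name = "event_id"
    if path is not None:
        # 17 significant digits keep the float64 -> text -> float64 round
        # trip exact
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    return out


def import_psi_download(path) -> PsiMatrix:
    """Read a download file back into a PsiMatrix (inverse of
    :func:`export_psi_download`; novel flags are not preserved)."""
    df = pd.read_csv(path, sep="\t", index_col="event_id", float_precision="round_trip")
    meta = df[_META_COLUMNS].copy()
    meta["novel"] = False
    body = df.drop(columns=_META_COLUMNS)
    records = []
    sample_ids = []
    for col in body.columns:
        group, tissue, sid = col.split(":", 2)
        records.append({"group": group, "tissue_class": tissue})
        sample_ids.append(sid)
    samples = pd.DataFrame(records, index=pd.Index(sample_ids, name="sample_id"))
    body.columns = sample_ids
    return PsiMatrix(body.astype(float), meta, samples)
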