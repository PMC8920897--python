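"""Haplotype-specific separation of long reads via marker overlap rules.

Each read's alignment records against the grouped contigs are reduced to
per-marker overlaps: a marker qualifies if at least 500 bp of the read align
to it, the marker with the largest overlap wins, a haplotig marker sends the
read to its group, and a collapsed (multi-haplotype) marker sends it to one
of its k groups uniformly at random.  Randomization is derived per read from
a stable hash so assignment of any single read is reproducible in isolation
and independent of input order.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import GroupingResult

__all__ = ["UNASSIGNED", "DEFAULT_MIN_OVERLAP_BP", "assign_read", "bin_reads"]

UNASSIGNED = -1
AMBIGUOUS = -2
DEFAULT_MIN_OVERLAP_BP = 500


@dataclass(frozen=True)
class MarkerIndex:
    """Per-contig marker intervals with group lists, for overlap lookup."""

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    marker_ids: dict[str, list[str]]
    groups: dict[str, list[list[int]]]

    @classmethod
    def build(cls, markers: pd.DataFrame, grouping: GroupingResult) -> "MarkerIndex":
        starts, ends, mids, grps = {}, {}, {}, {}
        for cid, grp in markers.groupby("contig_id", sort=True):
            grp = grp.sort_values("start")
            starts[cid] = grp["start"].to_numpy()
            ends[cid] = grp["end"].to_numpy()
            mids[cid] = list(grp["marker_id"])
            glist = grouping.group_of_contig.get(cid, [])
            grps[cid] = [list(glist)] * len(grp)
        return cls(starts, ends, mids, grps)


def _read_rng(read_id: str, seed: int) -> random.Random:
    digest = hashlib.blake2b(read_id.encode(), digest_size=8).digest()
    return random.Random(int.from_bytes(digest, "big") ^ seed)


def assign_read(records: pd.DataFrame, index: MarkerIndex, seed: int = 0,
                min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
                randomize_multicopy: bool = True
                ) -> tuple[int, str | None, float]:
    """Assign one read from its alignment records.

    Returns ``(group_id, winning_marker_id, overlap_bp)``; group_id is
    UNASSIGNED when no marker reaches the overlap floor (or the winner is
    ungrouped) and AMBIGUOUS when the winner is multi-copy but randomization
    is disabled.  Overlaps of split alignments to the same marker accumulate
    before thresholding; aligned_bp is spread evenly over each record's span.
    """
    overlaps: dict[tuple[str, int], float] = {}
    for rec in records.itertuples():
        cid = rec.contig_id
        if cid not in index.starts:
            raise ValueError(f"alignment references unknown contig {cid}")
        s, e, aln = rec.contig_start, rec.contig_end, rec.aligned_bp
        span = e - s
        if span <= 0 or aln <= 0:
            continue
        frac = min(aln / span, 1.0)
        ov = np.minimum(index.ends[cid], e) - np.maximum(index.starts[cid], s)
        for j in np.nonzero(ov > 0)[0]:
            key = (cid, int(j))
            overlaps[key] = overlaps.get(key, 0.0) + float(ov[j]) * frac
    qualifying = {k: v for k, v in overlaps.items() if v >= min_overlap_bp}
    if not qualifying:
        return UNASSIGNED, None, 0.0
    # largest overlap wins; ties break toward the earlier (contig, start)
    win = min(qualifying,
              key=lambda k: (-qualifying[k], k[0], index.starts[k[0]][k[1]]))
    cid, j = win
    marker_id = index.marker_ids[cid][j]
    groups = index.groups[cid][j]
    overlap = qualifying[win]
    if len(groups) == 0:
        return UNASSIGNED, marker_id, overlap
    if len(groups) == 1:
        return groups[0], marker_id, overlap
    if not randomize_multicopy:
        return AMBIGUOUS, marker_id, overlap
    read_id = str(records["read_id"].iat[0])
    choice = _read_rng(read_id, seed).randrange(len(groups))
    return sorted(groups)[choice], marker_id, overlap


def bin_reads(records: pd.DataFrame, markers: pd.DataFrame,
              grouping: GroupingResult, seed: int = 0,
              min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
              randomize_multicopy: bool = True,
              deny_contigs: set[str] | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin every read; returns (assignments, per-group summary).

    ``records`` is the PAF-like table (read_id, contig_id, contig_start,
    contig_end, aligned_bp).  ``deny_contigs`` drops records on excluded
    contigs (e.g. organellar) before assignment.  Counts conserve: assigned +
    unassigned (+ ambiguous) = number of distinct reads.
    """
    if deny_contigs:
        records = records[~records["contig_id"].isin(deny_contigs)]
    index = MarkerIndex.build(markers, grouping)
    rows = []
    if len(records):
        for read_id, grp in records.groupby("read_id", sort=True):
            g, marker, ov = assign_read(grp, index, seed, min_overlap_bp,
                                        randomize_multicopy)
            rows.append((read_id, g, marker if marker else "", round(ov, 1)))
    table = pd.DataFrame(rows, columns=["read_id", "group_id", "winning_marker",
                                        "overlap_bp"])
    if len(table):
        summary = (table.groupby("group_id").size().rename("n_reads")
                   .reset_index())
        n_total = len(table)
        n_assigned = int((table["group_id"] >= 0).sum())
        summary.attrs["assigned_fraction"] = n_assigned / n_total
    else:
        summary = pd.DataFrame(columns=["group_id", "n_reads"])
        summary.attrs["assigned_fraction"] = float("nan")
    return table, summary
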