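"""Copy-number classification of contig windows from somatic sequencing depth.

A contig assembled from an autopolyploid collapses wherever haplotypes are
(nearly) identical, so its somatic read depth is an integer multiple of the
per-haplotype depth H.  Windows are classified into copy classes 1..4
(haplotig, diplotig, triplotig, tetraplotig) by thresholding depth at
H*(i + 1/2), and same-class neighboring windows are merged into ~50-kb
"coverage markers", the genotyping unit for gamete presence/absence calls.
Windows beyond the tetraplotig bound are repetitive ("replotig") and carry no
linkage information.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simulate import chunk_length

__all__ = ["REP_CLASS", "class_bounds", "classify_windows", "merge_to_markers"]

#: sentinel copy class for repeat-like windows (depth beyond the 4-copy bound)
REP_CLASS = 5

DEFAULT_WINDOW_BP = 10_000
DEFAULT_MARKER_BP = 50_000


def round_half_up(x: float) -> int:
    """Round with ties away from zero (169.5 -> 170), unlike banker's rounding."""
    return int(math.floor(x + 0.5))


def class_bounds(H: float, n_classes: int = 4) -> list[int]:
    """Upper depth bounds of the copy classes: round_half_up(H * (i + 1/2)).

    Class i covers (bound_{i-1}, bound_i] with class 1 starting at depth 0;
    depths above the last bound are repeat-like (REP_CLASS).  For H = 113 this
    yields [170, 283, 396, 509].
    """
    if H <= 0:
        raise ValueError("per-haplotype depth H must be positive")
    return [round_half_up(H * (i + 0.5)) for i in range(1, n_classes + 1)]


def classify_windows(windows: pd.DataFrame, H: float,
                     n_classes: int = 4) -> pd.DataFrame:
    """Label each depth window with its copy class (1..4 or REP_CLASS).

    ``windows`` needs columns contig_id, start, end, depth.  Classification is
    a total function of depth: depths <= bound_1 are class 1 (including 0),
    depths > bound_4 are REP_CLASS.
    """
    if len(windows) == 0:
        raise ValueError("no depth windows given")
    depth = windows["depth"].to_numpy(dtype=float)
    if np.any(depth < 0):
        raise ValueError("negative window depth")
    bounds = class_bounds(H, n_classes)
    cls = 1 + np.searchsorted(bounds, depth, side="left")
    cls[cls > n_classes] = REP_CLASS
    out = windows.copy()
    out["copy_class"] = cls.astype(int)
    return out


def merge_to_markers(classified: pd.DataFrame,
                     marker_bp: int = DEFAULT_MARKER_BP,
                     window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Merge same-class neighboring windows into coverage markers.

    Maximal runs of adjacent equal-class windows along a contig are merged and
    cut into marker_bp pieces; a trailing remainder shorter than half a window
    is absorbed into the previous piece, larger remainders stand as their own
    (shorter) markers.  Windows must be sorted and non-overlapping per contig.
    """
    markers = []
    for contig_id, grp in classified.groupby("contig_id", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cls = grp["copy_class"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping or unsorted windows on {contig_id}")
        run_start = 0
        for i in range(1, len(grp) + 1):
            boundary = (
                i == len(grp)
                or cls[i] != cls[run_start]
                or starts[i] != ends[i - 1]  # gap breaks the run
            )
            if not boundary:
                continue
            s, e = int(starts[run_start]), int(ends[i - 1])
            for cs, ce in chunk_length(e - s, marker_bp, window_bp // 2):
                markers.append((contig_id, s + cs, s + ce, int(cls[run_start]),
                                ce - cs))
            run_start = i
    df = pd.DataFrame(markers,
                      columns=["contig_id", "start", "end", "copy_class", "W"])
    df.insert(0, "marker_id", [f"{r.contig_id}:{r.start}-{r.end}"
                               for r in df.itertuples()])
    return df
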