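"""Trio-style evaluation of phasing precision.

Sequence mode follows the parental k-mer logic: k-mers unique to one parent
(optionally coverage-filtered when parents are given as reads) are
intersected with each haplotype assembly; a haplotype is inherited from a
single parent, so it should carry k-mers of only one parental set.  Overall
precision = sum over haplotypes of max(count_A, count_B) divided by the sum
of count_A + count_B.

Counts mode applies the same max/total logic to parent-labeled diagnostic
markers, which is exact on simulated data where every marker's parent of
origin is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ParentKmerSets",
    "PhasingReport",
    "canonical_kmers",
    "extract_parent_kmers",
    "score_haplotype",
    "precision",
    "precision_from_labels",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

DEFAULT_K = 21
#: per-parent multiplicity windows used when parents are read sets
DEFAULT_COVERAGE_A = (6, 12)
DEFAULT_COVERAGE_B = (5, 11)


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        codes = codes[codes != 255]  # drop non-ACGT
    return codes


def canonical_kmers(seq: str, k: int = DEFAULT_K) -> np.ndarray:
    """All canonical (strand-collapsed) k-mers of a sequence as uint64 codes.

    A k-mer and its reverse complement map to the same code (the smaller of
    the two 2-bit packings), so scoring is orientation-invariant.  Requires
    k <= 32.
    """
    if not 0 < k <= 32:
        raise ValueError("k must be in 1..32")
    codes = _encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    comp = (3 - codes).astype(np.uint64)
    c64 = codes.astype(np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | c64[i:i + n]
        rev = (rev << np.uint64(2)) | comp[k - 1 - i:k - 1 - i + n]
    return np.minimum(fwd, rev)


def _kmer_multiset(seqs, k: int) -> tuple[np.ndarray, np.ndarray]:
    parts = [canonical_kmers(s, k) for s in seqs]
    allk = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    return np.unique(allk, return_counts=True)


@dataclass(frozen=True)
class ParentKmerSets:
    """Disjoint parent-specific canonical k-mer sets (sorted uint64 arrays)."""

    k: int
    set_a: np.ndarray
    set_b: np.ndarray


@dataclass
class PhasingReport:
    """Parent-specific k-mer (or marker) counts of one haplotype assembly."""

    haplotype: str
    count_a: int
    count_b: int

    @property
    def dominant(self) -> str:
        return "A" if self.count_a >= self.count_b else "B"


def extract_parent_kmers(seqs_a, seqs_b, k: int = DEFAULT_K,
                         coverage_a: tuple[int, int] | None = None,
                         coverage_b: tuple[int, int] | None = None
                         ) -> ParentKmerSets:
    """Canonical k-mers unique to each parent.

    ``seqs_a``/``seqs_b`` are iterables of sequence strings.  When a coverage
    window (lo, hi) is given — the read-input case — only k-mers whose
    multiplicity falls inside the window are eligible; for assembled/truth
    sequences pass None and every k-mer counts once.
    """
    ka, ca = _kmer_multiset(seqs_a, k)
    kb, cb = _kmer_multiset(seqs_b, k)
    if coverage_a is not None:
        lo, hi = coverage_a
        ka = ka[(ca >= lo) & (ca <= hi)]
    if coverage_b is not None:
        lo, hi = coverage_b
        kb = kb[(cb >= lo) & (cb <= hi)]
    only_a = np.setdiff1d(ka, kb, assume_unique=True)
    only_b = np.setdiff1d(kb, ka, assume_unique=True)
    return ParentKmerSets(k=k, set_a=only_a, set_b=only_b)


def score_haplotype(seqs, sets: ParentKmerSets, name: str = "") -> PhasingReport:
    """Count assembly k-mers present in each parent-specific set."""
    kmers = np.unique(np.concatenate(
        [canonical_kmers(s, sets.k) for s in seqs]
        or [np.empty(0, dtype=np.uint64)]))
    count_a = int(np.isin(kmers, sets.set_a, assume_unique=True).sum())
    count_b = int(np.isin(kmers, sets.set_b, assume_unique=True).sum())
    return PhasingReport(haplotype=name, count_a=count_a, count_b=count_b)


def precision(reports: list[PhasingReport]) -> float:
    """Overall phasing precision: sum of max(count_A, count_B) / sum of both.

    Haplotypes with no parent-specific hits are excluded (they carry no
    diagnostic signal); all-zero input is an error.
    """
    scored = [r for r in reports if r.count_a + r.count_b > 0]
    if not scored:
        raise ValueError("no haplotype carries parent-specific k-mers")
    correct = sum(max(r.count_a, r.count_b) for r in scored)
    total = sum(r.count_a + r.count_b for r in scored)
    return correct / total


def reports_frame(reports: list[PhasingReport]) -> pd.DataFrame:
    df = pd.DataFrame({
        "haplotype": [r.haplotype for r in reports],
        "count_A": [r.count_a for r in reports],
        "count_B": [r.count_b for r in reports],
        "dominant": [r.dominant for r in reports],
    })
    df.attrs["precision"] = precision(reports)
    return df


def precision_from_labels(assignments: pd.DataFrame) -> tuple[list[PhasingReport], float]:
    """Counts-mode precision from parent-labeled marker assignments.

    ``assignments`` needs columns group_id and parent (values 'A'/'B'),
    one row per marker-to-group assignment; markers whose parent of origin is
    ambiguous (collapsed across parents) must be excluded upstream.
    """
    reports = []
    for gid, grp in assignments.groupby("group_id", sort=True):
        reports.append(PhasingReport(
            haplotype=str(gid),
            count_a=int((grp["parent"] == "A").sum()),
            count_b=int((grp["parent"] == "B").sum()),
        ))
    return reports, precision(reports)
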