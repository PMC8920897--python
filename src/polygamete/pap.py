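"""Presence/absence-pattern (PAP) genotyping of coverage markers across gametes.

Each gamete's raw read count r at a marker of size W bp is normalized to
n_r = r * (1e4/W) * (1e6/N), where N is the gamete's total aligned reads; the
gamete's single-copy level m_r is the mean normalized count over its
"informative" markers (raw count > 7 * N/1e6).  The rounded ratio n_r/m_r is
the coverage genotype, clipped into the copy-class domain: {0,1} for
haplotig markers, {0,1,2} diplotig, {1,2} triplotig, {2} tetraplotig.  The
vector of genotypes of one marker across all gametes is its PAP — the linkage
signal everything downstream runs on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth import REP_CLASS

__all__ = [
    "normalize_count",
    "informative_threshold",
    "genotype_marker",
    "pap_correlation",
    "build_pap_matrix",
    "PAPMatrix",
    "CLASS_DOMAIN",
]

#: genotype value domain (lo, hi) per copy class
CLASS_DOMAIN = {1: (0, 1), 2: (0, 2), 3: (1, 2), 4: (2, 2)}

DEFAULT_MIN_INFORMATIVE = 50


def normalize_count(r: float, W: int, N: int) -> float:
    """n_r = r * (1e4 / W) * (1e6 / N); reads per 10 kb per million aligned."""
    if W <= 0 or N <= 0:
        raise ValueError("marker size W and library size N must be positive")
    if r < 0:
        raise ValueError("negative read count")
    return r * (1e4 / W) * (1e6 / N)


def informative_threshold(N: int) -> float:
    """Raw-count floor above which a marker informs a gamete's m_r: 7 * N/1e6."""
    return 7.0 * (N / 1e6)


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def genotype_marker(n_r: float, m_r: float, copy_class: int) -> int:
    """Round n_r/m_r half-up, then clip into the class genotype domain."""
    if m_r <= 0:
        raise ValueError("gamete has non-positive single-copy level m_r")
    lo, hi = CLASS_DOMAIN[copy_class]
    g = int(_round_half_up(n_r / m_r))
    return min(max(g, lo), hi)


def pap_correlation(x, y) -> float:
    """Pearson correlation of two PAPs; NaN if either has zero variance.

    Zero-variance PAPs (e.g. the constant '2...2' of tetraplotig markers)
    carry no linkage signal and are excluded from all thresholding.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("PAP length mismatch")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum()) * np.sqrt((dy * dy).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between PAP rows; NaN rows for zero variance."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


@dataclass
class PAPMatrix:
    """Genotype matrix (markers x gametes) plus marker metadata and normalizers."""

    markers: pd.DataFrame          # marker_id, contig_id, start, end, copy_class, W
    genotypes: np.ndarray          # int array, rows aligned with markers
    gamete_ids: list[str]
    normalizers: pd.DataFrame      # gamete_id, N, m_r, n_informative, usable
    dropped_gametes: list[str]

    def row(self, marker_id: str) -> np.ndarray:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        return self.genotypes[idx[0]]

    @property
    def zero_variance(self) -> np.ndarray:
        return self.genotypes.std(axis=1) == 0

    def to_frame(self) -> pd.DataFrame:
        df = self.markers[["marker_id", "copy_class"]].copy()
        geno = pd.DataFrame(self.genotypes, columns=self.gamete_ids,
                            index=df.index)
        return pd.concat([df, geno], axis=1)


def build_pap_matrix(counts: pd.DataFrame, markers: pd.DataFrame,
                     min_informative: int = DEFAULT_MIN_INFORMATIVE) -> PAPMatrix:
    """Genotype every marker in every gamete and assemble the PAP matrix.

    ``counts`` holds one row per marker (matching ``markers`` by marker_id)
    and one integer column per gamete; a missing alignment is a count of 0.
    Replotig markers are dropped (no defined genotype domain).  Gametes whose
    number of informative markers falls below ``min_informative`` cannot
    support a stable m_r estimate and are excluded panel-wide.
    """
    if list(counts["marker_id"]) != list(markers["marker_id"]):
        raise ValueError("counts rows do not match the marker table")
    gamete_ids = [c for c in counts.columns if c != "marker_id"]
    raw = counts[gamete_ids].to_numpy(dtype=float)
    if raw.shape[0] != len(markers):
        raise ValueError("counts/markers dimension mismatch")
    W = markers["W"].to_numpy(dtype=float)
    cls = markers["copy_class"].to_numpy()

    N = raw.sum(axis=0)
    if np.any(N <= 0):
        bad = [g for g, n in zip(gamete_ids, N) if n <= 0]
        raise ValueError(f"gametes with no aligned reads: {bad[:5]}")
    n_r = raw * (1e4 / W)[:, None] * (1e6 / N)[None, :]
    informative = raw > (7.0 * N / 1e6)[None, :]
    n_info = informative.sum(axis=0)
    with np.errstate(invalid="ignore"):
        m_r = np.where(n_info > 0,
                       (n_r * informative).sum(axis=0) / np.maximum(n_info, 1),
                       np.nan)
    usable = (n_info >= min_informative) & np.isfinite(m_r) & (m_r > 0)
    normalizers = pd.DataFrame({
        "gamete_id": gamete_ids,
        "N": N.astype(int),
        "m_r": m_r,
        "n_informative": n_info,
        "usable": usable,
    })
    kept = [g for g, u in zip(gamete_ids, usable) if u]
    dropped = [g for g, u in zip(gamete_ids, usable) if not u]
    if not kept:
        raise ValueError(
            f"every gamete fell below {min_informative} informative markers "
            f"(panel has only {raw.shape[0]} markers); lower min_informative")

    keep_markers = cls != REP_CLASS
    markers_kept = markers.loc[keep_markers].reset_index(drop=True)
    ratio = n_r[np.ix_(keep_markers, usable)] / m_r[usable][None, :]
    geno = _round_half_up(ratio).astype(np.int64)
    lo = np.array([CLASS_DOMAIN[c][0] for c in markers_kept["copy_class"]])
    hi = np.array([CLASS_DOMAIN[c][1] for c in markers_kept["copy_class"]])
    geno = np.clip(geno, lo[:, None], hi[:, None])
    return PAPMatrix(markers=markers_kept, genotypes=geno, gamete_ids=kept,
                     normalizers=normalizers, dropped_gametes=dropped)
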