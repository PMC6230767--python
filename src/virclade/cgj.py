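"""Composite generalized Jaccard (CGJ) similarity and distance.

The generalized Jaccard similarity of two non-negative vectors is
sum(min) / sum(max); the CGJ score of two genomes is the geometric mean of
the generalized Jaccard similarities of their PPHMM signatures and of their
GOM signatures, and the CGJ distance is 1 - CGJ (0 = identical signatures,
1 = no detectable relatedness).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import numpy as np
import pandas as pd

from virclade.genome_io import DatasetManifest
from virclade.signatures import SignatureTable


def generalized_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """sum(min(a, b)) / sum(max(a, b)) for non-negative vectors.

    Two all-zero vectors give 0: genomes with no detectable genes share no
    evidence of relatedness, so scoring them identical would spuriously
    cluster annotation failures.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("generalized Jaccard requires non-negative entries")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / denom)


def cgj_similarity(
    sig_a: tuple[np.ndarray, np.ndarray],
    sig_b: tuple[np.ndarray, np.ndarray],
    pphmm_weight: float = 0.5,
) -> float:
    """Weighted geometric mean of the PPHMM and GOM Jaccard similarities.

    Default weights are 0.5/0.5, the plain geometric mean
    sqrt(J_pphmm * J_gom). If the GOM block has zero columns the PPHMM
    Jaccard alone is returned.
    """
    if not 0.0 <= pphmm_weight <= 1.0:
        raise ValueError("pphmm_weight must be in [0, 1]")
    pphmm_a, gom_a = sig_a
    pphmm_b, gom_b = sig_b
    j_pphmm = generalized_jaccard(pphmm_a, pphmm_b)
    if len(gom_a) == 0:
        return j_pphmm
    j_gom = generalized_jaccard(gom_a, gom_b)
    return float(j_pphmm**pphmm_weight * j_gom ** (1.0 - pphmm_weight))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise CGJ distance matrix with zero diagonal."""

    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genome_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be zero")
        if v.min(initial=0.0) < 0 or v.max(initial=0.0) > 1:
            raise ValueError("distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.genome_ids), k=1)
        return self.values[iu]


def distance_matrix(table: SignatureTable, pphmm_weight: float = 0.5) -> DistanceMatrix:
    """Pairwise CGJ distances 1 - CGJ over every genome pair in a table."""
    n = len(table.genome_ids)
    if n == 0:
        raise ValueError("empty signature table")
    values = np.zeros((n, n))
    sigs = [(table.pphmm_block[i], table.gom_block[i]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - cgj_similarity(sigs[i], sigs[j], pphmm_weight)
            values[i, j] = values[j, i] = min(max(d, 0.0), 1.0)
    return DistanceMatrix(genome_ids=list(table.genome_ids), values=values)


BIN_WIDTH = 0.02


@dataclass
class DistanceDistribution:
    """Histogram of a distance stratum over 0.02-wide bins on [0, 1]."""

    stratum: str  # e.g. "within-family", "between-genus"
    bin_edges: np.ndarray
    counts: np.ndarray
    distances: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if self.distances.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
                "stratum": self.stratum,
            }
        )


def distance_distributions(
    D: DistanceMatrix, manifest: DatasetManifest, rank: str = "family"
) -> list[DistanceDistribution]:
    """Within- and between-rank CGJ distance histograms at 0.02 intervals.

    Pairs where either genome lacks a label at the requested rank are
    excluded. Returns the [within-<rank>, between-<rank>] pair of
    distributions; their counts sum to C(n_labeled, 2).
    """
    if rank not in ("family", "genus"):
        raise ValueError(f"rank must be 'family' or 'genus', got {rank!r}")
    labels = {
        g.genome_id: getattr(g.taxonomy, rank) for g in manifest.genomes
    }
    labeled = [g for g in D.genome_ids if labels.get(g)]
    if not labeled:
        raise ValueError(f"no genome carries a {rank} label")
    within, between = [], []
    for a, b in combinations(labeled, 2):
        d = D.get(a, b)
        (within if labels[a] == labels[b] else between).append(d)
    edges = np.round(np.arange(0.0, 1.0 + BIN_WIDTH / 2, BIN_WIDTH), 10)
    out = []
    for stratum, dists in ((f"within-{rank}", within), (f"between-{rank}", between)):
        arr = np.asarray(dists, dtype=float)
        counts, _ = np.histogram(arr, bins=edges)
        out.append(
            DistanceDistribution(
                stratum=stratum, bin_edges=edges, counts=counts, distances=arr
            )
        )
    return out
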