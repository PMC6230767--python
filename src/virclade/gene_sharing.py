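"""Shared-gene scoring between two virus groups by mutual information.

For each PPHMM feature, the dependence between a binary group membership
(group A vs group B) and the feature's presence (PPHMM score > 0) is
measured by the plug-in mutual information of the 2x2 empirical joint
distribution, in bits. Because small samples make the estimate noisy, the
statistic is the mean over repeated small subsamples (by default 100
replicates of two viruses per group), reported with its dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from virclade.signatures import SignatureTable


def mutual_information(
    labels: np.ndarray, scores: np.ndarray, presence_threshold: float = 0.0
) -> float:
    """Plug-in MI in bits between a binary grouping and score presence.

    Scores are binarized as presence (score > ``presence_threshold``); MI is
    computed from the 2x2 joint empirical distribution with 0*log0 = 0.
    Bounded by 1 bit for binary/binary variables.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size < 2:
        raise ValueError("labels and scores must be equal-length vectors (n >= 2)")
    uniq = np.unique(labels)
    if uniq.size > 2 or not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    x = labels.astype(int)
    y = (scores > presence_threshold).astype(int)
    n = x.size
    mi = 0.0
    for xv in (0, 1):
        px = np.mean(x == xv)
        for yv in (0, 1):
            pxy = np.mean((x == xv) & (y == yv))
            py = np.mean(y == yv)
            if pxy > 0:
                mi += pxy * math.log2(pxy / (px * py))
    return max(mi, 0.0)


def _binned_mi(labels: np.ndarray, scores: np.ndarray, n_bins: int) -> float:
    """Quantile-binned plug-in MI for continuous scores (config variant)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    qs = np.quantile(scores, np.linspace(0, 1, n_bins + 1)[1:-1])
    y = np.searchsorted(qs, scores, side="right")
    n = labels.size
    mi = 0.0
    for xv in np.unique(labels):
        for yv in np.unique(y):
            pxy = np.mean((labels == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * math.log2(
                    pxy / (np.mean(labels == xv) * np.mean(y == yv))
                )
    return max(mi, 0.0)


@dataclass
class MIResult:
    """Mean subsampled MI of one PPHMM feature against the grouping."""

    pphmm_id: str
    mean_mi: float  # bits
    sd: float
    n_estimates: int
    presence_a: int  # genomes in group A with the feature present
    presence_b: int
    replicates: np.ndarray | None = None


def mean_mi_subsampled(
    table: SignatureTable,
    group_a: list[str],
    group_b: list[str],
    per_group: int = 2,
    reps: int = 100,
    seed: int = 0,
    keep_replicates: bool = False,
    estimator: str = "presence",
    n_bins: int = 4,
) -> list[MIResult]:
    """Mean MI per PPHMM over repeated balanced subsamples of two groups.

    Per replicate, ``per_group`` genomes are drawn uniformly without
    replacement from each group; MI is computed on the 2*per_group pooled
    sample and averaged over ``reps`` replicates. PPHMMs scoring zero
    across every genome of both groups are excluded from the analysis.
    Reproducible given ``seed``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if per_group > min(len(group_a), len(group_b)):
        raise ValueError("per_group exceeds a group's size")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    idx = {g: i for i, g in enumerate(table.genome_ids)}
    rows_a = np.array([idx[g] for g in group_a])
    rows_b = np.array([idx[g] for g in group_b])
    scores_a = table.pphmm_block[rows_a]
    scores_b = table.pphmm_block[rows_b]
    present_any = (scores_a > 0).any(axis=0) | (scores_b > 0).any(axis=0)
    keep = np.where(present_any)[0]

    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.zeros(per_group, dtype=int), np.ones(per_group, dtype=int)])
    est = np.zeros((reps, keep.size))
    for r in range(reps):
        sa = rng.choice(len(group_a), size=per_group, replace=False)
        sb = rng.choice(len(group_b), size=per_group, replace=False)
        sub = np.vstack([scores_a[sa][:, keep], scores_b[sb][:, keep]])
        for c in range(keep.size):
            if estimator == "presence":
                est[r, c] = mutual_information(labels, sub[:, c])
            elif estimator == "binned":
                est[r, c] = _binned_mi(labels, sub[:, c], n_bins)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")

    results = []
    for c, j in enumerate(keep):
        results.append(
            MIResult(
                pphmm_id=table.pphmm_ids[j],
                mean_mi=float(est[:, c].mean()),
                sd=float(est[:, c].std(ddof=1)) if reps > 1 else 0.0,
                n_estimates=reps,
                presence_a=int((scores_a[:, j] > 0).sum()),
                presence_b=int((scores_b[:, j] > 0).sum()),
                replicates=est[:, c].copy() if keep_replicates else None,
            )
        )
    return results


def mi_report(results: list[MIResult]) -> pd.DataFrame:
    """Tabular MI report: one row per PPHMM, sorted by descending mean MI."""
    df = pd.DataFrame(
        {
            "pphmm_id": [r.pphmm_id for r in results],
            "mean_mi_bits": [r.mean_mi for r in results],
            "sd": [r.sd for r in results],
            "n_reps": [r.n_estimates for r in results],
            "presence_group_a": [r.presence_a for r in results],
            "presence_group_b": [r.presence_b for r in results],
        }
    )
    return df.sort_values(["mean_mi_bits", "pphmm_id"], ascending=[False, True]).reset_index(
        drop=True
    )
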