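"""Independent brute-force oracles used to validate the fast implementations.

Each function here is written from the textbook definition of the quantity,
deliberately avoiding the code paths (and vectorization tricks) of the
package itself, so agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

import math

import numpy as np

from virclade.homology import AMINO_ACIDS, PPHMM, TRANSITIONS

_T = {name: i for i, name in enumerate(TRANSITIONS)}
_AA = {a: i for i, a in enumerate(AMINO_ACIDS)}


def sw_score_dp(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Quadratic Smith-Waterman with affine gaps via explicit three-matrix DP.

    ``gap_open`` is charged for a gap's first residue, ``gap_extend`` for
    each further residue (matching the package's ScoringScheme semantics).
    """
    n, m = len(a), len(b)
    NEG = -math.inf
    H = np.zeros((n + 1, m + 1))  # best ending in match/mismatch or fresh start
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = sub[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_nw_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Needleman-Wunsch global score with affine gaps, explicit DP."""
    n, m = len(a), len(b)
    NEG = -math.inf
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        F[i][0] = -gap_open - (i - 1) * gap_extend
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = sub[a[i - 1], b[j - 1]]
                H[i][j] = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + s
            if j > 0 and i >= 0:
                cands = [H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend]
                if i == 0 and j == 1:
                    cands = [H[0][0] - gap_open]
                E[i][j] = max(E[i][j], *cands)
            if i > 0:
                cands = [H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend]
                F[i][j] = max(F[i][j], *cands)
    return max(H[n][m], E[n][m], F[n][m])


def jaccard_brute(a, b) -> float:
    """Generalized Jaccard by an explicit elementwise loop."""
    num = 0.0
    den = 0.0
    for x, y in zip(a, b):
        num += x if x < y else y
        den += x if x > y else y
    return num / den if den else 0.0


def dcor_naive(x, Y) -> float:
    """Distance correlation by literal elementwise double centering."""
    x = [float(v) for v in x]
    Y = [[float(v) for v in row] for row in np.atleast_2d(Y)]
    m = len(x)
    a = [[abs(x[j] - x[l]) for l in range(m)] for j in range(m)]
    b = [
        [
            math.sqrt(sum((Y[r][j] - Y[r][l]) ** 2 for r in range(len(Y))))
            for l in range(m)
        ]
        for j in range(m)
    ]

    def centered(d):
        row_means = [sum(row) / m for row in d]
        col_means = [sum(d[j][l] for j in range(m)) / m for l in range(m)]
        grand = sum(row_means) / m
        return [
            [d[j][l] - row_means[j] - col_means[l] + grand for l in range(m)]
            for j in range(m)
        ]

    A, B = centered(a), centered(b)
    dcov2 = sum(A[j][l] * B[j][l] for j in range(m) for l in range(m)) / m**2
    dvarx = sum(A[j][l] ** 2 for j in range(m) for l in range(m)) / m**2
    dvary = sum(B[j][l] ** 2 for j in range(m) for l in range(m)) / m**2
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return math.sqrt(max(dcov2 / math.sqrt(dvarx * dvary), 0.0))


def naive_upgma(ids, dmat):
    """Reference UPGMA returning the cophenetic matrix and merge heights.

    Re-derives every inter-cluster distance from the raw matrix (unweighted
    mean over all cross pairs), unlike the package's running-update form.
    Ties break on the lexicographically smallest (min-member, min-member)
    pair. Returns (cophenetic ndarray aligned to sorted(ids), list of merge
    heights, set of clades as frozensets).
    """
    ids = list(ids)
    pos = {g: i for i, g in enumerate(ids)}
    oidx = {g: k for k, g in enumerate(sorted(ids))}
    n = len(ids)
    clusters = [[g] for g in ids]
    coph = np.zeros((n, n))
    heights = []
    clades = set()

    def cdist(c1, c2):
        return float(np.mean([dmat[pos[a]][pos[b]] for a in c1 for b in c2]))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                key = (d, tuple(sorted((min(clusters[i]), min(clusters[j])))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _), i, j = best
        merged = clusters[i] + clusters[j]
        heights.append(d)
        clades.add(frozenset(merged))
        for a in clusters[i]:
            for b in clusters[j]:
                coph[oidx[a], oidx[b]] = coph[oidx[b], oidx[a]] = d
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return coph, heights, clades


def enumerate_forward_bits(seq: str, p: PPHMM) -> float:
    """Forward log-odds by exhaustive enumeration of all state paths.

    Walks the profile architecture (begin=M0, match/insert/delete, end
    after the last match position) recursively, multiplying transition
    probabilities and match emission odds along each path, and sums path
    contributions in probability space. Exponential; only for toy models.
    """
    L = p.n_match_states
    t = p.transitions
    em = p.match_emissions
    bg = p.background
    n = len(seq)
    total = 0.0

    def rec(state: str, k: int, i: int, prob: float) -> None:
        nonlocal total
        if prob == 0.0:
            return
        if state == "END":
            if i == n:
                total += prob
            return
        if state == "M":
            # transitions out of position k
            _step_from(k, i, prob, "M")
        elif state == "I":
            _step_from(k, i, prob, "I")
        else:  # D
            _step_from(k, i, prob, "D")

    def _step_from(k: int, i: int, prob: float, s: str) -> None:
        row = t[k]
        # -> M_{k+1} (or END when k == L)
        pm = row[_T[s + "M"]]
        if k == L:
            rec("END", L + 1, i, prob * pm)
        else:
            if i < n:
                a = _AA.get(seq[i])
                odds = em[k, a] / bg[a] if a is not None else 1.0
                rec("M", k + 1, i + 1, prob * pm * odds)
        # -> I_k (emits background; odds 1)
        if s in ("M", "I") and i < n:
            rec("I", k, i + 1, prob * row[_T[s + "I"]])
        # -> D_{k+1}
        if s in ("M", "D") and k < L:
            rec("D", k + 1, i, prob * row[_T[s + "D"]])

    rec("M", 0, 0, 1.0)
    return math.log2(total) if total > 0 else -math.inf


def plugin_mi_bits(labels, presence) -> float:
    """2x2 plug-in mutual information, written from the definition."""
    n = len(labels)
    mi = 0.0
    for xv in (0, 1):
        for yv in (0, 1):
            nxy = sum(1 for l, p in zip(labels, presence) if l == xv and p == yv)
            if nxy == 0:
                continue
            pxy = nxy / n
            px = sum(1 for l in labels if l == xv) / n
            py = sum(1 for p in presence if p == yv) / n
            mi += pxy * math.log2(pxy / (px * py))
    return mi
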