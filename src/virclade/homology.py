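"""Protein homology: all-vs-all similarity, gene-family clustering, and PPHMMs.

Pipeline stage one. Proteins pooled from all genomes are compared all-vs-all
by Smith-Waterman local alignment (bit scores on the classic gapped BLOSUM62
scale), clustered into putative gene families, aligned by the center-star
heuristic, and each cluster is turned into a protein profile hidden Markov
model (PPHMM). Genomes are then scanned against the PPHMM database with the
forward algorithm in log space to produce per-gene similarity scores and
locations.

The profile architecture is the standard match/insert/delete layout with no
I<->D transitions: begin, match states M1..ML, insert states I0..IL, delete
states D1..DL, end. Insert states emit the background distribution, so only
match emissions contribute to the log-odds score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from virclade.genome_io import AnnotatedGenome, DatasetManifest, GeneFeature

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Robinson & Robinson amino acid background frequencies, order AMINO_ACIDS.
BACKGROUND = np.array(
    [
        0.078047, 0.019246, 0.053640, 0.062949, 0.038556,
        0.073772, 0.021992, 0.051420, 0.057438, 0.090191,
        0.022425, 0.044873, 0.052028, 0.042644, 0.051295,
        0.071198, 0.058413, 0.064409, 0.013298, 0.032165,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: Transition slot order within each source position.
TRANSITIONS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
_T = {name: i for i, name in enumerate(TRANSITIONS)}


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring: substitution matrix plus affine gap costs.

    ``gap_open`` is the cost of the first residue of a gap and ``gap_extend``
    of each subsequent residue (both positive costs). ``lam``/``k`` are the
    Karlin-Altschul statistics used to convert raw scores to bits; the
    defaults are the classic gapped BLOSUM62 constants, chosen for scale
    consistency across the whole database rather than per-pair calibration.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def bits(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)


def _make_aligner(scoring: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = mode
    return aligner


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected protein-protein similarity edge (stored once)."""

    protein_a: str
    protein_b: str
    bit_score: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be non-negative")


@dataclass
class ProteinCluster:
    """A putative gene family: member proteins with genome bookkeeping."""

    cluster_id: str
    members: list[tuple[str, str]]  # (genome_id, feature_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")

    @property
    def n_member_viruses(self) -> int:
        return len({g for g, _ in self.members})

    @property
    def feature_ids(self) -> list[str]:
        return [f for _, f in self.members]


def pairwise_similarity(
    proteins: Sequence[GeneFeature],
    scoring: ScoringScheme | None = None,
    min_score: float = 20.0,
) -> list[SimilarityEdge]:
    """All-vs-all Smith-Waterman bit scores between proteins.

    Bit score = (lambda * S - ln K) / ln 2 where S is the raw local
    alignment score. Pairs scoring below ``min_score`` bits are omitted.
    The relation is symmetric; each unordered pair is reported once with
    ``protein_a < protein_b``.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    for p in proteins:
        if not p.translation:
            raise ValueError(f"empty sequence for {p.feature_id}")
    scoring = scoring or ScoringScheme()
    aligner = _make_aligner(scoring, "local")
    edges: list[SimilarityEdge] = []
    seqs = [p.translation for p in proteins]
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            raw = aligner.score(seqs[i], seqs[j])
            bits = scoring.bits(raw)
            if bits >= min_score:
                a, b = sorted((proteins[i].feature_id, proteins[j].feature_id))
                edges.append(SimilarityEdge(a, b, max(bits, 0.0)))
    return edges


def _connected_components(
    nodes: list[str], edges: Iterable[tuple[str, str]]
) -> list[list[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    return [sorted(c) for c in comps.values()]


def _mcl_components(
    nodes: list[str],
    weighted: list[tuple[str, str, float]],
    inflation: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[list[str]]:
    """Markov-cluster-style iteration (expansion then inflation) on the
    similarity graph; clusters read off attractor rows at convergence."""
    idx = {n: i for i, n in enumerate(sorted(nodes))}
    n = len(idx)
    m = np.zeros((n, n))
    for a, b, w in weighted:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    np.fill_diagonal(m, m.max(initial=1.0))
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        m[m < 1e-12] = 0.0
        if np.abs(m - prev).max() < tol:
            break
    names = sorted(nodes)
    attractors = np.where(np.diag(m) > 1e-6)[0]
    clusters: list[set[str]] = []
    for a in attractors:
        members = {names[j] for j in np.where(m[a] > 1e-6)[0]} | {names[a]}
        for c in clusters:
            if c & members:
                c |= members
                break
        else:
            clusters.append(set(members))
    assigned = set().union(*clusters) if clusters else set()
    clusters.extend({n_} for n_ in names if n_ not in assigned)
    return [sorted(c) for c in clusters]


def cluster_proteins(
    edges: Sequence[SimilarityEdge],
    proteins: Sequence[GeneFeature],
    method: str = "components",
    threshold: float = 30.0,
    inflation: float = 2.0,
) -> list[ProteinCluster]:
    """Partition proteins into putative gene families.

    ``components``: connected components of the similarity graph restricted
    to edges with bit score >= ``threshold``; deterministic and invariant to
    edge ordering. ``mcl_like``: Markov-cluster-style expansion/inflation on
    the thresholded weighted graph. Singleton proteins always form
    singleton clusters. Cluster ids are assigned in order of each cluster's
    lexicographically smallest member feature id.
    """
    genome_of = {p.feature_id: p.genome_id for p in proteins}
    nodes = sorted(genome_of)
    kept = [(e.protein_a, e.protein_b, e.bit_score) for e in edges if e.bit_score >= threshold]
    if method == "components":
        comps = _connected_components(nodes, [(a, b) for a, b, _ in kept])
    elif method == "mcl_like":
        comps = _mcl_components(nodes, kept, inflation)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    comps.sort(key=lambda c: c[0])
    width = max(4, len(str(len(comps))))
    return [
        ProteinCluster(
            cluster_id=f"PC{i + 1:0{width}d}",
            members=[(genome_of[f], f) for f in comp],
        )
        for i, comp in enumerate(comps)
    ]


def _merge_into_msa(
    master_center: str, rows: list[str], c_aln: str, m_aln: str
) -> tuple[str, list[str], str]:
    """Merge one pairwise (center, member) alignment into a center-anchored
    MSA, propagating any new center gaps into the existing rows."""
    i = j = 0
    new_master: list[str] = []
    ops: list[str] = []  # 'both', 'master_gap', 'new_gap'
    while i < len(master_center) or j < len(c_aln):
        in_master = i < len(master_center)
        in_new = j < len(c_aln)
        if in_master and master_center[i] == "-":
            ops.append("master_gap")
            new_master.append("-")
            i += 1
        elif in_new and c_aln[j] == "-":
            ops.append("new_gap")
            new_master.append("-")
            j += 1
        else:
            assert in_master and in_new and master_center[i] == c_aln[j]
            ops.append("both")
            new_master.append(master_center[i])
            i += 1
            j += 1
    new_rows = []
    for row in rows:
        out = []
        ri = 0
        for op in ops:
            if op == "new_gap":
                out.append("-")
            else:
                out.append(row[ri])
                ri += 1
        new_rows.append("".join(out))
    member_row = []
    mj = 0
    for op in ops:
        if op == "master_gap":
            member_row.append("-")
        else:
            member_row.append(m_aln[mj])
            mj += 1
    return "".join(new_master), new_rows, "".join(member_row)


def align_cluster(
    cluster: ProteinCluster,
    proteins: Sequence[GeneFeature],
    scoring: ScoringScheme | None = None,
) -> list[str]:
    """Center-star progressive multiple alignment of a cluster.

    The center is the member with the greatest summed pairwise bit score
    (ties to the smallest feature id); every other member is globally
    aligned to the center and merged. Rows are returned in sorted
    feature-id order; ungapping any row recovers the original sequence.
    """
    scoring = scoring or ScoringScheme()
    seq_of = {p.feature_id: p.translation for p in proteins}
    fids = sorted(cluster.feature_ids)
    missing = [f for f in fids if f not in seq_of]
    if missing:
        raise ValueError(f"cluster members missing from protein list: {missing}")
    if len(fids) == 1:
        return [seq_of[fids[0]]]

    local = _make_aligner(scoring, "local")
    sums = {f: 0.0 for f in fids}
    for i in range(len(fids)):
        for j in range(i + 1, len(fids)):
            s = scoring.bits(local.score(seq_of[fids[i]], seq_of[fids[j]]))
            sums[fids[i]] += s
            sums[fids[j]] += s
    center = min(fids, key=lambda f: (-sums[f], f))

    glob = _make_aligner(scoring, "global")
    master = seq_of[center]
    rows: list[str] = [master]
    row_ids = [center]
    for f in fids:
        if f == center:
            continue
        aln = glob.align(master.replace("-", ""), seq_of[f])[0]
        c_aln, m_aln = str(aln[0]), str(aln[1])
        master, rows, member_row = _merge_into_msa(master, rows, c_aln, m_aln)
        rows.append(member_row)
        row_ids.append(f)
    order = sorted(range(len(row_ids)), key=lambda k: row_ids[k])
    return [rows[k] for k in order]


@dataclass
class PPHMM:
    """A protein profile HMM built from one cluster's multiple alignment.

    ``match_emissions`` is (L, 20) over :data:`AMINO_ACIDS`;
    ``transitions`` is (L+1, 7) over :data:`TRANSITIONS`, row k holding the
    transitions out of position k (row 0 = begin; row L feeds the end
    state). All probability groups are pseudocounted and normalised.
    """

    pphmm_id: str
    n_match_states: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    member_virus_ids: list[str]
    member_feature_ids: list[str] = field(default_factory=list)

    def validate(self, atol: float = 1e-9) -> None:
        if self.n_match_states < 1:
            raise ValueError("need at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=atol):
            raise ValueError("match emission rows must sum to 1")
        if not math.isclose(float(self.insert_emissions.sum()), 1.0, abs_tol=atol):
            raise ValueError("insert emissions must sum to 1")
        t = self.transitions
        L = self.n_match_states
        if not np.allclose(t[:, [_T["MM"], _T["MI"], _T["MD"]]].sum(axis=1), 1.0, atol=atol):
            raise ValueError("M-state transition rows must sum to 1")
        if not np.allclose(t[:, [_T["IM"], _T["II"]]].sum(axis=1), 1.0, atol=atol):
            raise ValueError("I-state transition rows must sum to 1")
        if not np.allclose(t[1:L, [_T["DM"], _T["DD"]]].sum(axis=1), 1.0, atol=atol):
            raise ValueError("D-state transition rows must sum to 1")


@dataclass
class PPHMMDatabase:
    """Ordered PPHMM collection; the order fixes signature column order."""

    pphmms: list[PPHMM]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pphmm_id for p in self.pphmms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pphmm ids")

    @property
    def pphmm_ids(self) -> list[str]:
        return [p.pphmm_id for p in self.pphmms]

    def __len__(self) -> int:
        return len(self.pphmms)


def build_pphmm(
    msa: Sequence[str],
    cluster: ProteinCluster,
    alpha: float = 1.0,
    gap_threshold: float = 0.5,
    background: np.ndarray = BACKGROUND,
) -> PPHMM:
    """Estimate a profile HMM from a cluster's multiple alignment.

    Match states are the columns whose gap fraction is <= ``gap_threshold``.
    Match emissions are column counts plus background-weighted pseudocounts
    of total strength ``alpha``: P(a) = (count_a + alpha*q_a) / (n + alpha).
    Transitions are counted from each row's match/insert/delete state path
    with pseudocount 1 on every structurally allowed transition.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows have unequal lengths")
    cols = np.array([[c for c in row] for row in msa])
    gap_frac = (cols == "-").mean(axis=0)
    match_cols = np.where(gap_frac <= gap_threshold)[0]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no match columns (alignment too gappy)")

    emis = np.tile(alpha * background, (L, 1))
    for k, c in enumerate(match_cols):
        for ch in cols[:, c]:
            if ch != "-":
                emis[k, _AA_INDEX[ch]] += 1.0
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts: row k = out of position k (k=0 is begin)
    tcounts = np.zeros((L + 1, 7))
    is_match = np.zeros(width, dtype=bool)
    is_match[match_cols] = True
    col_pos = np.cumsum(is_match)  # match position after this column
    for row in msa:
        state, pos = "M", 0
        path = [("M", 0)]
        for c in range(width):
            if is_match[c]:
                path.append(("M" if row[c] != "-" else "D", col_pos[c]))
            elif row[c] != "-":
                path.append(("I", col_pos[c]))
        path.append(("M", L + 1))  # end
        for (s1, p1), (s2, p2) in zip(path, path[1:]):
            if s1 == "I" and s2 == "I" and p1 == p2:
                tcounts[p1, _T["II"]] += 1
            else:
                name = s1 + ("M" if s2 == "M" else s2)
                if s2 == "I":
                    tcounts[p1, _T[s1 + "I"]] += 1
                elif s2 == "D":
                    tcounts[p1, _T[s1 + "D"]] += 1
                else:
                    tcounts[p1, _T[s1 + "M"]] += 1

    trans = tcounts + 1.0  # pseudocount on every slot, invalid ones zeroed next
    trans[L, _T["MD"]] = 0.0  # no delete state past the last match
    trans[L, _T["DD"]] = 0.0
    trans[0, _T["DM"]] = 0.0  # no delete state at the begin position
    trans[0, _T["DD"]] = 0.0

    def _norm(slots: list[int]) -> None:
        s = trans[:, slots].sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        trans[:, slots] /= s

    _norm([_T["MM"], _T["MI"], _T["MD"]])
    _norm([_T["IM"], _T["II"]])
    _norm([_T["DM"], _T["DD"]])

    pphmm = PPHMM(
        pphmm_id=cluster.cluster_id,
        n_match_states=L,
        match_emissions=emis,
        insert_emissions=background.copy(),
        transitions=trans,
        background=background.copy(),
        member_virus_ids=sorted({g for g, _ in cluster.members}),
        member_feature_ids=sorted(f for _, f in cluster.members),
    )
    pphmm.validate()
    return pphmm


def filter_singletons(db: PPHMMDatabase, manifest: DatasetManifest) -> PPHMMDatabase:
    """Drop PPHMMs matching only one virus from a well-sampled family.

    A PPHMM whose member list holds a single virus is removed when that
    virus's family is represented by more than two viruses in the manifest;
    singletons from unclassified viruses or small families are retained, as
    are all multi-virus PPHMMs. Idempotent.
    """
    family_of = {g.genome_id: g.taxonomy.family for g in manifest.genomes}
    family_counts: dict[str, int] = {}
    for g in manifest.genomes:
        fam = g.taxonomy.family
        if fam:
            family_counts[fam] = family_counts.get(fam, 0) + 1
    kept = []
    for p in db.pphmms:
        if len(p.member_virus_ids) == 1:
            fam = family_of.get(p.member_virus_ids[0], "")
            if fam and family_counts.get(fam, 0) > 2:
                continue
        kept.append(p)
    return PPHMMDatabase(pphmms=kept, provenance=dict(db.provenance))


@dataclass(frozen=True)
class Hit:
    """Best-scoring match of one genome against one PPHMM."""

    genome_id: str
    pphmm_id: str
    score: float  # bits, > score floor
    midpoint: float  # fractional position in (0, 1] on the concatenated genome
    strand: str
    feature_id: str


def _logsumexp3(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Elementwise logsumexp of three arrays, tolerating all--inf entries."""
    mx = np.maximum(np.maximum(a, b), c)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    out = safe + np.log(np.exp(a - safe) + np.exp(b - safe) + np.exp(c - safe))
    return np.where(np.isfinite(mx), out, -np.inf)


def forward_bits_batch(sequences: Sequence[str], pphmm: PPHMM) -> np.ndarray:
    """Forward-algorithm log-odds scores (bits) of many proteins at once.

    Full forward in log space over the global profile architecture, run as
    one padded batch. The null model emits every residue from the
    background, and insert states emit the background too, so insert
    emissions cancel and only match emissions and transitions contribute.
    """
    if not sequences:
        return np.zeros(0)
    if any(not s for s in sequences):
        raise ValueError("empty sequence")
    L = pphmm.n_match_states
    t = np.log(np.where(pphmm.transitions > 0, pphmm.transitions, 1e-300))
    # column 20 = unknown residue, log-odds 0
    em = np.zeros((L, 21))
    em[:, :20] = np.log(pphmm.match_emissions) - np.log(pphmm.background)
    tMM, tMI, tMD = t[:, _T["MM"]], t[:, _T["MI"]], t[:, _T["MD"]]
    tIM, tII = t[:, _T["IM"]], t[:, _T["II"]]
    tDM, tDD = t[:, _T["DM"]], t[:, _T["DD"]]

    B = len(sequences)
    lengths = np.array([len(s) for s in sequences])
    max_len = int(lengths.max())
    codes = np.zeros((B, max_len), dtype=np.int64)
    for b, s in enumerate(sequences):
        codes[b, : len(s)] = [_AA_INDEX.get(ch, 20) for ch in s]

    NEG = -np.inf
    # cumulative delete-chain weights: C[k] = sum of tDD[1..k], C[0] = 0;
    # lets the delete recursion collapse to one logaddexp.accumulate scan
    C = np.concatenate([[0.0], np.cumsum(tDD[1 : L])])  # length L

    def delete_scan(m_mat: np.ndarray) -> np.ndarray:
        """D[:, k] = logsumexp_j<k (M[:, j] + tMD[j] + tDD[j+1..k-1])."""
        u = m_mat[:, :L] + (tMD[:L] - C)
        acc = np.logaddexp.accumulate(u, axis=1)
        out = np.full((B, L + 1), NEG)
        out[:, 1:] = C + acc
        return out

    # state matrices over k = 0..L (M0 = begin; D0 unused)
    M = np.full((B, L + 1), NEG)
    I = np.full((B, L + 1), NEG)
    M[:, 0] = 0.0
    D = delete_scan(M)
    scores = np.zeros(B)

    def terminate(done: np.ndarray) -> None:
        end = _logsumexp3(
            M[done, L] + tMM[L], I[done, L] + tIM[L], D[done, L] + tDM[L]
        )
        scores[done] = end / math.log(2.0)

    for i in range(max_len):
        eo = em[np.arange(L)[None, :], codes[:, i, None]]  # (B, L)
        newM = np.empty((B, L + 1))
        newM[:, 0] = NEG
        newM[:, 1:] = eo + _logsumexp3(
            M[:, :-1] + tMM[:-1], I[:, :-1] + tIM[:-1], D[:, :-1] + tDM[:-1]
        )
        newI = np.logaddexp(M + tMI, I + tII)
        newD = delete_scan(newM)
        active = lengths > i
        M = np.where(active[:, None], newM, M)
        I = np.where(active[:, None], newI, I)
        D = np.where(active[:, None], newD, D)
        done = lengths == i + 1
        if done.any():
            terminate(done)
    return scores


def forward_bits(sequence: str, pphmm: PPHMM) -> float:
    """Log-odds score (bits) of one protein against a PPHMM, null = background."""
    return float(forward_bits_batch([sequence], pphmm)[0])


def scan_genome(
    genome: AnnotatedGenome, db: PPHMMDatabase, score_floor: float = 0.0
) -> list[Hit]:
    """Scan a genome's proteins against every PPHMM; keep best hits.

    For each (genome, PPHMM) pair the best-scoring protein is retained as a
    Hit when its forward log-odds score exceeds ``score_floor`` bits. The
    hit midpoint is the CDS midpoint mapped into the concatenated-genome
    fractional coordinate system; the strand is copied from the feature.
    """
    if not len(db):
        raise ValueError("empty PPHMM database")
    hits: list[Hit] = []
    total = genome.total_length
    seqs = [f.translation for f in genome.features]
    for pphmm in db.pphmms:
        if not seqs:
            break
        all_scores = forward_bits_batch(seqs, pphmm)
        best_idx = int(np.argmax(all_scores))
        if all_scores[best_idx] > score_floor:
            s, feat = float(all_scores[best_idx]), genome.features[best_idx]
            mid = (genome.segment_offset(feat.segment_index) + (feat.start + feat.end) / 2.0) / total
            hits.append(
                Hit(
                    genome_id=genome.genome_id,
                    pphmm_id=pphmm.pphmm_id,
                    score=s,
                    midpoint=mid,
                    strand=feat.strand,
                    feature_id=feat.feature_id,
                )
            )
    return hits


def export_hmmer_ascii(db: PPHMMDatabase, path) -> None:
    """Write match emissions and transitions in a HMMER3-style ASCII layout.

    Interoperability export only (negative natural-log probabilities, one
    line per match state); not a byte-faithful HMMER save file.
    """
    with open(path, "w") as fh:
        for p in db.pphmms:
            fh.write(f"HMMER3/f [virclade export]\nNAME  {p.pphmm_id}\n")
            fh.write(f"LENG  {p.n_match_states}\nALPH  amino\nHMM\n")
            for k in range(p.n_match_states):
                row = " ".join(f"{-math.log(x):.5f}" for x in p.match_emissions[k])
                tr = " ".join(
                    f"{-math.log(x):.5f}" if x > 0 else "*"
                    for x in p.transitions[k + 1]
                )
                fh.write(f"  {k + 1} {row}\n      {tr}\n")
            fh.write("//\n")


def import_similarity_scores(path) -> list[SimilarityEdge]:
    """Read externally computed scores as 3-column TSV (id_a, id_b, bits)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, s = line.split("\t")
            a, b = sorted((a, b))
            edges.append(SimilarityEdge(a, b, float(s)))
    return edges
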