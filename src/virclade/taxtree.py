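"""UPGMA dendrograms, bootstrap supports, threshold collapse, assignment.

The dendrogram is a rooted ultrametric tree on the CGJ-distance scale:
an internal node's height is the average-linkage merge distance of its two
children, so collapsing the tree "at height 0.8" cuts on the same scale as
the 0.8 family-delimitation threshold. Clade support comes from
bootstrapping the signature table at the feature (PPHMM column) level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from virclade.cgj import DistanceMatrix, distance_matrix
from virclade.genome_io import DatasetManifest
from virclade.signatures import SignatureTable


@dataclass
class TreeNode:
    """A node of a rooted ultrametric dendrogram."""

    height: float
    name: str | None = None  # leaf label; None for internal nodes
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return [l for c in self.children for l in c.leaves()]

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Dendrogram:
    """Rooted binary ultrametric tree over genomes, heights = CGJ distances."""

    root: TreeNode

    @property
    def leaf_ids(self) -> list[str]:
        return sorted(self.root.leaves())

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes."""
        return [frozenset(n.leaves()) for n in self.internal_nodes()]

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (height of the lowest common ancestor)."""
        ids = self.leaf_ids
        idx = {g: i for i, g in enumerate(ids)}
        n = len(ids)
        values = np.zeros((n, n))
        for node in self.internal_nodes():
            child_leaf_sets = [c.leaves() for c in node.children]
            for a in range(len(child_leaf_sets)):
                for b in range(a + 1, len(child_leaf_sets)):
                    for la in child_leaf_sets[a]:
                        for lb in child_leaf_sets[b]:
                            i, j = idx[la], idx[lb]
                            values[i, j] = values[j, i] = node.height
        return DistanceMatrix(genome_ids=ids, values=values)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            blen = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.name}:{blen:.6f}"
            inner = ",".join(fmt(c, node.height) for c in _ordered_children(node))
            label = "" if node.support is None else f"{node.support:.0f}"
            return f"({inner}){label}:{blen:.6f}"

        if self.root.is_leaf:
            return f"{self.root.name}:0.0;"
        inner = ",".join(fmt(c, self.root.height) for c in _ordered_children(self.root))
        label = "" if self.root.support is None else f"{self.root.support:.0f}"
        return f"({inner}){label};"


def _ordered_children(node: TreeNode) -> list[TreeNode]:
    return sorted(node.children, key=lambda c: (c.height, min(c.leaves())))


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration of a CGJ distance matrix.

    Repeatedly merges the closest pair of clusters; the merged cluster's
    distance to every other is the size-weighted arithmetic mean; the new
    node's height is the merge distance. Ties are broken by the
    lexicographically smallest (min-member-id, min-member-id) pair, making
    the tree invariant to input ordering.
    """
    ids = list(D.genome_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two genomes")
    if not np.isfinite(D.values).all():
        raise ValueError("distance matrix contains non-finite values")

    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    min_id = {i: ids[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.values[i, j])

    next_id = n
    while len(clusters) > 1:
        best_key: tuple[int, int] | None = None
        best = (np.inf, ("", ""))
        for (i, j), d in dist.items():
            pair = tuple(sorted((min_id[i], min_id[j])))
            cand = (d, pair)
            if cand < best:
                best = cand
                best_key = (i, j)
        assert best_key is not None
        i, j = best_key
        d_merge = best[0]
        node = TreeNode(height=d_merge, children=[clusters[i], clusters[j]])
        si, sj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[(k, new) if k < new else (new, k)] = (si * dik + sj * djk) / (si + sj)
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del clusters[i], clusters[j]
        clusters[new] = node
        sizes[new] = si + sj
        min_id[new] = min(min_id[i], min_id[j])
    return Dendrogram(root=next(iter(clusters.values())))


def bootstrap_supports(
    table: SignatureTable,
    n_reps: int = 100,
    seed: int = 0,
    joint: bool = False,
    pphmm_weight: float = 0.5,
) -> Dendrogram:
    """UPGMA tree with clade supports from signature-table bootstrap.

    Each pseudoreplicate resamples the PPHMM columns with replacement
    (same count); the GOM columns derive from the same underlying gene set
    and are kept fixed unless ``joint`` is set, in which case they are
    resampled too. Distances and the UPGMA tree are recomputed per
    replicate and a clade's support is the percentage of replicate trees
    containing the same leaf set. Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(table.pphmm_ids) < 2:
        raise ValueError("need at least two PPHMM columns to bootstrap")
    tree = upgma(distance_matrix(table, pphmm_weight))
    clade_nodes = tree.internal_nodes()
    clade_sets = [frozenset(n.leaves()) for n in clade_nodes]
    counts = np.zeros(len(clade_nodes))
    rng = np.random.default_rng(seed)
    p = len(table.pphmm_ids)
    f = len(table.family_ids)
    for _ in range(n_reps):
        cols = rng.integers(0, p, size=p)
        rep = SignatureTable(
            genome_ids=list(table.genome_ids),
            pphmm_ids=[f"bs{i}" for i in range(p)],
            family_ids=list(table.family_ids),
            pphmm_block=table.pphmm_block[:, cols],
            gom_block=(
                table.gom_block[:, rng.integers(0, f, size=f)]
                if joint and f
                else table.gom_block
            ),
            location_profiles=table.location_profiles[:, cols],
        )
        rep_tree = upgma(distance_matrix(rep, pphmm_weight))
        rep_clades = set(frozenset(n.leaves()) for n in rep_tree.internal_nodes())
        for k, cs in enumerate(clade_sets):
            if cs in rep_clades:
                counts[k] += 1
    for node, c in zip(clade_nodes, counts):
        node.support = 100.0 * c / n_reps
    return tree


@dataclass
class ClusterPartition:
    """Threshold-collapsed dendrogram clusters with composition summaries."""

    threshold: float
    clusters: list[list[str]]  # sorted genome ids per cluster
    cluster_ids: list[str]
    composition: pd.DataFrame  # indexed by cluster_id

    def cluster_of(self, genome_id: str) -> str:
        for cid, members in zip(self.cluster_ids, self.clusters):
            if genome_id in members:
                return cid
        raise KeyError(genome_id)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_frame(self, manifest: DatasetManifest | None = None) -> pd.DataFrame:
        rows = []
        for cid, members in zip(self.cluster_ids, self.clusters):
            for g in members:
                row = {"cluster_id": cid, "genome_id": g}
                if manifest is not None:
                    genome = manifest.get(g)
                    row["classified"] = manifest.classified[g]
                    row["family"] = genome.taxonomy.family
                    row["host_group"] = genome.taxonomy.host_group
                rows.append(row)
        return pd.DataFrame(rows)


def collapse(
    tree: Dendrogram,
    threshold: float = 0.8,
    manifest: DatasetManifest | None = None,
) -> ClusterPartition:
    """Cut the dendrogram at a height threshold into clusters.

    Clusters are the maximal clades whose root height is strictly below the
    threshold; a leaf whose every ancestor merges at or above the threshold
    becomes a singleton. The default 0.8 corresponds to the CGJ distance
    that delimits family-equivalent groups.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")

    clusters: list[list[str]] = []

    def descend(node: TreeNode) -> None:
        if node.height < threshold or (node.is_leaf and node.height <= threshold):
            clusters.append(sorted(node.leaves()))
        else:
            if node.is_leaf:
                clusters.append([node.name])  # type: ignore[list-item]
                return
            for c in _ordered_children(node):
                descend(c)

    descend(tree.root)
    width = max(3, len(str(len(clusters))))
    cluster_ids = [f"CL{i + 1:0{width}d}" for i in range(len(clusters))]
    comp_rows = []
    for cid, members in zip(cluster_ids, clusters):
        row: dict = {"cluster_id": cid, "n_genomes": len(members)}
        if manifest is not None:
            fams = Counter(
                manifest.get(g).taxonomy.family
                for g in members
                if manifest.get(g).taxonomy.family
            )
            hosts = Counter(
                manifest.get(g).taxonomy.host_group
                for g in members
                if manifest.get(g).taxonomy.host_group
            )
            n_classified = sum(manifest.classified[g] for g in members)
            row.update(
                families=";".join(f"{k}:{v}" for k, v in sorted(fams.items())),
                host_groups=";".join(f"{k}:{v}" for k, v in sorted(hosts.items())),
                n_classified=n_classified,
                n_unclassified=len(members) - n_classified,
            )
        comp_rows.append(row)
    composition = pd.DataFrame(comp_rows).set_index("cluster_id")
    return ClusterPartition(
        threshold=threshold,
        clusters=clusters,
        cluster_ids=cluster_ids,
        composition=composition,
    )


def assign_unclassified(
    partition: ClusterPartition,
    manifest: DatasetManifest,
    table: SignatureTable | None = None,
) -> pd.DataFrame:
    """Report cluster assignment for every unclassified genome.

    Each unclassified genome is labeled with its cluster and that cluster's
    classified-family composition. Clusters containing only unclassified
    genomes are flagged as candidate unassigned taxonomic units (UTUs).
    Genomes whose PPHMM signature is all zero (no detectable similarity to
    any sequence in the classified dataset) are reported in a separate
    "no similarity" bucket.
    """
    rows = []
    for cid, members in zip(partition.cluster_ids, partition.clusters):
        classified = [g for g in members if manifest.classified[g]]
        unclassified = [g for g in members if not manifest.classified[g]]
        fams = Counter(
            manifest.get(g).taxonomy.family for g in classified
            if manifest.get(g).taxonomy.family
        )
        fam_str = ";".join(f"{k}:{v}" for k, v in sorted(fams.items()))
        is_utu = len(classified) == 0
        for g in unclassified:
            no_sim = False
            if table is not None:
                scores, _ = table.row(g)
                no_sim = bool((scores == 0).all())
            rows.append(
                {
                    "genome_id": g,
                    "cluster_id": cid,
                    "n_cluster_members": len(members),
                    "n_classified_in_cluster": len(classified),
                    "cluster_families": fam_str,
                    "is_utu": is_utu and not no_sim,
                    "no_similarity": no_sim,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "cluster_id",
            "n_cluster_members",
            "n_classified_in_cluster",
            "cluster_families",
            "is_utu",
            "no_similarity",
        ],
    )


def leaf_order_for_heatmap(tree: Dendrogram) -> list[str]:
    """Deterministic left-to-right leaf order for heat-map rows.

    Children are visited smaller-height first, ties by smallest leaf id, so
    the order is stable across reruns and matches the dendrogram layout.
    """
    order: list[str] = []

    def descend(node: TreeNode) -> None:
        if node.is_leaf:
            order.append(node.name)  # type: ignore[arg-type]
            return
        for c in _ordered_children(node):
            descend(c)

    descend(tree.root)
    return order
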