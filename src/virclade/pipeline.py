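"""End-to-end orchestration: build-db, annotate, relate, classify, mi.

Every stage is a pure function of (inputs, config): rerunning with the same
config and seeds reproduces outputs bit-identically. Baltimore groups are
analysed as separate datasets (one dendrogram per group); the config's
``baltimore_filter`` restricts the manifest accordingly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from virclade import __version__
from virclade.cgj import DistanceMatrix, distance_distributions, distance_matrix
from virclade.gene_sharing import mean_mi_subsampled, mi_report
from virclade.genome_io import (
    DatasetManifest,
    read_genbank,
    read_metadata,
    write_table,
)
from virclade.homology import (
    Hit,
    PPHMMDatabase,
    ScoringScheme,
    align_cluster,
    build_pphmm,
    cluster_proteins,
    filter_singletons,
    pairwise_similarity,
    scan_genome,
)
from virclade.signatures import (
    GOM,
    SignatureTable,
    build_goms,
    build_signature_table,
    location_profile,
)
from virclade.taxtree import (
    ClusterPartition,
    Dendrogram,
    assign_unclassified,
    bootstrap_supports,
    collapse,
    leaf_order_for_heatmap,
)

log = logging.getLogger("virclade")


@dataclass
class RunConfig:
    """All stage parameters with defaults; serializable to/from YAML."""

    genbank_paths: list[str] = field(default_factory=list)
    metadata_path: str | None = None
    out_dir: str = "virclade_run"
    baltimore_filter: str | None = None
    translation_table: int = 11
    # homology
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 20.0
    cluster_method: str = "components"
    cluster_threshold: float = 30.0
    mcl_inflation: float = 2.0
    # PPHMM construction / scanning
    alpha: float = 1.0
    gap_threshold: float = 0.5
    score_floor: float = 0.0
    # distances and trees
    pphmm_weight: float = 0.5
    collapse_threshold: float = 0.8
    bootstrap_reps: int = 100
    bootstrap_joint: bool = False
    # MI
    mi_reps: int = 100
    mi_per_group: int = 2
    seed: int = 0

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(
            matrix=self.matrix, gap_open=self.gap_open, gap_extend=self.gap_extend
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def load_manifest(config: RunConfig) -> DatasetManifest:
    """Read genomes and metadata; apply the Baltimore group filter."""
    if not config.genbank_paths:
        raise ValueError("config.genbank_paths is empty")
    manifest = read_genbank(config.genbank_paths, config.translation_table)
    if config.metadata_path:
        manifest = read_metadata(config.metadata_path, manifest)
    if config.baltimore_filter:
        keep = [
            g
            for g in manifest.genomes
            if not g.taxonomy.baltimore_group
            or g.taxonomy.baltimore_group == config.baltimore_filter
        ]
        if not keep:
            raise ValueError(
                f"Baltimore filter {config.baltimore_filter!r} excludes every genome"
            )
        manifest = DatasetManifest(
            genomes=keep,
            classified={g.genome_id: manifest.classified[g.genome_id] for g in keep},
        )
    return manifest


def run_build_db(
    config: RunConfig, manifest: DatasetManifest
) -> tuple[PPHMMDatabase, dict[str, GOM], dict[str, list[Hit]]]:
    """Cluster classified proteins, build PPHMMs, filter, and build GOMs.

    Returns the filtered PPHMM database, the per-family GOMs, and the
    cached classified-genome hits for reuse by the annotation stage.
    """
    classified = manifest.classified_genomes()
    if not classified:
        raise ValueError("no classified genomes: cannot build a reference database")
    proteins = [f for g in classified for f in g.features]
    if len(proteins) < 2:
        raise ValueError("need at least two classified proteins")
    log.info("pairwise similarity over %d proteins", len(proteins))
    edges = pairwise_similarity(proteins, config.scoring, config.min_score)
    clusters = cluster_proteins(
        edges,
        proteins,
        method=config.cluster_method,
        threshold=config.cluster_threshold,
        inflation=config.mcl_inflation,
    )
    log.info("%d clusters from %d edges", len(clusters), len(edges))
    pphmms = []
    for cl in clusters:
        msa = align_cluster(cl, proteins, config.scoring)
        pphmms.append(
            build_pphmm(msa, cl, alpha=config.alpha, gap_threshold=config.gap_threshold)
        )
    db = PPHMMDatabase(
        pphmms=pphmms,
        provenance={
            "version": __version__,
            "method": config.cluster_method,
            "cluster_threshold": config.cluster_threshold,
            "min_score": config.min_score,
            "n_proteins": len(proteins),
        },
    )
    db = filter_singletons(db, manifest)
    log.info("database holds %d PPHMMs after singleton filtering", len(db))
    hits_cache: dict[str, list[Hit]] = {}
    profiles = {}
    for g in classified:
        hits = scan_genome(g, db, config.score_floor)
        hits_cache[g.genome_id] = hits
        profiles[g.genome_id] = location_profile(hits, g, db.pphmm_ids)
    goms = build_goms(manifest, profiles)
    return db, goms, hits_cache


def run_annotate(
    config: RunConfig,
    manifest: DatasetManifest,
    db: PPHMMDatabase,
    goms: Mapping[str, GOM],
    hits_cache: Mapping[str, list[Hit]] | None = None,
) -> SignatureTable:
    """Annotate every genome with a PPHMM and a GOM signature."""
    hits_by_genome: dict[str, list[Hit]] = {}
    for g in manifest.genomes:
        if hits_cache is not None and g.genome_id in hits_cache:
            hits_by_genome[g.genome_id] = list(hits_cache[g.genome_id])
        else:
            hits_by_genome[g.genome_id] = scan_genome(g, db, config.score_floor)
    return build_signature_table(
        manifest, db, goms=goms, score_floor=config.score_floor,
        hits_by_genome=hits_by_genome,
    )


def run_relate(
    config: RunConfig, table: SignatureTable, manifest: DatasetManifest
) -> tuple[DistanceMatrix, Dendrogram, ClusterPartition]:
    """Distances, bootstrapped UPGMA dendrogram, threshold clusters."""
    D = distance_matrix(table, config.pphmm_weight)
    tree = bootstrap_supports(
        table,
        n_reps=config.bootstrap_reps,
        seed=config.seed,
        joint=config.bootstrap_joint,
        pphmm_weight=config.pphmm_weight,
    )
    partition = collapse(tree, config.collapse_threshold, manifest)
    return D, tree, partition


def run_classify(
    config: RunConfig,
    partition: ClusterPartition,
    manifest: DatasetManifest,
    table: SignatureTable,
) -> pd.DataFrame:
    """Assignment report for unclassified genomes (incl. UTU flags)."""
    return assign_unclassified(partition, manifest, table)


def run_mi(
    config: RunConfig,
    table: SignatureTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Subsampled mutual-information report for two genome groups."""
    results = mean_mi_subsampled(
        table,
        list(group_a),
        list(group_b),
        per_group=config.mi_per_group,
        reps=config.mi_reps,
        seed=config.seed,
    )
    return mi_report(results)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Returns the in-memory artifacts keyed by stage name; the run directory
    receives signatures, locations, distances, pairwise list, newick tree,
    cluster membership, assignment report, and a JSON run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(config)
    db, goms, hits_cache = run_build_db(config, manifest)
    table = run_annotate(config, manifest, db, goms, hits_cache)
    write_table(table.to_frame(), out / "signatures.tsv", "signatures")
    write_table(table.locations_frame(), out / "locations.tsv", "signatures")
    D, tree, partition = run_relate(config, table, manifest)
    write_table(D.to_frame(), out / "distances.tsv", "distances")
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    pairs = pair_list(D, manifest)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    try:
        strata = distance_distributions(D, manifest, rank="family")
        pd.concat([s.to_frame() for s in strata]).to_csv(
            out / "distance_distributions.tsv", sep="\t", index=False
        )
    except ValueError:
        pass  # no family labels in this dataset
    partition.to_frame(manifest).to_csv(out / "clusters.tsv", sep="\t", index=False)
    report = run_classify(config, partition, manifest, table)
    report.to_csv(out / "assignments.tsv", sep="\t", index=False)
    order = leaf_order_for_heatmap(tree)
    (out / "heatmap_order.txt").write_text("\n".join(order) + "\n")
    run_manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_genomes": len(manifest.genomes),
        "n_classified": sum(manifest.classified.values()),
        "n_pphmms": len(db),
        "n_families": len(goms),
        "n_clusters": partition.n_clusters,
    }
    (out / "run.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return {
        "manifest": manifest,
        "db": db,
        "goms": goms,
        "table": table,
        "distances": D,
        "tree": tree,
        "partition": partition,
        "assignments": report,
    }


def pair_list(D: DistanceMatrix, manifest: DatasetManifest) -> pd.DataFrame:
    """Long-format pair list: id_a, id_b, distance, same_family, same_genus."""
    fam = {g.genome_id: g.taxonomy.family for g in manifest.genomes}
    gen = {g.genome_id: g.taxonomy.genus for g in manifest.genomes}
    rows = []
    ids = D.genome_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "distance": D.values[i, j],
                    "same_family": bool(fam[a] and fam[a] == fam[b]),
                    "same_genus": bool(gen[a] and gen[a] == gen[b]),
                }
            )
    return pd.DataFrame(rows)
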