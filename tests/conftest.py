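"""Session-scoped datasets and pipeline runs shared across the suite.

The heavier simulated runs are computed once per session; tests must not
mutate the returned objects.
"""

from __future__ import annotations

import pytest

from virclade import pipeline
from virclade.synthetic_data import SimConfig, simulate, two_regime_benchmark


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Two cohesive families, three members each; small fast genomes."""
    out = tmp_path_factory.mktemp("tiny_sim")
    cfg = SimConfig(
        n_families=2,
        members_per_family=3,
        genes_per_family=3,
        gene_length_range=(40, 60),
        substitution_rate=0.1,
        seed=42,
    )
    manifest, truth = simulate(cfg, out_dir=out)
    return {"dir": out, "config": cfg, "manifest": manifest, "truth": truth}


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_run")
    cfg = pipeline.RunConfig(
        genbank_paths=[str(tiny_dataset["dir"] / "genomes.gbk")],
        metadata_path=str(tiny_dataset["dir"] / "metadata.tsv"),
        out_dir=str(out),
        bootstrap_reps=25,
        seed=7,
    )
    artifacts = pipeline.run_all(cfg)
    artifacts["run_config"] = cfg
    artifacts["truth"] = tiny_dataset["truth"]
    return artifacts


@pytest.fixture(scope="session")
def family_bench(tmp_path_factory):
    """Five families x six members at substitution rate 0.15, no mosaicism."""
    out = tmp_path_factory.mktemp("bench_sim")
    cfg = SimConfig(
        n_families=5,
        members_per_family=6,
        genes_per_family=8,
        substitution_rate=0.15,
        shared_gene_fraction=0.0,
        seed=2026,
    )
    manifest, truth = simulate(cfg, out_dir=out)
    run_out = tmp_path_factory.mktemp("bench_run")
    rcfg = pipeline.RunConfig(
        genbank_paths=[str(out / "genomes.gbk")],
        metadata_path=str(out / "metadata.tsv"),
        out_dir=str(run_out),
        bootstrap_reps=100,
        seed=2026,
    )
    artifacts = pipeline.run_all(rcfg)
    artifacts["truth"] = truth
    artifacts["run_config"] = rcfg
    return artifacts


@pytest.fixture(scope="session")
def two_regime(tmp_path_factory):
    """Cohesive vs heterogeneous family regimes; distances only (no bootstrap)."""
    out = tmp_path_factory.mktemp("two_regime")
    manifest, truth = two_regime_benchmark(seed=3, out_dir=out)
    cfg = pipeline.RunConfig(
        genbank_paths=[str(out / "genomes.gbk")],
        metadata_path=str(out / "metadata.tsv"),
        out_dir=str(out / "run"),
        seed=3,
    )
    loaded = pipeline.load_manifest(cfg)
    db, goms, hits = pipeline.run_build_db(cfg, loaded)
    table = pipeline.run_annotate(cfg, loaded, db, goms, hits)
    from virclade.cgj import distance_matrix

    D = distance_matrix(table)
    return {
        "manifest": loaded,
        "truth": truth,
        "table": table,
        "distances": D,
    }
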