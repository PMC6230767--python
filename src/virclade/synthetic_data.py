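"""Simulated annotated virus genomes with known family/genus structure.

The generator draws, per family, an ancestral set of ordered protein-coding
genes (random amino-acid sequences, random strands, random intergenic
spacers) and derives member genomes by residue substitution, whole-gene
loss and strand inversion. Genes are back-translated to nucleotide CDS and
emitted as valid GenBank flat files plus a metadata TSV, so every pipeline
stage can be exercised without downloads. A two-regime benchmark emulates
the contrast between cohesive ("eukaryote-like") families and heterogeneous
("phage-like") families whose genera share almost no genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from virclade.genome_io import (
    METADATA_COLUMNS,
    AnnotatedGenome,
    DatasetManifest,
    GeneFeature,
    Taxonomy,
)
from virclade.homology import AMINO_ACIDS

#: Most-frequent codon per amino acid under genetic code table 11.
CODON = {
    "A": "GCC", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    ``substitution_rate`` is the expected fraction of residues replaced per
    member relative to its ancestor; ``gene_loss_prob`` and
    ``inversion_prob`` apply per gene per member; ``shared_gene_fraction``
    moves that fraction of each family's genes into a pool common to all
    families (mosaicism). With ``genera_per_family`` > 1, members descend
    from genus-level ancestors; ``genus_private_genes`` gives every genus
    its own independent gene set (heterogeneous, phage-like families)
    instead of deriving genera from one family ancestor.
    """

    n_families: int = 5
    members_per_family: int = 6
    genes_per_family: int = 8
    gene_length_range: tuple[int, int] = (60, 120)
    substitution_rate: float = 0.15
    gene_loss_prob: float = 0.0
    inversion_prob: float = 0.0
    shared_gene_fraction: float = 0.0
    seed: int = 0
    genera_per_family: int = 1
    genus_private_genes: bool = False
    genus_substitution_rate: float | None = None  # None: use substitution_rate
    intergenic_range: tuple[int, int] = (20, 60)
    n_unclassified_families: int = 0

    def __post_init__(self) -> None:
        for p in (self.substitution_rate, self.gene_loss_prob, self.inversion_prob,
                  self.shared_gene_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_families, self.members_per_family, self.genes_per_family) < 1:
            raise ValueError("counts must be >= 1")
        if self.gene_length_range[0] < 5 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("bad gene_length_range")
        if self.genera_per_family < 1 or self.genera_per_family > self.members_per_family:
            raise ValueError("genera_per_family must be in [1, members_per_family]")


@dataclass
class TruthTable:
    """Ground-truth labels: genome -> (family, genus); gene -> founding family."""

    genome_taxon: dict[str, tuple[str, str]] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"genome_id": g, "family": fam, "genus": gen}
                for g, (fam, gen) in sorted(self.genome_taxon.items())
            ]
        )

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, (fam, _) in sorted(self.genome_taxon.items()):
            out.setdefault(fam, []).append(g)
        return out

    def genera(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, (_, gen) in sorted(self.genome_taxon.items()):
            out.setdefault(gen, []).append(g)
        return out


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = rng.integers(0, 20, size=length - 1)
    return "M" + "".join(AMINO_ACIDS[i] for i in aas)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.where(hit)[0]:
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def back_translate(aa: str) -> str:
    """Back-translate using the most frequent codon per residue (table 11)."""
    return "".join(CODON[a] for a in aa) + STOP_CODON


@dataclass
class _Gene:
    gene_id: str
    family: str
    aa: str
    strand: str
    spacer_len: int  # ancestral intergenic spacer preceding this gene


def _assemble_genome(
    genome_id: str,
    genes: list[_Gene],
    tail_len: int,
) -> AnnotatedGenome:
    """Lay genes onto a genome using their ancestral spacer lengths.

    Spacer lengths are part of the ancestor, so members that lose no genes
    keep identical coordinates and identical location profiles.
    """
    features: list[GeneFeature] = []
    pos = 0
    for g in genes:
        pos += g.spacer_len
        nt_len = 3 * len(g.aa) + 3  # CDS plus stop codon
        start = pos + 1
        end = pos + nt_len
        pos = end
        features.append(
            GeneFeature(
                feature_id=f"{genome_id}|{g.gene_id}",
                genome_id=genome_id,
                start=start,
                end=end,
                strand=g.strand,
                translation=g.aa,
            )
        )
    return AnnotatedGenome(
        genome_id=genome_id,
        accession=genome_id,
        segment_lengths=[pos + tail_len],
        features=features,
    )


def _generate_block(
    config: SimConfig,
    rng: np.random.Generator,
    family_prefix: str = "Fam",
    genome_prefix: str = "SV",
) -> tuple[list[AnnotatedGenome], TruthTable, list[dict]]:
    """Generate one block of families; returns genomes, truth, metadata rows."""
    n_shared = int(round(config.shared_gene_fraction * config.genes_per_family))
    shared_pool: list[tuple[str, str]] = []  # (aa, strand)
    lo, hi = config.gene_length_range
    slo, shi = config.intergenic_range
    tail_len = (slo + shi) // 2
    for s in range(n_shared):
        shared_pool.append(
            (
                _random_protein(rng, int(rng.integers(lo, hi + 1))),
                "+" if rng.random() < 0.5 else "-",
            )
        )

    genus_rate = (
        config.genus_substitution_rate
        if config.genus_substitution_rate is not None
        else config.substitution_rate
    )
    total_families = config.n_families + config.n_unclassified_families
    genomes: list[AnnotatedGenome] = []
    truth = TruthTable()
    metadata_rows: list[dict] = []
    for fi in range(total_families):
        family = f"{family_prefix}{fi + 1:02d}"
        classified_family = fi < config.n_families

        def new_ancestor() -> list[_Gene]:
            anc = []
            for gi in range(config.genes_per_family):
                if gi < n_shared:
                    aa, strand = shared_pool[gi]
                else:
                    aa = _random_protein(rng, int(rng.integers(lo, hi + 1)))
                    strand = "+" if rng.random() < 0.5 else "-"
                gene_id = f"g{gi + 1:02d}"
                anc.append(
                    _Gene(
                        gene_id=gene_id,
                        family=family,
                        aa=aa,
                        strand=strand,
                        spacer_len=int(rng.integers(slo, shi + 1)),
                    )
                )
            return anc

        family_ancestor = new_ancestor() if not config.genus_private_genes else None
        members_per_genus = config.members_per_family // config.genera_per_family
        extras = config.members_per_family % config.genera_per_family
        member_counter = 0
        for gi in range(config.genera_per_family):
            genus = f"{family}_gen{gi + 1}"
            if config.genus_private_genes:
                genus_ancestor = new_ancestor()
            elif config.genera_per_family == 1:
                genus_ancestor = family_ancestor
            else:
                genus_ancestor = [
                    replace(g, aa=_mutate(rng, g.aa, genus_rate))
                    for g in family_ancestor  # type: ignore[union-attr]
                ]
            n_members = members_per_genus + (1 if gi < extras else 0)
            for _ in range(n_members):
                member_counter += 1
                genome_id = f"{genome_prefix}{fi + 1:02d}M{member_counter:02d}"
                member_genes = []
                for g in genus_ancestor:  # type: ignore[union-attr]
                    if config.gene_loss_prob and rng.random() < config.gene_loss_prob:
                        continue
                    aa = _mutate(rng, g.aa, config.substitution_rate)
                    strand = g.strand
                    if config.inversion_prob and rng.random() < config.inversion_prob:
                        strand = "-" if strand == "+" else "+"
                    member_genes.append(replace(g, aa=aa, strand=strand))
                if not member_genes:  # keep at least one gene
                    g = genus_ancestor[0]  # type: ignore[index]
                    member_genes = [replace(g, aa=_mutate(rng, g.aa, config.substitution_rate))]
                genome = _assemble_genome(genome_id, member_genes, tail_len)
                truth.genome_taxon[genome_id] = (family, genus)
                for g in genus_ancestor:  # type: ignore[union-attr]
                    truth.gene_family.setdefault(f"{family}|{g.gene_id}", family)
                if classified_family:
                    genome.taxonomy = Taxonomy(
                        baltimore_group="I",
                        order="Simulatavirales",
                        family=family,
                        subfamily="",
                        genus=genus,
                        virus_name=f"Synthetic virus {genome_id}",
                        genbank_accession=genome_id,
                        refseq_accession="",
                        description="synthetic genome",
                        host_group="bacteria",
                    )
                    metadata_rows.append(
                        {c: getattr(genome.taxonomy, c) for c in METADATA_COLUMNS}
                    )
                genomes.append(genome)
    return genomes, truth, metadata_rows


def write_genbank(genomes: list[AnnotatedGenome], sequences: dict[str, str], path: str | Path) -> None:
    """Write genomes (with their nucleotide sequences) as a GenBank flat file."""
    records = []
    for g in genomes:
        rec = SeqRecord(
            Seq(sequences[g.genome_id]),
            id=g.accession,
            name=g.genome_id,
            description=g.taxonomy.virus_name or f"synthetic genome {g.genome_id}",
        )
        rec.annotations = {
            "molecule_type": "DNA",
            "topology": "linear",
            "data_file_division": "PHG",
            "date": "01-JAN-2018",
            "accessions": [g.accession],
        }
        for f in g.features:
            loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1)
            rec.features.append(
                SeqFeature(
                    loc,
                    type="CDS",
                    qualifiers={
                        "protein_id": [f.feature_id.split("|", 1)[1]],
                        "translation": [f.translation],
                        "transl_table": ["11"],
                    },
                )
            )
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def simulate(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[DatasetManifest, TruthTable]:
    """Simulate a dataset; optionally write GenBank + metadata + truth TSVs.

    Deterministic per seed: the same config yields byte-identical output
    files. Families beyond ``n_families`` (``n_unclassified_families``)
    receive no metadata row and are therefore unclassified downstream.
    """
    rng = np.random.default_rng(config.seed)
    genomes, truth, metadata_rows = _generate_block(config, rng)
    classified = {
        g.genome_id: bool(g.taxonomy.family) for g in genomes
    }
    manifest = DatasetManifest(genomes=genomes, classified=classified)
    if out_dir is not None:
        write_dataset(manifest, truth, out_dir, metadata_rows, config.seed)
    return manifest, truth


def write_dataset(
    manifest: DatasetManifest,
    truth: TruthTable,
    out_dir: str | Path,
    metadata_rows: list[dict] | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write genomes.gbk, metadata.tsv and truth.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # nucleotide sequences are regenerated from the features: spacers are
    # arbitrary non-coding DNA, so a fresh deterministic fill is used
    rng = np.random.default_rng(seed + 1)
    sequences = {}
    for g in manifest.genomes:
        seq = list(_random_nt(rng, g.total_length))
        for f in g.features:
            nt = back_translate(f.translation)
            if f.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            seq[f.start - 1 : f.end] = nt
        sequences[g.genome_id] = "".join(seq)
    gbk = out_dir / "genomes.gbk"
    write_genbank(manifest.genomes, sequences, gbk)
    if metadata_rows is None:
        metadata_rows = [
            {c: getattr(g.taxonomy, c) for c in METADATA_COLUMNS}
            for g in manifest.genomes
            if manifest.classified[g.genome_id]
        ]
    meta = out_dir / "metadata.tsv"
    pd.DataFrame(metadata_rows, columns=list(METADATA_COLUMNS)).to_csv(
        meta, sep="\t", index=False
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    return {"genbank": gbk, "metadata": meta, "truth": truth_path}


def two_regime_benchmark(
    seed: int = 0, out_dir: str | Path | None = None
) -> tuple[DatasetManifest, TruthTable]:
    """A dataset contrasting cohesive and heterogeneous family regimes.

    The "eukaryote-like" block holds three families of two genera each
    derived from a single family ancestor (members of one family always
    share genes), while the "phage-like" block holds three families of
    three genera each with independent gene sets, so between-genus
    within-family distances approach 1 while within-genus distances stay
    low. Ground truth within-genus distances are low in both blocks.
    """
    rng = np.random.default_rng(seed)
    euk_cfg = SimConfig(
        n_families=3,
        members_per_family=6,
        genes_per_family=8,
        substitution_rate=0.05,
        genus_substitution_rate=0.10,
        genera_per_family=2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    phage_cfg = SimConfig(
        n_families=3,
        members_per_family=9,
        genes_per_family=8,
        substitution_rate=0.05,
        genera_per_family=3,
        genus_private_genes=True,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    euk_genomes, euk_truth, euk_meta = _generate_block(
        euk_cfg, np.random.default_rng(euk_cfg.seed), family_prefix="EukFam", genome_prefix="EV"
    )
    phage_genomes, phage_truth, phage_meta = _generate_block(
        phage_cfg, np.random.default_rng(phage_cfg.seed), family_prefix="PhgFam", genome_prefix="PV"
    )
    genomes = euk_genomes + phage_genomes
    truth = TruthTable(
        genome_taxon={**euk_truth.genome_taxon, **phage_truth.genome_taxon},
        gene_family={**euk_truth.gene_family, **phage_truth.gene_family},
    )
    manifest = DatasetManifest(
        genomes=genomes, classified={g.genome_id: True for g in genomes}
    )
    if out_dir is not None:
        write_dataset(manifest, truth, out_dir, euk_meta + phage_meta, seed)
    return manifest, truth
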