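"""Read annotated virus genomes and taxonomy metadata; write tabular outputs.

Genomes arrive as GenBank flat files (or FASTA plus GFF3) with annotated CDS
features; taxonomy arrives as a ten-column TSV keyed by GenBank accession.
Coordinates are kept 1-based inclusive throughout, matching the GenBank
convention; downstream stages convert to fractional midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: Exact header of the metadata TSV, in order.
METADATA_COLUMNS = (
    "baltimore_group",
    "order",
    "family",
    "subfamily",
    "genus",
    "virus_name",
    "genbank_accession",
    "refseq_accession",
    "description",
    "host_group",
)


class GenomeIOError(ValueError):
    """Raised for malformed genome or metadata input."""


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated CDS with its protein translation.

    ``start``/``end`` are 1-based inclusive nucleotide positions on the
    feature's segment; ``strand`` is "+" or "-"; ``segment_index`` indexes
    into the genome's segment list.
    """

    feature_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    translation: str
    segment_index: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"feature {self.feature_id}: bad strand {self.strand!r}")
        if len(self.translation) < 1:
            raise GenomeIOError(f"feature {self.feature_id}: empty translation")


@dataclass(frozen=True)
class Taxonomy:
    """The ten per-genome metadata fields; any may be empty."""

    baltimore_group: str = ""
    order: str = ""
    family: str = ""
    subfamily: str = ""
    genus: str = ""
    virus_name: str = ""
    genbank_accession: str = ""
    refseq_accession: str = ""
    description: str = ""
    host_group: str = ""

    @classmethod
    def from_row(cls, row: dict) -> "Taxonomy":
        return cls(**{c: str(row.get(c, "") or "") for c in METADATA_COLUMNS})


@dataclass
class AnnotatedGenome:
    """A (possibly segmented) genome with CDS features and taxonomy labels."""

    genome_id: str
    accession: str
    segment_lengths: list[int]
    features: list[GeneFeature]
    taxonomy: Taxonomy = field(default_factory=Taxonomy)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.segment_index >= len(self.segment_lengths):
                raise GenomeIOError(
                    f"feature {f.feature_id}: segment index {f.segment_index} "
                    f"out of range for genome {self.genome_id}"
                )
            if f.end > self.segment_lengths[f.segment_index]:
                raise GenomeIOError(
                    f"feature {f.feature_id}: end {f.end} beyond segment length "
                    f"{self.segment_lengths[f.segment_index]}"
                )

    @property
    def total_length(self) -> int:
        return sum(self.segment_lengths)

    def segment_offset(self, segment_index: int) -> int:
        """Nucleotides preceding a segment in the concatenated coordinate system."""
        return sum(self.segment_lengths[:segment_index])


@dataclass
class DatasetManifest:
    """An ordered collection of genomes plus classified/unclassified flags."""

    genomes: list[AnnotatedGenome]
    classified: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise GenomeIOError("manifest must contain at least one genome")
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeIOError(f"duplicate genome ids: {dupes}")
        for gid in ids:
            self.classified.setdefault(gid, False)

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def get(self, genome_id: str) -> AnnotatedGenome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def classified_genomes(self) -> list[AnnotatedGenome]:
        return [g for g in self.genomes if self.classified[g.genome_id]]

    def proteins(self) -> list[GeneFeature]:
        """All CDS features pooled across genomes (segments included)."""
        return [f for g in self.genomes for f in g.features]


def _translate_cds(nt_seq: str, strand: str, table: int) -> str:
    seq = Seq(nt_seq)
    if strand == "-":
        seq = seq.reverse_complement()
    aa = str(seq.translate(table=table))
    return aa.rstrip("*")


def _feature_from_seqfeature(
    feat, record_seq: str, genome_id: str, idx: int, table: int, path: str
) -> GeneFeature | None:
    loc = feat.location
    start = int(loc.start) + 1  # Biopython is 0-based half-open
    end = int(loc.end)
    strand = "-" if loc.strand == -1 else "+"
    quals = feat.qualifiers
    if "translation" in quals:
        aa = str(quals["translation"][0]).rstrip("*")
    else:
        nt = str(feat.extract(Seq(record_seq)))
        aa = str(Seq(nt).translate(table=table)).rstrip("*")
    if not aa:
        return None
    if "*" in aa:
        warnings.warn(
            f"{path}: CDS {idx} of {genome_id} has internal stop codon(s); stripped",
            stacklevel=3,
        )
        aa = aa.replace("*", "")
        if not aa:
            return None
    fid = quals.get("protein_id", quals.get("locus_tag", [f"{genome_id}_cds{idx}"]))[0]
    return GeneFeature(
        feature_id=f"{genome_id}|{fid}",
        genome_id=genome_id,
        start=start,
        end=end,
        strand=strand,
        translation=aa,
        segment_index=0,
    )


def read_genbank(
    paths: Sequence[str | Path], translation_table: int = 11
) -> DatasetManifest:
    """Parse GenBank flat files into a :class:`DatasetManifest`.

    One genome per LOCUS record. CDS features lacking a ``translation``
    qualifier are translated from the nucleotide sequence (default genetic
    code table 11). Non-CDS features are ignored. CDS with internal stop
    codons raise a warning and are retained with stops stripped.
    """
    genomes: list[AnnotatedGenome] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise GenomeIOError(f"no such file: {path}")
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:  # malformed flat file
            raise GenomeIOError(f"malformed GenBank file {path}: {exc}") from exc
        if not records:
            raise GenomeIOError(f"{path}: no GenBank records found")
        for rec in records:
            genome_id = rec.name or rec.id
            accession = rec.id.split(".")[0] if rec.id else genome_id
            seq = str(rec.seq)
            if not seq:
                raise GenomeIOError(f"{path}: record {genome_id} has no sequence")
            features = []
            cds_idx = 0
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                cds_idx += 1
                gf = _feature_from_seqfeature(
                    feat, seq, genome_id, cds_idx, translation_table, str(path)
                )
                if gf is not None:
                    features.append(gf)
            genomes.append(
                AnnotatedGenome(
                    genome_id=genome_id,
                    accession=accession,
                    segment_lengths=[len(seq)],
                    features=features,
                )
            )
    return DatasetManifest(genomes=genomes)


def read_fasta_gff(
    fasta_path: str | Path, gff_path: str | Path, translation_table: int = 11
) -> DatasetManifest:
    """Read genomes from FASTA plus a GFF3 file of CDS features.

    CDS features use the ``translation`` attribute when present, otherwise
    the translation is derived from the nucleotide sequence.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise GenomeIOError(f"{fasta_path}: no FASTA records")
    feats: dict[str, list[GeneFeature]] = {sid: [] for sid in seqs}
    counters: dict[str, int] = {sid: 0 for sid in seqs}
    with open(gff_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{gff_path}:{line_no}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in seqs:
                raise GenomeIOError(f"{gff_path}:{line_no}: unknown sequence {seqid}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            counters[seqid] += 1
            start_i, end_i = int(start), int(end)
            aa = attr_map.get("translation", "")
            if not aa:
                aa = _translate_cds(
                    seqs[seqid][start_i - 1 : end_i], strand, translation_table
                )
            fid = attr_map.get("ID", f"{seqid}_cds{counters[seqid]}")
            feats[seqid].append(
                GeneFeature(
                    feature_id=f"{seqid}|{fid}",
                    genome_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    translation=aa.rstrip("*"),
                )
            )
    genomes = [
        AnnotatedGenome(
            genome_id=sid,
            accession=sid.split(".")[0],
            segment_lengths=[len(seq)],
            features=feats[sid],
        )
        for sid, seq in seqs.items()
    ]
    return DatasetManifest(genomes=genomes)


def _merge_segments(genomes: list[AnnotatedGenome], accessions: list[str]) -> AnnotatedGenome:
    """Join per-segment genomes into one genome, concatenating segments in
    the order the metadata row lists their accessions."""
    by_acc = {g.accession: g for g in genomes}
    parts = [by_acc[a] for a in accessions]
    seg_lengths: list[int] = []
    features: list[GeneFeature] = []
    for seg_idx, part in enumerate(parts):
        seg_lengths.extend(part.segment_lengths)
        for f in part.features:
            features.append(replace(f, segment_index=seg_idx, genome_id=parts[0].genome_id))
    return AnnotatedGenome(
        genome_id=parts[0].genome_id,
        accession=accessions[0],
        segment_lengths=seg_lengths,
        features=features,
    )


def read_metadata(path: str | Path, manifest: DatasetManifest) -> DatasetManifest:
    """Attach taxonomy to genomes by GenBank accession match.

    Genomes with no metadata row are flagged unclassified. A metadata row
    whose ``genbank_accession`` lists several accessions separated by ";"
    joins those segment records into one multi-segment genome. Duplicate
    accession rows are an error; unmatched rows raise a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise GenomeIOError(f"{path}: missing metadata columns {missing}")
    seen: set[str] = set()
    for acc_field in df["genbank_accession"]:
        for acc in str(acc_field).split(";"):
            acc = acc.strip()
            if acc and acc in seen:
                raise GenomeIOError(f"{path}: duplicate accession {acc}")
            if acc:
                seen.add(acc)

    by_acc = {g.accession: g for g in manifest.genomes}
    used: set[str] = set()
    out_genomes: list[AnnotatedGenome] = []
    classified: dict[str, bool] = {}
    for _, row in df.iterrows():
        taxonomy = Taxonomy.from_row(row.to_dict())
        accs = [a.strip() for a in str(row["genbank_accession"]).split(";") if a.strip()]
        matched = [a for a in accs if a in by_acc]
        if not matched:
            warnings.warn(f"{path}: metadata row {row['genbank_accession']} matches no genome")
            continue
        if len(matched) > 1:
            genome = _merge_segments(manifest.genomes, matched)
        else:
            genome = by_acc[matched[0]]
        genome.taxonomy = taxonomy
        out_genomes.append(genome)
        classified[genome.genome_id] = True
        used.update(matched)
    for g in manifest.genomes:
        if g.accession not in used:
            out_genomes.append(g)
            classified[g.genome_id] = False
    # preserve original manifest order where possible
    order = {g.genome_id: i for i, g in enumerate(manifest.genomes)}
    out_genomes.sort(key=lambda g: order.get(g.genome_id, len(order)))
    return DatasetManifest(genomes=out_genomes, classified=classified)


_TABLE_KINDS = ("signatures", "distances", "clusters", "mi")


def write_table(obj, path: str | Path, kind: str = "distances") -> None:
    """Write a labeled matrix or DataFrame to TSV.

    Values round-trip losslessly at 12 significant digits. Non-finite
    values are an error.
    """
    if kind not in _TABLE_KINDS:
        raise GenomeIOError(f"unknown table kind {kind!r}; expected one of {_TABLE_KINDS}")
    df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)
    numeric = df.select_dtypes(include=[np.number])
    if numeric.size and not np.isfinite(numeric.to_numpy(dtype=float)).all():
        raise GenomeIOError(f"non-finite values in {kind} table")
    df.to_csv(path, sep="\t", float_format="%.12g", index=True)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (first column = index)."""
    return pd.read_csv(path, sep="\t", index_col=0)
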