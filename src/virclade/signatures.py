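"""Per-genome signatures: PPHMM scores, gene-location profiles, GOM scores.

A genome's PPHMM signature is its vector of best forward-algorithm scores
against every PPHMM in the database. Its gene-location profile encodes, per
PPHMM, the signed fractional midpoint of the best hit (sign = strand), so
both gene order and orientation are visible downstream. A family's genome
organization model (GOM) stacks the location profiles of its classified
members; a genome's GOM signature is the vector of distance correlations
between its own profile and each family GOM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from virclade.genome_io import AnnotatedGenome, DatasetManifest
from virclade.homology import Hit, PPHMMDatabase, scan_genome


def location_profile(
    hits: Sequence[Hit], genome: AnnotatedGenome, pphmm_ids: Sequence[str]
) -> np.ndarray:
    """Signed fractional-midpoint location vector over the PPHMM columns.

    For each PPHMM with a hit, the value is s*m where m is the hit's
    fractional midpoint in (0, 1] over the concatenated genome and s is +1
    for "+" strand, -1 for "-". PPHMMs without a hit are 0.
    """
    index = {pid: i for i, pid in enumerate(pphmm_ids)}
    profile = np.zeros(len(pphmm_ids))
    for h in hits:
        if h.genome_id != genome.genome_id:
            raise ValueError(f"hit {h.feature_id} is not from genome {genome.genome_id}")
        if not 0.0 < h.midpoint <= 1.0:
            raise ValueError(f"hit midpoint {h.midpoint} outside genome")
        sign = 1.0 if h.strand == "+" else -1.0
        profile[index[h.pphmm_id]] = sign * h.midpoint
    return profile


@dataclass
class GOM:
    """Genome organization model: member location profiles of one family."""

    family_id: str
    genome_ids: list[str]
    profiles: np.ndarray  # (members, n_pphmms)

    def __post_init__(self) -> None:
        if self.profiles.ndim != 2 or self.profiles.shape[0] < 1:
            raise ValueError("GOM needs at least one member profile")
        if len(self.genome_ids) != self.profiles.shape[0]:
            raise ValueError("genome_ids/profiles mismatch")


def build_gom(family_id: str, member_profiles: Mapping[str, np.ndarray]) -> GOM:
    """Stack member location profiles into a GOM, rows in sorted-id order."""
    if not member_profiles:
        raise ValueError(f"family {family_id!r} has no member profiles")
    ids = sorted(member_profiles)
    return GOM(
        family_id=family_id,
        genome_ids=ids,
        profiles=np.vstack([np.asarray(member_profiles[g], dtype=float) for g in ids]),
    )


def build_goms(
    manifest: DatasetManifest, profiles: Mapping[str, np.ndarray]
) -> dict[str, GOM]:
    """One GOM per family, from the classified genomes carrying that label."""
    members: dict[str, dict[str, np.ndarray]] = {}
    for g in manifest.classified_genomes():
        fam = g.taxonomy.family
        if fam:
            members.setdefault(fam, {})[g.genome_id] = profiles[g.genome_id]
    return {fam: build_gom(fam, m) for fam, m in sorted(members.items())}


def distance_correlation(x: np.ndarray, Y: np.ndarray) -> float:
    """Sample distance correlation between a profile and a GOM matrix.

    The m PPHMM columns are the observations: scalar x_j against the
    k-dimensional column Y[:, j]. Pairwise distances |x_j - x_l| and
    ||Y[:, j] - Y[:, l]||_2 are double-centered and combined into
    dCor = dCov / sqrt(dVar_x * dVar_Y); degenerate cases (either distance
    variance zero, e.g. a constant profile) return 0 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least two observations")
    if Y.shape[1] != m:
        raise ValueError(f"GOM has {Y.shape[1]} columns, profile has {m}")
    a = np.abs(x[:, None] - x[None, :])
    diff = Y[:, :, None] - Y[:, None, :]
    b = np.sqrt((diff**2).sum(axis=0))

    def center(d: np.ndarray) -> np.ndarray:
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    A, B = center(a), center(b)
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    val = dcov2 / np.sqrt(dvar_x * dvar_y)
    return float(np.sqrt(max(val, 0.0)))


@dataclass
class SignatureTable:
    """Genomes x [PPHMM scores | GOM scores], plus location profiles.

    All blocks share row order; column metadata records the PPHMM ids and
    family ids that label the two blocks.
    """

    genome_ids: list[str]
    pphmm_ids: list[str]
    family_ids: list[str]
    pphmm_block: np.ndarray  # (n, p) scores >= 0
    gom_block: np.ndarray  # (n, f) distance correlations in [0, 1]
    location_profiles: np.ndarray  # (n, p) signed locations in [-1, 1]

    def __post_init__(self) -> None:
        n, p, f = len(self.genome_ids), len(self.pphmm_ids), len(self.family_ids)
        if self.pphmm_block.shape != (n, p):
            raise ValueError("pphmm_block shape mismatch")
        if self.gom_block.shape != (n, f):
            raise ValueError("gom_block shape mismatch")
        if self.location_profiles.shape != (n, p):
            raise ValueError("location_profiles shape mismatch")
        for name, block in (
            ("pphmm_block", self.pphmm_block),
            ("gom_block", self.gom_block),
            ("location_profiles", self.location_profiles),
        ):
            if block.size and not np.isfinite(block).all():
                raise ValueError(f"non-finite values in {name}")

    def row(self, genome_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.genome_ids.index(genome_id)
        return self.pphmm_block[i], self.gom_block[i]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"pphmm:{p}" for p in self.pphmm_ids] + [
            f"gom:{f}" for f in self.family_ids
        ]
        return pd.DataFrame(
            np.hstack([self.pphmm_block, self.gom_block]),
            index=self.genome_ids,
            columns=cols,
        )

    def locations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.location_profiles,
            index=self.genome_ids,
            columns=[f"pphmm:{p}" for p in self.pphmm_ids],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, locations: pd.DataFrame) -> "SignatureTable":
        pphmm_cols = [c for c in df.columns if c.startswith("pphmm:")]
        gom_cols = [c for c in df.columns if c.startswith("gom:")]
        return cls(
            genome_ids=list(df.index),
            pphmm_ids=[c.split(":", 1)[1] for c in pphmm_cols],
            family_ids=[c.split(":", 1)[1] for c in gom_cols],
            pphmm_block=df[pphmm_cols].to_numpy(dtype=float),
            gom_block=df[gom_cols].to_numpy(dtype=float),
            location_profiles=locations.loc[df.index].to_numpy(dtype=float),
        )


def build_signature_table(
    manifest: DatasetManifest,
    db: PPHMMDatabase,
    goms: Mapping[str, GOM] | None = None,
    score_floor: float = 0.0,
    hits_by_genome: Mapping[str, Sequence[Hit]] | None = None,
) -> SignatureTable:
    """Annotate every genome in the manifest with PPHMM and GOM signatures.

    The PPHMM/GOM databases are built from the classified subset; rows are
    produced for classified and unclassified genomes alike. When ``goms``
    is None the family GOMs are first built from the classified genomes'
    own location profiles. Precomputed hits may be supplied to avoid
    re-scanning.
    """
    pphmm_ids = db.pphmm_ids
    n, p = len(manifest.genomes), len(pphmm_ids)
    scores = np.zeros((n, p))
    locs = np.zeros((n, p))
    col = {pid: j for j, pid in enumerate(pphmm_ids)}
    for i, genome in enumerate(manifest.genomes):
        hits = (
            hits_by_genome[genome.genome_id]
            if hits_by_genome is not None
            else scan_genome(genome, db, score_floor=score_floor)
        )
        for h in hits:
            scores[i, col[h.pphmm_id]] = h.score
        locs[i] = location_profile(hits, genome, pphmm_ids)

    profiles = {g.genome_id: locs[i] for i, g in enumerate(manifest.genomes)}
    if goms is None:
        goms = build_goms(manifest, profiles)
    family_ids = sorted(goms)
    gom_block = np.zeros((n, len(family_ids)))
    for i, genome in enumerate(manifest.genomes):
        for j, fam in enumerate(family_ids):
            if p >= 2:
                gom_block[i, j] = distance_correlation(locs[i], goms[fam].profiles)
    return SignatureTable(
        genome_ids=[g.genome_id for g in manifest.genomes],
        pphmm_ids=list(pphmm_ids),
        family_ids=family_ids,
        pphmm_block=scores,
        gom_block=gom_block,
        location_profiles=locs,
    )


def subset_signature_table(
    table: SignatureTable,
    genome_subset: Sequence[str],
    family_subset: Sequence[str],
) -> SignatureTable:
    """Restrict a signature table for a focused reanalysis.

    Rows are restricted to ``genome_subset``; PPHMM columns whose scores are
    zero for every retained genome are dropped; GOM columns are restricted
    to ``family_subset``.
    """
    if not genome_subset or not family_subset:
        raise ValueError("subsets must be nonempty")
    missing = [g for g in genome_subset if g not in table.genome_ids]
    if missing:
        raise ValueError(f"unknown genomes: {missing}")
    missing_f = [f for f in family_subset if f not in table.family_ids]
    if missing_f:
        raise ValueError(f"unknown families: {missing_f}")
    rows = [table.genome_ids.index(g) for g in genome_subset]
    sub_scores = table.pphmm_block[rows]
    keep_cols = np.where((sub_scores > 0).any(axis=0))[0]
    if keep_cols.size == 0:
        raise ValueError("no PPHMM column has a nonzero score in the subset")
    fam_cols = [table.family_ids.index(f) for f in family_subset]
    return SignatureTable(
        genome_ids=list(genome_subset),
        pphmm_ids=[table.pphmm_ids[j] for j in keep_cols],
        family_ids=list(family_subset),
        pphmm_block=sub_scores[:, keep_cols],
        gom_block=table.gom_block[np.ix_(rows, fam_cols)],
        location_profiles=table.location_profiles[np.ix_(rows, keep_cols)],
    )
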