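# Methods

This note documents the models and procedures implemented in `virclade`,
the parameter defaults and why they were chosen, what the synthetic data
does and does not emulate, and the package's known limitations.

## Pipeline overview

1. **Protein pooling.** CDS translations are pooled from the classified
   genomes (segments of one genome are pooled; location arithmetic keeps
   segments separate and concatenates them in metadata order).
2. **All-vs-all similarity.** Smith–Waterman local alignment with BLOSUM62
   and affine gaps (first gap residue 11, extension 1). Raw scores `S` are
   converted to bits as `(λS − ln K)/ln 2` with the classic gapped BLOSUM62
   constants λ = 0.267, K = 0.041. Per-pair Karlin–Altschul estimation is
   deliberately not done: downstream the scores only enter a ratio (the
   generalized Jaccard), so a consistent scale matters more than absolute
   calibration. Pairs below 20 bits are dropped from the edge list.
3. **Clustering into putative gene families.** Default is connected
   components of the similarity graph thresholded at 30 bits —
   deterministic, order-invariant and dependency-free. A Markov-cluster
   style option (`mcl_like`, expansion 2, inflation 2.0) is available for
   datasets where promiscuous domains chain unrelated families together.
   The 30-bit threshold sits well above the ~13–20-bit noise floor that
   unrelated proteins of this length reach under these statistics.
4. **Cluster alignment.** Center-star progressive alignment: the center is
   the member with the greatest summed pairwise bit score; every other
   member is globally aligned to the center and merged. For the tightly
   related clusters this stage sees (members of one gene family), the
   center-star approximation is adequate and exactly reproducible.
5. **PPHMM estimation.** Standard profile-HMM topology (match/insert/
   delete, no I↔D transitions). Columns with gap fraction ≤ 0.5 become
   match states. Match emissions are column counts plus background-weighted
   pseudocounts of total strength α = 1:
   `P(a) = (n_a + α q_a) / (n + α)` with `q` the Robinson–Robinson amino
   acid frequencies. Insert states emit `q`. Transitions are counted from
   each row's state path with pseudocount 1 on every structurally allowed
   transition. α = 1 and the 0.5 gap rule are the standard textbook
   choices; nothing in the pipeline is sensitive to them at the divergences
   the simulator produces.
6. **Scanning.** Each protein is scored against each PPHMM by the full
   forward algorithm in log space, as a log-odds against the background
   null. Because inserts emit the background, only match emissions and
   transitions contribute; the delete-state recursion is evaluated as a
   single `logaddexp` prefix scan, and all proteins of a genome are scored
   as one padded batch. Per (genome, PPHMM) the best-scoring protein above
   the floor of 0 bits becomes the hit ("similarity detected" = positive
   log-odds). The hit's location is the CDS midpoint as a fraction of the
   concatenated genome length, signed by strand.
7. **Singleton filtering.** A PPHMM matching only one virus is removed if
   that virus's family has more than two members in the dataset — such a
   profile cannot help relate the family's members and only adds noise
   columns; singletons from unclassified viruses or one/two-member
   families are kept, since they may be the only evidence those genomes
   have.
8. **Signatures and distances.** The PPHMM signature is the vector of best
   hit scores (0 for no hit). The GOM of a family stacks the location
   profiles of its classified members (sorted genome id order; one-member
   families are allowed). The GOM signature is the vector of biased sample
   distance correlations between the genome's location profile and each
   family GOM, treating PPHMM columns as observations; degenerate cases
   (constant profile, or an empty profile) return 0 rather than NaN — no
   organizational evidence, not missing data. CGJ similarity is the
   geometric mean of the two generalized Jaccards, CGJ distance its
   complement. Two all-zero signatures score similarity 0 (distance 1):
   genomes with no detectable genes share no evidence of relatedness, and
   scoring them as identical would cluster annotation failures together.
9. **Dendrogram, bootstrap, collapse.** UPGMA with size-weighted average
   linkage; node heights are the merge distances on the CGJ scale (not
   half-heights), so the 0.8 collapse threshold and the tree heights live
   on the same axis. Ties break on the lexicographically smallest
   member-id pair, making the tree invariant to input order. Bootstrap
   pseudoreplicates resample PPHMM signature columns with replacement and
   keep the GOM block fixed (the GOM block derives from the same gene set;
   a config switch resamples both). Support is the percentage of replicate
   trees containing the clade's exact leaf set (rooted clades — UPGMA
   trees are rooted). Default 100 replicates. Collapse at threshold `t`
   takes maximal clades whose height is strictly below `t`; leaves whose
   every ancestor merges at ≥ `t` become singletons.
10. **Assignment.** Each unclassified genome is reported with its cluster
    and the cluster's classified-family composition. Clusters containing
    only unclassified genomes are flagged candidate unassigned taxonomic
    units (UTUs). Genomes whose PPHMM signature is all zero are reported
    separately as having no similarity to the classified dataset — they
    cannot meaningfully cluster, since their distance to everything
    (including each other) is 1 by the all-zero rule.
11. **Shared genes.** For two disjoint genome groups, each PPHMM's score
    column is reduced to presence (> 0) and the plug-in mutual information
    of the 2×2 joint with group membership is computed in bits (0·log 0 =
    0, so the estimate is bounded by 1 bit). Because tiny samples make the
    plug-in estimate noisy, the statistic reported is the mean over 100
    replicates of 2 genomes drawn per group without replacement, with the
    replicate standard deviation alongside. A quantile-binned variant for
    the raw scores is available behind config. PPHMMs scoring zero across
    both groups are excluded.

## Key defaults

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| substitution matrix / gaps | BLOSUM62, 11/1 | — | field standard for protein search |
| λ, K | 0.267, 0.041 | — | classic gapped BLOSUM62 statistics; fixed for scale consistency |
| edge floor `min_score` | 20 | bits | above the ~13-bit random-pair noise floor |
| clustering threshold | 30 | bits | separates gene families from noise with margin |
| match-column gap fraction | 0.5 | — | standard profile construction |
| emission pseudocount α | 1 | counts | Laplace-type, background weighted |
| hit floor `score_floor` | 0 | bits | positive log-odds defines "similarity detected" |
| CGJ component weight | 0.5/0.5 | — | plain geometric mean; configurable exponent |
| collapse threshold | 0.8 | CGJ distance | the family-equivalence threshold |
| bootstrap replicates | 100 | — | upper end of the customary 50–100 range |
| MI replicates × per-group | 100 × 2 | — | averages out small-sample noise while staying group-size robust |

## Synthetic data

The simulator draws, per family, an ancestor of ordered genes (random
amino-acid sequences, lengths 60–120 aa by default, random strands,
ancestral intergenic spacer lengths) and derives members by uniform residue
substitution, whole-gene loss and strand inversion; genes are
back-translated with the most frequent codons of genetic code table 11 and
written as valid GenBank flat files plus a metadata TSV. Spacer lengths
belong to the ancestor, so members that lose no genes keep identical
coordinates — at zero divergence the within-family CGJ distance is exactly
0. Substitutions are uniform over the 19 alternative residues; there is no
rate matrix, no within-gene indels, no recombination breakpoints and no
codon-usage realism. A `shared_gene_fraction` moves genes into a pool
common to all families, emulating mosaicism/horizontal transfer. The
two-regime benchmark contrasts three cohesive families (two genera derived
from one family ancestor) with three heterogeneous families (three genera
with fully independent gene sets), mimicking the difference between
eukaryote-like families and tailed-phage-like families whose genera share
no genes.

Because simulated families are either clearly homologous or fully
unrelated, passing the recovery tests shows the machinery is correct and
self-consistent — not that the 0.8 threshold, or any other constant, is
calibrated for real viral datasets, where divergence is continuous,
annotation is imperfect and gene sharing is pervasive.

Problem sizes used by the test suite and the acceptance script — 5
families × 6 members × 8 genes for family recovery, 45 genomes for the
two-regime contrast, 18 genomes for the assignment scenario — are the
package's chosen demonstration scale: large enough that every stage
(clustering, profile construction, scanning, bootstrap) runs on non-trivial
input, small enough to re-run routinely.

## Numerical and design notes

- **Forward scores** are exact log-space sums over all alignments (no
  Viterbi approximation); agreement with exhaustive path enumeration on
  toy models is tested to 1e-6. Unknown residues emit odds 1.
- **Distance correlation** uses the biased (classic) sample estimator;
  the unbiased variant can go negative, which would complicate the
  Jaccard-of-signatures step.
- **UPGMA tie-breaks** are deterministic; equal-distance merges pick the
  pair with the smallest member ids, so rerunning or permuting input
  cannot change the tree.
- **Circular genomes** are treated as linearized at the annotated origin;
  location profiles inherit that choice.
- **Multi-segment genomes** pool proteins across segments; location
  profiles use the concatenated coordinate system with segments in
  metadata order. Segment order is therefore part of the model input.
- **External search engines**: the similarity stage accepts a precomputed
  3-column TSV of bit scores, so a faster tool can replace the internal
  aligner without touching downstream stages.

## Limitations

- Signature scanning uses annotated CDS only; there is no ORF discovery,
  no frameshift handling and no domain-level multi-hit parsing.
- Scores carry no E-value calibration; the bit scale is internally
  consistent but not comparable to BLAST E-values.
- CGJ condenses relatedness to one number; heavily mosaic genomes with
  genes of conflicting histories are better served by network methods —
  here they will show intermediate distances to several groups.
- The bootstrap resamples signature columns, not sequences; it measures
  stability of the signature table, not alignment uncertainty.
- With `per_group = 2` the MI estimator is intentionally coarse; the
  replicate dispersion reported alongside the mean should always be
  consulted.
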