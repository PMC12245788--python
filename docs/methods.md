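# Methods

## Model and procedure

The pipeline treats an inverse-docking campaign as a long table of scores
`(ligand, pdb_id, chain, score)` in arbitrary docking units, lower =
stronger.  That polarity is fixed package-wide; there is no per-file
polarity flag, because the Z-score convention (negative = stronger) depends
on it.

**Aggregation.**  Chains are mapped to UniProt accessions by an external
table ((pdb_id, chain) → accession; chains compared case-sensitively, as
PDB chain identifiers are case-sensitive).  Each (ligand, target) cell is
the minimum score over every record mapping to that target; the winning
structure is kept as provenance.  Duplicate (ligand, pdb, chain) rows keep
the minimum and are logged.  Unmapped chains are dropped with a warning
rather than failing the run — mapping databases cover only a subset of PDB
chains — but zero mappable records is fatal.  Rows + rejected + unmapped
always reconcile with the input row count.

**Fingerprints.**  Z-scores use the per-ligand mean and *sample* SD
(ddof = 1; standard finite-sample convention) over the set of targets
scored for every ligand (intersection policy).  Restricting to the
intersection keeps a single well-defined N_t for the RMSD formula; the
dropped-target count is logged.  Z statistics are computed on the
aggregated (per-UniProt) matrix, not across raw structures.  The hit-table
cutoff is strict (Z < −2.58; the boundary does not count) and the −2.58
value corresponds to the 99.5th percentile of a standard normal reference
— the package computes that percentile as `100·P(X > z)` rather than
hard-coding it.

**Top-target curation.**  The display list is the union of each ligand's
k = 10 lowest-Z targets, ordered by minimum Z across ligands (ties by
accession).  Curation is user data, not code: an exclude list removes
non-druggable proteins, an include list appends known targets of interest
in the given order.  Heatmap Z values are carried over from the full-matrix
fingerprints, never recomputed on the curated subset — recomputing would
change values with the subset chosen, which is the alternative we
deliberately rejected.

**Clustering.**  R_{l,k} is Euclidean distance scaled by 1/√N_t, so the
standard Ward treatment of a precomputed distance matrix applies; we use
SciPy's implementation (`linkage(..., method="ward")`), whose nearest-
neighbour-chain agglomeration is deterministic for a given matrix.  Merge
heights are reported on the distance (RMSD) scale so cluster separations
read directly as fingerprint RMSD.  Cutting at height h applies every merge
strictly below h; cutting at k applies the first n − k merges.  Newick
export orders children smaller-subtree-first (ties by alphabetical first
leaf) and prints branch lengths at 10 significant digits; heights are
quantised to that grid on both the write and the read path, making
export → parse → re-export a byte-identical fixed point while keeping
cophenetic distances within 1e-9 of the tree's.

**Enrichment metrics.**  Targets are ranked by raw score ascending with
accession tie-breaks.  AUC is the tie-aware Mann–Whitney statistic computed
from raw scores (ties count ½), so it is invariant under the arbitrary
tie-break and any strictly increasing score transform; the rank-based
metrics (EF, RIE, BEDROC) use the tie-broken integer ranks, which their
formulas require.  EF uses a top-n prefix of n = ceil(f·N), never empty.
RIE follows the exponential-weight definition with the uniform-ranking
expectation in the denominator; BEDROC is RIE linearly rescaled to [0, 1]
(α = 20 by default, weighting roughly the top 8 % of the ranking).  Total
gain estimates the predictiveness curve with B = 10 equal-count bins
(configurable); published web implementations do not document their
binning, so TG concordance across tools is approximate by construction.
Actives are pairs with pChEMBL strictly greater than 4.  Validation is per
ligand; there is no pooled multi-ligand metric.

## Synthetic campaigns

The generator emulates the statistical shape the analysis relies on, not
docking physics:

| parameter | default | meaning |
|---|---|---|
| `n_ligands` / `n_targets` | 14 / 500 | campaign size (desk-scale; thousands of targets supported) |
| `class_labels` | two 7-ligand classes | planted structural classes |
| `block_fraction` | 0.10 | fraction of targets in each class's affinity block |
| `block_shift` | 2.0 σ | mean score decrease on block targets |
| `mu_range` / `sigma_range` | U(−60, −45) / U(4, 6) | per-ligand score location/scale, arbitrary units |
| `structures_geom_p` | 0.175 | 1 + shifted-geometric structures per target → median 4 |
| `struct_jitter` | 0.1 σ | per-structure spread around the latent (ligand, target) score |
| `n_actives_per_ligand` / `active_shift` | 25 / 1.0 σ | planted actives, on non-block targets |

Scores are drawn hierarchically: one latent N(μ_l − shifts, σ_l) score per
(ligand, target), then per-structure jitter N(0, 0.1 σ_l).  The latent
layer matters: redundant structures of one binding site produce strongly
correlated scores in practice, and drawing structures independently would
make the best-of-n aggregate left-skewed (min-of-normals), violating the
near-normality the Z-percentile interpretation leans on.  With the latent
model, per-ligand aggregated distributions stay near-normal (|skew|
typically < 0.15 at zero block shift).  Class and active shifts move the
latent mean, so the per-target minimum preserves the planted signal.
Planting actives on non-block targets keeps enrichment checks independent
of cluster-structure checks.

The structures-per-target law matches the median (4) of real redundancy
rather than its mean (≈ 13), trading the extreme right tail for small
default campaigns; the tail is qualitatively present through the geometric
distribution.  What passing recovery tests shows is that the pipeline
detects block-structured mean shifts of ~2 SD under realistic redundancy
and noise — not that it would rank the targets of any particular real
compound correctly, which depends on docking accuracy the generator does
not model.

## Numerical choices and determinism

* Sample SD everywhere a ligand's score spread is estimated.
* Zero score variance for a ligand is fatal (named in the error); fewer
  than 3 shared targets is fatal.
* Tie-breaks are lexicographic on accession (ranking) and deterministic in
  SciPy's agglomeration (clustering); repeated runs are byte-identical for
  all tabular/JSON outputs, and manifests deliberately contain no
  timestamps.
* BEDROC and TG are clipped to [0, 1] against floating-point undershoot.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Test and reproduction problem sizes

The test suite and `scripts/acceptance.py` use desk-scale campaigns chosen
as the package's defaults: 14 ligands × 500 targets for recovery runs
(20 seeds for the planted and null conditions), 8 × 120 for parameter
sweeps (12 seeds per block-shift level), and one 14 × 3,888-target run to
exercise realistic campaign scale end-to-end.  Oracle comparisons (RMSD
double loop, Lance–Williams recurrence, direct-sum RIE/BEDROC, brute-force
AUC/EF/hit scans, RDKit's scoring module) are run on 20–100 random
instances each.

## Known limitations

* No docking engine, structure preparation, binding-site detection or
  chemistry is modelled anywhere; scores are consumed as given.
* The intersection completeness policy discards targets missing for any
  ligand; campaigns with very uneven coverage lose targets accordingly.
* TG depends on the binning estimator; values are comparable within this
  package, approximately across tools.
* Curation (which targets are non-druggable, which known targets to
  append) is input data; the package never makes that judgement.
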