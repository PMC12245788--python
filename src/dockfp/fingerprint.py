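"""Per-ligand Z-score fingerprints over the common target set.

Because different ligands have different typical docking scores, raw scores
are not comparable across ligands.  Each ligand's scores are therefore
standardised against that ligand's own score distribution over all targets:

    Z_l(i) = (s(l, i) - mu_l) / sigma_l

with mu_l / sigma_l the mean and *sample* standard deviation of ligand l's
scores over the shared target set.  A negative Z means stronger-than-average
predicted binding for that ligand; per-ligand score distributions are close
enough to normal that Z < -2.58 corresponds to roughly the strongest 0.5 %
of a ligand's interactions.  The vector Z_l is the ligand's inverse docking
fingerprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ScoreMatrix

log = logging.getLogger(__name__)


class FingerprintError(ValueError):
    pass


@dataclass
class FingerprintSet:
    """Z-score fingerprints: ligands x shared ordered target list.

    ``Z`` is a complete DataFrame (no NaNs); ``mu`` and ``sigma`` are the
    per-ligand statistics used for standardisation.  ``n_dropped_targets``
    counts targets discarded because not every ligand had a score there.
    """

    Z: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    n_dropped_targets: int = 0

    @property
    def ligands(self) -> list[str]:
        return list(self.Z.index)

    @property
    def targets(self) -> list[str]:
        return list(self.Z.columns)

    @property
    def n_targets(self) -> int:
        return self.Z.shape[1]

    def to_csv(self, path: str | Path) -> None:
        self.Z.to_csv(path, index_label="ligand_id")


def zscore_fingerprints(matrix: ScoreMatrix) -> FingerprintSet:
    """Standardise the best-score matrix into per-ligand fingerprints.

    The matrix is first restricted to the targets scored for *every* ligand
    (intersection policy) so that all fingerprints live over one shared,
    identically ordered target list; the number of dropped targets is
    logged.  Sample SD (ddof=1) is used.  Fewer than 3 shared targets, or a
    ligand with zero score variance, is fatal.
    """
    full = matrix.scores
    common = full.dropna(axis=1, how="any")
    n_dropped = full.shape[1] - common.shape[1]
    if n_dropped:
        log.info("dropped %d targets not scored for every ligand", n_dropped)
    if common.shape[1] < 3:
        raise FingerprintError(
            f"only {common.shape[1]} targets shared by all ligands; need >= 3")
    mu = common.mean(axis=1)
    sigma = common.std(axis=1, ddof=1)
    degenerate = sigma[sigma == 0.0]
    if len(degenerate):
        raise FingerprintError(
            "zero score variance for ligand(s): " + ", ".join(degenerate.index))
    Z = common.sub(mu, axis=0).div(sigma, axis=0)
    return FingerprintSet(Z=Z, mu=mu, sigma=sigma, n_dropped_targets=n_dropped)


def percentile_of_z(z: float) -> float:
    """Percentage of a standard normal reference weaker than ``z``.

    Returns 100 * P(X > z): the fraction of targets a normally distributed
    score would place *behind* this one.  Z = -2.58 sits at the 99.5th
    percentile, i.e. stronger than 99.5 % of the reference distribution.
    """
    if not np.isfinite(z):
        raise FingerprintError("z must be finite")
    return float(100.0 * stats.norm.sf(z))


def select_top_targets(
    fps: FingerprintSet,
    k: int = 10,
    exclude: Sequence[str] = (),
    include: Sequence[str] = (),
) -> list[str]:
    """Union of every ligand's k best (lowest-Z) targets, curated.

    Each ligand contributes its k lowest-Z targets (ties broken by Z then
    accession); the union is de-duplicated and ordered by minimum Z across
    ligands (ascending, ties by accession).  ``exclude`` removes manually
    curated non-targets; ``include`` appends known targets of interest, in
    the given order, if not already selected.  Includes absent from the
    fingerprint target list are skipped with a warning.
    """
    if k < 1:
        raise FingerprintError("k must be >= 1")
    if k > fps.n_targets:
        raise FingerprintError(f"k={k} exceeds the {fps.n_targets} shared targets")
    overlap = set(exclude) & set(include)
    if overlap:
        raise FingerprintError(
            "exclude and include lists overlap: " + ", ".join(sorted(overlap)))
    union: set[str] = set()
    for ligand in fps.ligands:
        row = fps.Z.loc[ligand]
        order = sorted(fps.targets, key=lambda t: (row[t], t))
        union.update(order[:k])
    union -= set(exclude)
    min_z = fps.Z.min(axis=0)
    selected = sorted(union, key=lambda t: (min_z[t], t))
    for t in include:
        if t in selected:
            continue
        if t not in fps.Z.columns:
            log.warning("include target %s absent from fingerprints; skipped", t)
            continue
        selected.append(t)
    return selected


def hit_table(
    fps: FingerprintSet, z_cut: float = -2.58, min_ligands: int = 3
) -> pd.DataFrame:
    """Targets where at least ``min_ligands`` ligands score below ``z_cut``.

    The cutoff is strict (Z < z_cut; the boundary value itself does not
    count).  Returns a DataFrame with columns ``uniprot_id``,
    ``hit_ligands`` (alphabetical, ';'-joined), ``n_hits`` and ``min_Z``,
    sorted by (n_hits descending, min_Z ascending, accession).  May be empty.
    """
    if min_ligands < 1:
        raise FingerprintError("min_ligands must be >= 1")
    rows = []
    hits_mask = fps.Z < z_cut
    for target in fps.targets:
        hit_ligands = sorted(fps.Z.index[hits_mask[target]])
        if len(hit_ligands) >= min_ligands:
            rows.append({
                "uniprot_id": target,
                "hit_ligands": ";".join(hit_ligands),
                "n_hits": len(hit_ligands),
                "min_Z": float(fps.Z[target].min()),
            })
    table = pd.DataFrame(rows, columns=["uniprot_id", "hit_ligands",
                                        "n_hits", "min_Z"])
    if len(table):
        table = table.sort_values(
            ["n_hits", "min_Z", "uniprot_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return table


def normality_diagnostic(
    matrix: ScoreMatrix, ligand: str
) -> tuple[float, float, float]:
    """Moment and KS diagnostics of one ligand's score distribution.

    Returns (skewness, excess kurtosis, KS distance) of the ligand's scores
    against a normal with the ligand's own sample mean and SD.  The Z-score
    interpretation (percentile attached to a cutoff) leans on approximate
    normality, so this is the supporting check -- advisory only, it never
    gates the pipeline.
    """
    if ligand not in matrix.scores.index:
        raise FingerprintError(f"unknown ligand {ligand!r}")
    s = matrix.scores.loc[ligand].dropna().to_numpy(float)
    if s.size < 20:
        raise FingerprintError(
            f"ligand {ligand!r} has only {s.size} scores; need >= 20")
    skew = float(stats.skew(s))
    kurt = float(stats.kurtosis(s))
    ks = float(stats.kstest(s, "norm", args=(s.mean(), s.std(ddof=1))).statistic)
    return skew, kurt, ks


def heatmap_export(
    fps: FingerprintSet,
    targets: Sequence[str],
    image_path: str | Path,
    csv_path: str | Path,
    target_classes: Mapping[str, str] | None = None,
) -> None:
    """Write the fingerprint heatmap (ligands x curated targets) and its data.

    Cell colour maps Z with more negative (stronger) cells hotter/yellow.
    Z values are carried over from the full-matrix fingerprints, never
    recomputed on the subset.  When per-target class annotations are given,
    columns are grouped by class.  The long CSV holds one (ligand, target, Z)
    row per cell, |ligands| x |targets| rows in total.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    unknown = [t for t in targets if t not in fps.Z.columns]
    if unknown:
        raise FingerprintError("unknown target(s): " + ", ".join(unknown))
    cols = list(targets)
    if target_classes:
        cols = sorted(cols, key=lambda t: (target_classes.get(t, "~"), t))
    sub = fps.Z[cols]

    long = sub.stack().rename("Z").reset_index()
    long.columns = ["ligand_id", "uniprot_id", "Z"]
    long.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.22 * len(cols)), max(3.0, 0.35 * len(sub.index))))
    im = ax.imshow(sub.to_numpy(), aspect="auto", cmap="viridis_r")
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=90, fontsize=6)
    ax.set_yticks(range(len(sub.index)))
    ax.set_yticklabels(sub.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Z-score")
    ax.set_xlabel("protein target")
    ax.set_ylabel("ligand")
    fig.tight_layout()
    fig.savefig(image_path)
    plt.close(fig)
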