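"""Retrospective validation of per-ligand target rankings.

Given one ligand's ranked target list (ascending docking score, best first)
and a set of experimentally known targets ("actives", pChEMBL > 4), this
module computes the standard virtual-screening quality metrics:

* ROC curve and its area (AUC) -- overall ranking quality;
* enrichment factor EF@f -- actives concentration in the top fraction f;
* robust initial enhancement (RIE) -- exponentially rank-weighted actives
  sum normalised by its uniform-ranking expectation;
* BEDROC -- RIE rescaled to [0, 1], alpha controlling how early "early
  recognition" is (alpha = 20 weights roughly the top 8 %);
* total gain (TG) -- predictiveness-curve statistic: normalised mean
  absolute deviation of the conditional active rate from prevalence.

All metrics are evaluated per ligand; there is no pooled multi-ligand score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ingest import Source, _dialect_delimiter, _open, UNIPROT_RE
from .ingest import ScoreMatrix

log = logging.getLogger(__name__)


class EnrichError(ValueError):
    pass


@dataclass
class RankedScreen:
    """One ligand's targets ranked best-first, with active labels.

    ``scores`` are raw docking scores sorted ascending after a deterministic
    accession tie-break; ``labels`` marks actives.  ``ranks`` (1-based
    positions of actives) feed the rank-based metrics, while tie-aware AUC
    is computed from the raw scores directly.
    """

    ligand_id: str
    targets: list[str]
    scores: np.ndarray
    labels: np.ndarray
    alpha: float = 20.0
    n_actives_dropped: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape:
            raise EnrichError("scores and labels length mismatch")
        if self.alpha <= 0:
            raise EnrichError("alpha must be positive")
        if not (0 < self.n_actives < self.n):
            raise EnrichError(
                f"{self.ligand_id}: need both actives and inactives "
                f"(N={self.n}, N_a={self.n_actives})")

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def ranks(self) -> np.ndarray:
        return np.flatnonzero(self.labels) + 1

    @property
    def ra(self) -> float:
        return self.n_actives / self.n


def read_actives(
    source: Source, pchembl_min: float = 4.0, delimiter: str | None = None
) -> set[tuple[str, str]]:
    """Read experimentally relevant (ligand, target) pairs.

    Expects columns ``ligand_id, uniprot_id, pchembl``.  Pairs are retained
    when their best pChEMBL is strictly greater than ``pchembl_min`` (a pair
    at exactly the threshold is excluded); duplicate pairs collapse keeping
    the maximum pChEMBL.  Rows with a non-numeric pChEMBL are rejected and
    logged.
    """
    import csv

    fh, close, fname = _open(source)
    try:
        reader = csv.DictReader(fh, delimiter=_dialect_delimiter(fname, delimiter))
        if reader.fieldnames is None:
            raise EnrichError("empty actives file")
        for col in ("ligand_id", "uniprot_id", "pchembl"):
            if col not in reader.fieldnames:
                raise EnrichError(f"actives file lacks required column '{col}'")
        best: dict[tuple[str, str], float] = {}
        for row in reader:
            ligand = (row.get("ligand_id") or "").strip()
            acc = (row.get("uniprot_id") or "").strip()
            try:
                p = float((row.get("pchembl") or "").strip())
            except ValueError:
                log.warning("rejected actives row at line %d: non-numeric pChEMBL",
                            reader.line_num)
                continue
            if not ligand or not UNIPROT_RE.match(acc) or not np.isfinite(p):
                log.warning("rejected malformed actives row at line %d",
                            reader.line_num)
                continue
            key = (ligand, acc)
            if p > best.get(key, -np.inf):
                best[key] = p
        return {k for k, p in best.items() if p > pchembl_min}
    finally:
        if close:
            fh.close()


def rank_targets(
    matrix: ScoreMatrix,
    ligand: str,
    actives: Iterable[tuple[str, str]],
    alpha: float = 20.0,
) -> RankedScreen:
    """Rank one ligand's scored targets best-first and label the actives.

    Targets sort by raw score ascending (lower = stronger), ties broken by
    accession so repeated runs are identical.  Actives listed for the ligand
    but absent from the matrix are dropped with a logged count; a ligand
    with no usable active (or no inactive) is fatal.
    """
    if ligand not in matrix.scores.index:
        raise EnrichError(f"unknown ligand {ligand!r}")
    row = matrix.scores.loc[ligand].dropna()
    ligand_actives = {t for (l, t) in actives if l == ligand}
    n_dropped = len(ligand_actives - set(row.index))
    if n_dropped:
        log.info("%s: %d active target(s) absent from the score matrix",
                 ligand, n_dropped)
    order = sorted(row.index, key=lambda t: (row[t], t))
    scores = row[order].to_numpy(float)
    labels = np.array([t in ligand_actives for t in order])
    return RankedScreen(ligand_id=ligand, targets=order, scores=scores,
                        labels=labels, alpha=alpha,
                        n_actives_dropped=n_dropped)


def roc_points(rs: RankedScreen) -> list[tuple[float, float]]:
    """Stepwise ROC points: (FPF, TPF) after each rank threshold, plus (0,0)."""
    tp = np.cumsum(rs.labels)
    fp = np.cumsum(~rs.labels)
    n_a, n_i = rs.n_actives, rs.n - rs.n_actives
    points = [(0.0, 0.0)]
    points.extend(zip(fp / n_i, tp / n_a))
    return [(float(x), float(y)) for x, y in points]


def auc(rs: RankedScreen) -> float:
    """Tie-aware ROC AUC: P(score_active < score_inactive) + half-ties.

    Computed from the raw scores with the Mann-Whitney statistic (identical
    raw scores count 1/2), not from the post-tie-break integer ranks, so the
    value is invariant under the arbitrary accession tie-break and under any
    strictly increasing transform of the scores.
    """
    r = rankdata(rs.scores, method="average")
    n_a = rs.n_actives
    n_i = rs.n - n_a
    u_inactive_first = float(r[rs.labels].sum()) - n_a * (n_a + 1) / 2.0
    return 1.0 - u_inactive_first / (n_a * n_i)


def enrichment_factor(rs: RankedScreen, f: float = 0.10) -> float:
    """EF@f: actives rate in the top ceil(f*N) divided by overall prevalence."""
    if not 0 < f <= 1:
        raise EnrichError(f"fraction must be in (0, 1], got {f}")
    n_top = math.ceil(f * rs.n)
    hits = int(rs.labels[:n_top].sum())
    return (hits / n_top) / rs.ra


def rie(rs: RankedScreen) -> float:
    """Robust initial enhancement at the screen's alpha.

    RIE = [ (1/N_a) sum_i exp(-alpha * r_i / N) ]
          / [ (1/N) * (1 - e^{-alpha}) / (e^{alpha/N} - 1) ],
    i.e. the exponentially rank-weighted actives sum over its expectation for
    a uniformly random ranking.  RIE = 1 means no enrichment.
    """
    a = rs.alpha
    num = float(np.exp(-a * rs.ranks / rs.n).sum()) / rs.n_actives
    denom = (1.0 / rs.n) * (1.0 - math.exp(-a)) / (math.exp(a / rs.n) - 1.0)
    return num / denom


def bedroc(rs: RankedScreen) -> float:
    """BEDROC: RIE mapped onto [0, 1] (Truchon-Bayly scaling).

    BEDROC = RIE * Ra * sinh(a/2) / (cosh(a/2) - cosh(a/2 - a*Ra))
             + 1 / (1 - e^{a (1 - Ra)}),
    clipped to [0, 1].  0 = all actives ranked last, 1 = all ranked first.
    """
    a, ra = rs.alpha, rs.ra
    scale = ra * math.sinh(a / 2) / (math.cosh(a / 2) - math.cosh(a / 2 - a * ra))
    const = 1.0 / (1.0 - math.exp(a * (1.0 - ra)))
    return float(np.clip(rie(rs) * scale + const, 0.0, 1.0))


def total_gain(
    scores: Sequence[float], labels: Sequence[bool], bins: int = 10
) -> float:
    """Predictiveness-curve total gain from raw scores and active flags.

    The score-ranked list (best scores at the highest score-quantile p, by
    convention) is split into ``bins`` equal-count bins; the predictiveness
    R(p) is estimated as each bin's active fraction, and

        TG = sum_b w_b |R_b - pi| / (2 pi (1 - pi)),   w_b = bin size / N,

    with pi the overall prevalence.  0 = labels independent of scores, 1 =
    perfect separation; clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size != labels.size:
        raise EnrichError("scores and labels length mismatch")
    if scores.size < 20:
        raise EnrichError("total gain needs >= 20 targets")
    if labels.all() or not labels.any():
        raise EnrichError("total gain needs both classes present")
    if bins < 1:
        raise EnrichError("bins must be >= 1")
    order = np.argsort(scores, kind="stable")
    sorted_labels = labels[order]
    pi = labels.mean()
    gain = 0.0
    for chunk in np.array_split(sorted_labels, bins):
        if chunk.size == 0:
            continue
        w = chunk.size / labels.size
        gain += w * abs(chunk.mean() - pi)
    return float(np.clip(gain / (2 * pi * (1 - pi)), 0.0, 1.0))


@dataclass
class EnrichmentReport:
    """All retrospective metrics for one ligand's screen."""

    ligand_id: str
    n: int
    n_actives: int
    n_actives_dropped: int
    auc: float
    ef: dict[str, float]
    rie: float
    bedroc: float
    tg: float
    alpha: float
    roc: list[tuple[float, float]] = field(repr=False, default_factory=list)

    @property
    def prevalence(self) -> float:
        return self.n_actives / self.n

    def to_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id,
            "n": self.n,
            "n_actives": self.n_actives,
            "n_actives_dropped": self.n_actives_dropped,
            "auc": self.auc,
            "ef": self.ef,
            "rie": self.rie,
            "bedroc": self.bedroc,
            "tg": self.tg,
            "alpha": self.alpha,
        }

    def roc_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc, columns=["FPF", "TPF"]).to_csv(path, index=False)


def evaluate_ligand(
    matrix: ScoreMatrix,
    ligand: str,
    actives: Iterable[tuple[str, str]],
    alpha: float = 20.0,
    fractions: Sequence[float] = (0.10,),
    bins: int = 10,
) -> EnrichmentReport:
    """Rank one ligand's targets and compute the full metric panel."""
    rs = rank_targets(matrix, ligand, actives, alpha=alpha)
    return EnrichmentReport(
        ligand_id=ligand,
        n=rs.n,
        n_actives=rs.n_actives,
        n_actives_dropped=rs.n_actives_dropped,
        auc=auc(rs),
        ef={f"{f:g}": enrichment_factor(rs, f) for f in fractions},
        rie=rie(rs),
        bedroc=bedroc(rs),
        tg=total_gain(rs.scores, rs.labels, bins=bins),
        alpha=alpha,
        roc=roc_points(rs),
    )
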