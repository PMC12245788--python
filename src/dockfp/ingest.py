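"""Reading docking-score tables and chain-to-protein maps, and aggregating
redundant structures to a ligand x unique-target best-score matrix.

Inverse docking runs score one ligand against many PDB structures.  Several
structures (PDB id + chain) usually resolve to the same protein, so scores
are collapsed to one value per UniProt accession by taking the *best*
(minimum, i.e. most negative) docking score over every structure of that
protein.  Docking scores are in arbitrary units; lower means stronger
predicted binding -- this polarity is fixed package-wide.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
#: UniProt accession: 6 or 10 alphanumerics starting with a letter.
UNIPROT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]{5}(?:[A-Za-z0-9]{4})?$")

Source = Union[str, Path, TextIO]


class IngestError(ValueError):
    """Fatal problem with an input table (missing column, conflicting map...)."""


@dataclass(frozen=True)
class DockingRecord:
    """One docking score for one ligand against one protein chain."""

    ligand_id: str
    pdb_id: str
    chain: str
    score: float


@dataclass
class ParseReport:
    """Valid records plus bookkeeping on rejected rows.

    ``n_rows`` counts data rows seen (header excluded), so
    ``len(records) + n_rejected == n_rows`` always holds.
    """

    records: list[DockingRecord]
    n_rows: int = 0
    n_rejected: int = 0
    rejected_lines: list[int] = field(default_factory=list)


@dataclass
class ChainTargetMap:
    """Functional mapping (pdb_id, chain) -> UniProt accession.

    Optional per-target annotations (free-text name and protein class) ride
    along keyed by accession; they are used only for display grouping.
    """

    mapping: dict[tuple[str, str], str]
    target_name: dict[str, str] = field(default_factory=dict)
    target_class: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, pdb_id: str, chain: str) -> str | None:
        return self.mapping.get((pdb_id, chain))


@dataclass
class ScoreMatrix:
    """Ligand x unique-target matrix of best (minimum) docking scores.

    ``scores`` is a pandas DataFrame with ligand ids as the index and UniProt
    accessions as columns; absent cells (no structure of that protein scored
    for that ligand) are NaN.  ``provenance`` records, per present cell, the
    (pdb_id, chain) that supplied the minimum.
    """

    scores: pd.DataFrame
    provenance: pd.DataFrame | None = None
    n_unmapped: int = 0
    n_used: int = 0

    @property
    def ligands(self) -> list[str]:
        return list(self.scores.index)

    @property
    def targets(self) -> list[str]:
        return list(self.scores.columns)

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path, index_label="ligand_id")

    def provenance_to_csv(self, path: str | Path) -> None:
        if self.provenance is None:
            raise IngestError("matrix carries no provenance")
        self.provenance.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col="ligand_id")
        df.index = df.index.astype(str)
        return cls(scores=df)


def _open(source: Source) -> tuple[TextIO, bool, str | None]:
    if isinstance(source, (str, Path)):
        return open(source, newline=""), True, str(source)
    return source, False, getattr(source, "name", None)


def _dialect_delimiter(name: str | None, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if name and name.lower().endswith((".tsv", ".tab")):
        return "\t"
    return ","


def read_docking_records(
    source: Source,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> ParseReport:
    """Read a long-format docking score table into DockingRecords.

    The table needs a header with columns ``ligand_id, pdb_id, chain, score``
    (names remappable via ``columns``, e.g. ``{"score": "docking_score"}``).
    Rows with a non-numeric or non-finite score, a malformed PDB id, or empty
    identifier fields are rejected individually and counted; a missing
    required column is fatal.  Comma is the default delimiter; ``.tsv`` /
    ``.tab`` paths switch to tabs.
    """
    names = {"ligand_id": "ligand_id", "pdb_id": "pdb_id",
             "chain": "chain", "score": "score"}
    if columns:
        names.update(columns)
    fh, close, fname = _open(source)
    try:
        reader = csv.DictReader(fh, delimiter=_dialect_delimiter(fname, delimiter))
        if reader.fieldnames is None:
            raise IngestError("empty input: no header row")
        missing = [v for v in names.values() if v not in reader.fieldnames]
        if missing:
            raise IngestError(f"missing required column(s): {', '.join(missing)}")
        report = ParseReport(records=[])
        for row in reader:
            report.n_rows += 1
            lineno = reader.line_num
            ligand = (row.get(names["ligand_id"]) or "").strip()
            pdb = (row.get(names["pdb_id"]) or "").strip()
            chain = (row.get(names["chain"]) or "").strip()
            raw_score = (row.get(names["score"]) or "").strip()
            try:
                score = float(raw_score)
            except ValueError:
                score = float("nan")
            if (not ligand or not chain or not PDB_ID_RE.match(pdb)
                    or not np.isfinite(score)):
                report.n_rejected += 1
                report.rejected_lines.append(lineno)
                log.warning("rejected malformed docking row at line %d", lineno)
                continue
            report.records.append(DockingRecord(ligand, pdb, chain, score))
        if report.n_rejected:
            log.warning("rejected %d of %d docking rows",
                        report.n_rejected, report.n_rows)
        return report
    finally:
        if close:
            fh.close()


def read_chain_map(source: Source, delimiter: str | None = None) -> ChainTargetMap:
    """Read the (pdb_id, chain) -> UniProt mapping table.

    Tab is the default delimiter (``.csv`` paths switch to comma).  Duplicate
    identical rows collapse silently; two rows assigning *different*
    accessions to the same (pdb_id, chain) are a fatal inconsistency.
    Optional ``target_name`` / ``target_class`` columns annotate accessions.
    """
    fh, close, fname = _open(source)
    if delimiter is None:
        delimiter = "," if (fname and fname.lower().endswith(".csv")) else "\t"
    try:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise IngestError("empty mapping file")
        for col in ("pdb_id", "chain", "uniprot_id"):
            if col not in reader.fieldnames:
                raise IngestError(f"mapping file lacks required column '{col}'")
        cmap = ChainTargetMap(mapping={})
        for row in reader:
            pdb = (row.get("pdb_id") or "").strip()
            chain = (row.get("chain") or "").strip()
            acc = (row.get("uniprot_id") or "").strip()
            if not pdb or not chain or not UNIPROT_RE.match(acc):
                raise IngestError(
                    f"malformed mapping row at line {reader.line_num}: "
                    f"{pdb!r}/{chain!r} -> {acc!r}")
            key = (pdb, chain)
            prior = cmap.mapping.get(key)
            if prior is not None and prior != acc:
                raise IngestError(
                    f"conflicting mapping for {pdb}/{chain}: {prior} vs {acc}")
            cmap.mapping[key] = acc
            name = (row.get("target_name") or "").strip()
            tclass = (row.get("target_class") or "").strip()
            if name:
                cmap.target_name[acc] = name
            if tclass:
                cmap.target_class[acc] = tclass
        return cmap
    finally:
        if close:
            fh.close()


def aggregate_best(
    records: Iterable[DockingRecord], chain_map: ChainTargetMap
) -> ScoreMatrix:
    """Collapse per-structure scores to the best score per unique protein.

    Structures are grouped by the UniProt accession their (pdb_id, chain)
    maps to, and each (ligand, target) cell takes the minimum score over the
    group, with the winning structure recorded as provenance.  Records whose
    chain is absent from the map are dropped with a warning (the mapping
    database typically covers only a subset of PDB chains); an input with
    zero mappable records is fatal.  Ligand rows and target columns are
    sorted lexicographically, so the result is invariant to input order.
    """
    rows = [(r.ligand_id, r.pdb_id, r.chain, r.score) for r in records]
    if not rows:
        raise IngestError("no docking records supplied")
    df = pd.DataFrame(rows, columns=["ligand_id", "pdb_id", "chain", "score"])
    n_dup = int(df.duplicated(["ligand_id", "pdb_id", "chain"]).sum())
    if n_dup:
        log.warning("%d duplicate (ligand, pdb, chain) records; keeping minima", n_dup)
    df["uniprot_id"] = [
        chain_map.get(p, c) for p, c in zip(df["pdb_id"], df["chain"])
    ]
    unmapped = df["uniprot_id"].isna()
    n_unmapped = int(unmapped.sum())
    if n_unmapped:
        log.warning("dropping %d records with unmapped (pdb_id, chain)", n_unmapped)
    df = df[~unmapped]
    if df.empty:
        raise IngestError("no record maps to any target: nothing to aggregate")
    # idxmin with a deterministic tie-break on (pdb_id, chain)
    df = df.sort_values(["ligand_id", "uniprot_id", "score", "pdb_id", "chain"],
                        kind="mergesort")
    best = df.groupby(["ligand_id", "uniprot_id"], sort=True).head(1)
    wide = best.pivot(index="ligand_id", columns="uniprot_id", values="score")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    wide.index.name = "ligand_id"
    wide.columns.name = "uniprot_id"
    prov = best[["ligand_id", "uniprot_id", "pdb_id", "chain", "score"]]
    prov = prov.sort_values(["ligand_id", "uniprot_id"]).reset_index(drop=True)
    return ScoreMatrix(scores=wide, provenance=prov,
                       n_unmapped=n_unmapped, n_used=len(df))
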