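"""Synthetic docking-score fixtures with planted, recoverable structure.

The generator emulates the statistical shape of a large inverse-docking
campaign without simulating any docking physics:

* per-ligand scores are near-normal with ligand-specific mean and SD
  (different ligands score on different absolute scales, which is exactly
  why fingerprints standardise per ligand);
* each protein target is represented by a variable number of redundant
  structures (1 + shifted-geometric count, parameterised to a median of 4
  structures per target, qualitatively matching the heavy right tail of
  real structure databases); structures of one target share a latent
  (ligand, target) score and differ only by a small jitter, mirroring how
  redundant structures of one binding site yield strongly correlated
  docking scores -- this keeps the per-ligand *aggregated* best-score
  distribution near-normal, as observed in real campaigns;
* ligands belong to structural classes, and each class has a disjoint
  "affinity block" of targets whose mean score is shifted down (stronger)
  by ``block_shift`` ligand-SDs -- the planted signal that downstream
  fingerprint clustering should recover;
* a planted set of active (ligand, target) pairs, on non-block targets so
  enrichment checks are independent of the cluster structure, shifted by
  ``active_shift`` SDs.

Ground truth (classes, blocks, actives) is returned alongside the records so
recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ChainTargetMap, DockingRecord

log = logging.getLogger(__name__)

_B36 = string.digits + string.ascii_uppercase


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults mirror a 14-ligand campaign.

    ``block_shift`` and ``active_shift`` are in units of the ligand's score
    SD.  ``structures_geom_p`` is the success probability of the shifted
    geometric law for structures per target (the default 0.175 yields a
    median of 4); ``struct_jitter`` is the SD of the per-structure score
    spread around the latent (ligand, target) score, again in ligand-SD
    units.  Score units are arbitrary; lower = stronger.
    """

    n_ligands: int = 14
    n_targets: int = 500
    n_classes: int = 2
    class_labels: tuple[int, ...] | None = None  # default: equal split
    block_fraction: float = 0.10
    block_shift: float = 2.0
    mu_range: tuple[float, float] = (-60.0, -45.0)
    sigma_range: tuple[float, float] = (4.0, 6.0)
    structures_geom_p: float = 0.175
    struct_jitter: float = 0.1
    n_actives_per_ligand: int = 25
    active_shift: float = 1.0
    seed: int = 0

    def resolved_classes(self) -> tuple[int, ...]:
        if self.class_labels is not None:
            return self.class_labels
        # equal split, remainder to the earlier classes
        return tuple(i * self.n_classes // self.n_ligands
                     for i in range(self.n_ligands))

    def validate(self) -> None:
        if self.n_targets < 20:
            raise SyntheticError("n_targets must be >= 20")
        if self.n_ligands < 2:
            raise SyntheticError("n_ligands must be >= 2")
        if not 0 < self.block_fraction < 1:
            raise SyntheticError("block_fraction must be in (0, 1)")
        if self.block_shift < 0:
            raise SyntheticError("block_shift must be >= 0")
        if self.active_shift < 0:
            raise SyntheticError("active_shift must be >= 0")
        if not 0 < self.structures_geom_p < 1:
            raise SyntheticError("structures_geom_p must be in (0, 1)")
        if self.struct_jitter < 0:
            raise SyntheticError("struct_jitter must be >= 0")
        labels = self.resolved_classes()
        if len(labels) != self.n_ligands:
            raise SyntheticError("class_labels length must equal n_ligands")
        counts = np.bincount(labels, minlength=self.n_classes)
        if (counts == 0).any():
            raise SyntheticError("every class must contain at least one ligand")
        n_block = int(round(self.block_fraction * self.n_targets))
        if n_block * self.n_classes > self.n_targets:
            raise SyntheticError("block_fraction too large for disjoint blocks")
        if self.n_actives_per_ligand >= self.n_targets - n_block * self.n_classes:
            raise SyntheticError("n_actives_per_ligand too large")


@dataclass
class SyntheticTruth:
    """Planted ground truth echoed back for recovery scoring."""

    ligands: list[str]
    class_of: dict[str, int]
    blocks: dict[int, list[str]]  # class -> block target accessions
    actives: list[tuple[str, str]]
    config: SyntheticConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ligands": self.ligands,
            "class_of": self.class_of,
            "blocks": {str(k): v for k, v in self.blocks.items()},
            "actives": [list(p) for p in self.actives],
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        for key in ("class_labels", "mu_range", "sigma_range"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
        return cls(
            ligands=payload["ligands"],
            class_of={k: int(v) for k, v in payload["class_of"].items()},
            blocks={int(k): list(v) for k, v in payload["blocks"].items()},
            actives=[tuple(p) for p in payload["actives"]],
            config=SyntheticConfig(**cfg),
        )


def _pdb_id(index: int) -> str:
    """Fabricated PDB id: leading digit 1-9 then three base-36 characters."""
    lead, rest = divmod(index, 36 ** 3)
    if lead > 8:
        raise SyntheticError("too many structures for the PDB id space")
    chars = []
    for _ in range(3):
        rest, r = divmod(rest, 36)
        chars.append(_B36[r])
    return str(lead + 1) + "".join(reversed(chars))


def generate(
    config: SyntheticConfig,
) -> tuple[list[DockingRecord], ChainTargetMap, SyntheticTruth]:
    """Draw a synthetic docking campaign; identical seed => identical output.

    Per (ligand, target) latent score:

        N( mu_l - block_shift*sigma_l*[target in ligand-class block]
                - active_shift*sigma_l*[(ligand, target) active],  sigma_l )

    and each structure of the target scores latent + N(0, struct_jitter *
    sigma_l).  The class/active shifts therefore move the mean for every
    structure of the target, so the per-target best score preserves the
    planted signal, and redundant structures stay strongly correlated the
    way repeated structures of one binding site are.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ligands = [f"L{i + 1:02d}" for i in range(config.n_ligands)]
    targets = [f"Q{j + 1:05d}" for j in range(config.n_targets)]
    classes = config.resolved_classes()
    class_of = dict(zip(ligands, classes))

    mu = rng.uniform(*config.mu_range, size=config.n_ligands)
    sigma = rng.uniform(*config.sigma_range, size=config.n_ligands)

    n_block = int(round(config.block_fraction * config.n_targets))
    perm = rng.permutation(config.n_targets)
    blocks: dict[int, list[str]] = {}
    for c in range(config.n_classes):
        picked = perm[c * n_block:(c + 1) * n_block]
        blocks[c] = sorted(targets[j] for j in picked)
    block_targets = {t for ts in blocks.values() for t in ts}
    free = [t for t in targets if t not in block_targets]

    actives: list[tuple[str, str]] = []
    active_set: set[tuple[str, str]] = set()
    for ligand in ligands:
        picked = rng.choice(len(free), size=config.n_actives_per_ligand,
                            replace=False)
        for j in sorted(picked):
            actives.append((ligand, free[j]))
            active_set.add((ligand, free[j]))

    # structures per target: 1 + (geometric over {0,1,...})
    n_struct = 1 + rng.geometric(config.structures_geom_p,
                                 size=config.n_targets) - 1

    records: list[DockingRecord] = []
    mapping: dict[tuple[str, str], str] = {}
    struct_idx = 0
    block_lookup = {(c, t) for c, ts in blocks.items() for t in ts}
    for j, target in enumerate(targets):
        latent = np.empty(config.n_ligands)
        for i, ligand in enumerate(ligands):
            shift = 0.0
            if (classes[i], target) in block_lookup:
                shift += config.block_shift * sigma[i]
            if (ligand, target) in active_set:
                shift += config.active_shift * sigma[i]
            latent[i] = rng.normal(mu[i] - shift, sigma[i])
        for _ in range(int(n_struct[j])):
            pdb = _pdb_id(struct_idx)
            chain = "AB"[struct_idx % 2]
            struct_idx += 1
            mapping[(pdb, chain)] = target
            for i, ligand in enumerate(ligands):
                score = latent[i] + rng.normal(
                    0.0, config.struct_jitter * sigma[i])
                records.append(DockingRecord(ligand, pdb, chain, float(score)))

    truth = SyntheticTruth(ligands=ligands, class_of=class_of, blocks=blocks,
                           actives=actives, config=config)
    return records, ChainTargetMap(mapping=mapping), truth


def write_fixture(
    records: list[DockingRecord],
    chain_map: ChainTargetMap,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write scores.csv, chain_map.tsv, actives.csv and truth.json.

    The files round-trip through the package's own readers; planted actives
    are written with pChEMBL 6.0 so they clear the default > 4 threshold.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": out / "scores.csv",
        "chain_map": out / "chain_map.tsv",
        "actives": out / "actives.csv",
        "truth": out / "truth.json",
    }
    scores = pd.DataFrame(
        [(r.ligand_id, r.pdb_id, r.chain, r.score) for r in records],
        columns=["ligand_id", "pdb_id", "chain", "score"])
    scores.to_csv(paths["scores"], index=False)

    cmap_rows = sorted(
        (pdb, chain, acc) for (pdb, chain), acc in chain_map.mapping.items())
    cm = pd.DataFrame(cmap_rows, columns=["pdb_id", "chain", "uniprot_id"])
    cm.to_csv(paths["chain_map"], sep="\t", index=False)

    act = pd.DataFrame(
        [(l, t, 6.0) for l, t in truth.actives],
        columns=["ligand_id", "uniprot_id", "pchembl"])
    act.to_csv(paths["actives"], index=False)

    truth.to_json(paths["truth"])
    return paths
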