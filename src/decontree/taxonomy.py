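"""BLAST-derived training labels.

Each scaffold is assigned the taxon of its single best BLASTn hit (highest
bitscore; ties broken by lowest e-value, then input order) and labeled
``target`` when the hit's genus matches the configured target genus,
``contaminant`` otherwise. Scaffolds with no hit are ``unknown``: excluded
from training and testing but still classified by a fitted model. Manual
curation hooks (contaminant/target override substrings) handle cases like
known-contaminant strains inside published assemblies of the target clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .cart import CLASS_NAMES

TARGET, CONTAMINANT = CLASS_NAMES
UNKNOWN_LABEL = "No BLAST hit"


@dataclass(frozen=True)
class BlastHit:
    scaffold_id: str
    subject_taxon: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class LabeledDataset:
    """target/contaminant labels plus the excluded unknown set."""

    entries: dict  # scaffold_id -> "target" | "contaminant"
    unknown_ids: set

    def __post_init__(self):
        overlap = set(self.entries) & self.unknown_ids
        if overlap:
            raise ValueError(f"ids both labeled and unknown: {sorted(overlap)[:5]}")
        bad = set(self.entries.values()) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"unknown class labels: {bad}")

    @property
    def labeled_ids(self) -> list[str]:
        return sorted(self.entries)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASS_NAMES}
        for v in self.entries.values():
            counts[v] += 1
        return counts


@dataclass(frozen=True)
class TrainTestSplit:
    train_ids: tuple
    test_ids: tuple
    fraction: float
    seed: int


def read_blast_tsv(path: Union[str, Path]) -> dict:
    """Parse BLAST outfmt-6 rows into per-scaffold hit lists.

    Standard 12 columns are expected; a 13th column, when present, is taken
    as the subject title/taxonomy text (e.g. from ``salltitles`` or
    ``stitle``). Without it, the subject sequence id (column 2) is used as
    the taxon string.
    """
    hits: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})")
            taxon = parts[12] if len(parts) > 12 and parts[12] else parts[1]
            hits.setdefault(parts[0], []).append(
                BlastHit(parts[0], taxon, bitscore, evalue)
            )
    return hits


def select_best_hit(hits: Sequence[BlastHit]) -> Optional[BlastHit]:
    """Single best hit: max bitscore, then min e-value, then input order."""
    if not hits:
        return None
    ids = {h.scaffold_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple scaffolds: {sorted(ids)}")
    best = hits[0]
    for h in hits[1:]:
        if h.bitscore > best.bitscore or (
            h.bitscore == best.bitscore and h.evalue < best.evalue
        ):
            best = h
    return best


def genus_of(taxon: str) -> str:
    """First whitespace-delimited token of the subject taxon text."""
    tokens = taxon.split()
    return tokens[0] if tokens else ""


def assign_labels(
    best_hits: Mapping[str, Optional[BlastHit]],
    target_genus: str,
    contaminant_overrides: Sequence[str] = (),
    target_overrides: Sequence[str] = (),
) -> LabeledDataset:
    """Label scaffolds by genus of their best hit, with curation overrides.

    Precedence: contaminant overrides beat target overrides beat the genus
    rule. Overrides are case-insensitive substring matches against the full
    subject taxon text. A hit matched by overrides on both lists is an
    ambiguous curation and raises.
    """
    if not target_genus:
        raise ValueError("target_genus must be non-empty")
    entries: dict[str, str] = {}
    unknown: set[str] = set()
    tg = target_genus.lower()
    for sid, hit in best_hits.items():
        if hit is None:
            unknown.add(sid)
            continue
        taxon = hit.subject_taxon.lower()
        is_contam = any(p.lower() in taxon for p in contaminant_overrides)
        is_target = any(p.lower() in taxon for p in target_overrides)
        if is_contam and is_target:
            raise ValueError(
                f"ambiguous curation for {sid!r}: {hit.subject_taxon!r} matches "
                "both contaminant and target overrides"
            )
        if is_contam:
            entries[sid] = CONTAMINANT
        elif is_target or genus_of(taxon) == tg:
            entries[sid] = TARGET
        else:
            entries[sid] = CONTAMINANT
    return LabeledDataset(entries=entries, unknown_ids=unknown)


def split_training(
    labeled: LabeledDataset,
    fraction: float,
    seed: int,
    stratify: bool = False,
) -> TrainTestSplit:
    """Random train/test partition of the labeled ids (unknowns never enter).

    |train| = round(fraction * |labeled|), sampled uniformly without
    replacement; deterministic for a fixed seed. Requires both classes
    present among the labels and a non-degenerate split.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    counts = labeled.class_counts()
    absent = [c for c, n in counts.items() if n == 0]
    if absent:
        raise ValueError(f"untrainable: class(es) {absent} absent from labels")
    ids = np.asarray(labeled.labeled_ids)
    rng = np.random.default_rng(seed)
    if stratify:
        train = []
        for c in CLASS_NAMES:
            cids = np.asarray([i for i in ids if labeled.entries[i] == c])
            k = int(round(fraction * len(cids)))
            train.extend(rng.choice(cids, size=k, replace=False).tolist())
        train_set = set(train)
    else:
        k = int(round(fraction * len(ids)))
        train_set = set(rng.choice(ids, size=k, replace=False).tolist())
    if not train_set or len(train_set) == len(ids):
        raise ValueError(
            f"degenerate split: fraction {fraction} of {len(ids)} labeled ids"
        )
    test = tuple(sorted(set(ids) - train_set))
    return TrainTestSplit(
        train_ids=tuple(sorted(train_set)),
        test_ids=test,
        fraction=fraction,
        seed=seed,
    )


def labels_to_indices(labels: Iterable[str]) -> np.ndarray:
    """Map class names to canonical indices (target=0, contaminant=1)."""
    lut = {c: i for i, c in enumerate(CLASS_NAMES)}
    return np.asarray([lut[l] for l in labels], dtype=int)
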