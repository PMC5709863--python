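"""Synthetic contaminated-assembly generator.

Rather than simulating reads and re-assembling, the generator draws the
eight per-scaffold predictor variables directly from class-conditional
distributions that mimic the regimes a decontamination run encounters:

* ``separable`` — GC-rich, low-coverage microbial contaminants in a
  metazoan assembly; target and contaminant separate jointly in GC and
  DNA depth (and coding density).
* ``overlapping`` — a fungal contaminant whose GC range sits inside the
  target's and whose DNA depth matches it; only the RNA-derived
  predictors (gene density) discriminate.
* ``empirical_like`` — the structure of a real contaminated nematode
  assembly: a low-coverage wide-GC bacterial component plus a high-GC
  component at target-like coverage, with noisy labels and a no-hit
  fraction.

Per scaffold: length ~ log-normal; GC ~ uniform on the class range; DNA
depth ~ gamma (mean/sd parameterized); RNA breadth ~ beta (gene density);
RNA depth = breadth x log-normal expression level; DNA breadth saturates
with depth; read GC tracks scaffold GC with noise. A BLAST-labeling
process adds an unknown fraction and optional label flips, and a toy file
bundle (FASTA + depth TSVs + outfmt-6 hits) realizes a drawn table on disk
so the real parsers can be exercised end to end.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .cart import CLASS_NAMES, PREDICTOR_NAMES
from .taxonomy import CONTAMINANT, TARGET, LabeledDataset

PRESET_NAMES = ("separable", "overlapping", "empirical_like")


@dataclass(frozen=True)
class ClassComponent:
    """Distribution parameters of one mixture component of a class."""

    weight: float
    gc_range: tuple  # (low, high), fractions
    dna_depth_mean: float  # reads per base
    dna_depth_sd: float
    rna_breadth_mean: float  # fraction of positions transcribed
    rna_breadth_conc: float  # beta concentration (a + b)
    rna_expr_mean: float  # RNA depth per transcribed base
    length_meanlog: float  # log-normal parameters, bp
    length_sdlog: float
    #: alignability: fraction of depth-saturated breadth actually covered.
    #: Well-assembled sequence sits near 1; fragmented or repeat-rich
    #: scaffolds (under-assembled contaminants) sit lower and patchier.
    dna_align_mean: float = 0.96
    dna_align_conc: float = 52.0

    def __post_init__(self):
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"gc_range must be within [0, 1], got {self.gc_range}")
        if self.dna_depth_mean < 0 or self.dna_depth_sd <= 0:
            raise ValueError("DNA depth mean must be >= 0 and sd > 0")
        if not 0 < self.rna_breadth_mean < 1:
            raise ValueError("rna_breadth_mean must be in (0, 1)")


@dataclass(frozen=True)
class RegimePreset:
    name: str
    target: tuple  # ClassComponents
    contaminant: tuple
    n_target: int
    n_contam: int
    label_noise: float
    unknown_fraction: float
    target_genus: str
    target_taxon: str
    contaminant_taxa: tuple

    def __post_init__(self):
        if self.n_target < 1 or self.n_contam < 1:
            raise ValueError("each class needs at least one scaffold")
        for rate in (self.label_noise, self.unknown_fraction):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")


def _component(d: dict) -> ClassComponent:
    return ClassComponent(
        weight=float(d.get("weight", 1.0)),
        gc_range=tuple(d["gc_range"]),
        dna_depth_mean=float(d["dna_depth_mean"]),
        dna_depth_sd=float(d["dna_depth_sd"]),
        rna_breadth_mean=float(d["rna_breadth_mean"]),
        rna_breadth_conc=float(d["rna_breadth_conc"]),
        rna_expr_mean=float(d["rna_expr_mean"]),
        length_meanlog=float(d["length_meanlog"]),
        length_sdlog=float(d["length_sdlog"]),
        dna_align_mean=float(d.get("dna_align_mean", 0.96)),
        dna_align_conc=float(d.get("dna_align_conc", 52.0)),
    )


def preset_from_dict(d: dict) -> RegimePreset:
    return RegimePreset(
        name=d["name"],
        target=tuple(_component(c) for c in d["target"]),
        contaminant=tuple(_component(c) for c in d["contaminant"]),
        n_target=int(d["n_target"]),
        n_contam=int(d["n_contam"]),
        label_noise=float(d["label_noise"]),
        unknown_fraction=float(d["unknown_fraction"]),
        target_genus=d["target_genus"],
        target_taxon=d["target_taxon"],
        contaminant_taxa=tuple(d["contaminant_taxa"]),
    )


def load_preset(source: Union[str, Path]) -> RegimePreset:
    """A builtin preset by name, or any YAML file with the same schema."""
    if isinstance(source, str) and source in PRESET_NAMES:
        ref = importlib.resources.files("decontree.presets") / f"{source}.yaml"
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    return preset_from_dict(yaml.safe_load(text))


def _component_counts(components, n: int) -> list[int]:
    """Deterministic per-component scaffold counts from mixture weights."""
    weights = np.asarray([c.weight for c in components], dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * n).astype(int)
    for i in np.argsort(-(weights * n - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _draw_class(rng: np.random.Generator, components, n: int) -> pd.DataFrame:
    frames = []
    for comp, k in zip(components, _component_counts(components, n)):
        if k == 0:
            continue
        length = np.maximum(
            np.round(rng.lognormal(comp.length_meanlog, comp.length_sdlog, k)), 250
        )
        gc = rng.uniform(*comp.gc_range, size=k)
        shape = (comp.dna_depth_mean / comp.dna_depth_sd) ** 2
        scale = comp.dna_depth_sd**2 / comp.dna_depth_mean
        dna_depth = rng.gamma(shape, scale, size=k)
        a = comp.rna_breadth_mean * comp.rna_breadth_conc
        b = (1 - comp.rna_breadth_mean) * comp.rna_breadth_conc
        rna_breadth = rng.beta(a, b, size=k)
        expr = rng.lognormal(np.log(comp.rna_expr_mean), 0.5, size=k)
        rna_depth = rna_breadth * expr
        # breadth saturates with depth, scaled by per-scaffold alignability
        aa = comp.dna_align_mean * comp.dna_align_conc
        ab = (1 - comp.dna_align_mean) * comp.dna_align_conc
        dna_breadth = np.clip(
            (1 - np.exp(-0.8 * dna_depth)) * rng.beta(aa, ab, size=k), 0, 1
        )
        dna_read_gc = np.clip(gc + rng.normal(0, 0.01, size=k), 0, 1)
        rna_read_gc = np.clip(gc + rng.normal(0.02, 0.02, size=k), 0, 1)
        frames.append(
            pd.DataFrame(
                {
                    "length": length,
                    "gc": gc,
                    "dna_mean_depth": dna_depth,
                    "rna_mean_depth": rna_depth,
                    "dna_breadth": dna_breadth,
                    "rna_breadth": rna_breadth,
                    "dna_read_gc": dna_read_gc,
                    "rna_read_gc": rna_read_gc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_predictor_table(
    preset: Union[str, RegimePreset],
    seed: int,
    n_target: Optional[int] = None,
    n_contam: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a predictor table plus its ground truth.

    Returns ``(table, truth)``: the table is indexed by scaffold id with
    the eight canonical predictor columns; truth has a ``true_class``
    column over the same index and carries the preset name and seed in
    ``truth.attrs``. Row order is shuffled so class blocks are not
    contiguous.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    nt = preset.n_target if n_target is None else n_target
    nc = preset.n_contam if n_contam is None else n_contam
    if nt < 1 or nc < 1:
        raise ValueError("each class needs at least one scaffold")
    rng = np.random.default_rng(seed)
    tgt = _draw_class(rng, preset.target, nt)
    con = _draw_class(rng, preset.contaminant, nc)
    table = pd.concat([tgt, con], ignore_index=True)
    classes = np.array([TARGET] * nt + [CONTAMINANT] * nc)
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    classes = classes[order]
    ids = [f"scaffold_{i + 1:05d}" for i in range(len(table))]
    table.index = pd.Index(ids, name="scaffold_id")
    truth = pd.DataFrame({"true_class": classes}, index=table.index)
    truth.attrs.update({"preset": preset.name, "seed": seed,
                        "n_target": nt, "n_contam": nc})
    return table, truth


def simulate_blast_labels(
    truth: pd.DataFrame,
    unknown_fraction: float,
    mislabel_rate: float,
    seed: int,
) -> LabeledDataset:
    """Degrade ground truth into BLAST-like labels.

    Each scaffold independently becomes unknown ('No BLAST hit') with
    probability ``unknown_fraction``; surviving labels flip class with
    probability ``mislabel_rate``.
    """
    for rate in (unknown_fraction, mislabel_rate):
        if not 0 <= rate < 1:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    entries, unknown = {}, set()
    flip = {TARGET: CONTAMINANT, CONTAMINANT: TARGET}
    for sid, cls in truth["true_class"].items():
        if rng.random() < unknown_fraction:
            unknown.add(sid)
            continue
        entries[sid] = flip[cls] if rng.random() < mislabel_rate else cls
    if not entries:
        raise ValueError("all scaffolds became unknown; no labels to train on")
    return LabeledDataset(entries=entries, unknown_ids=unknown)


def _exact_gc_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence whose GC count is round(gc * length)."""
    n_gc = int(round(gc * length))
    bases = np.empty(length, dtype="<U1")
    gc_pos = rng.permutation(length)[:n_gc]
    mask = np.zeros(length, dtype=bool)
    mask[gc_pos] = True
    bases[mask] = rng.choice(list("GC"), size=n_gc)
    bases[~mask] = rng.choice(list("AT"), size=length - n_gc)
    return "".join(bases)


def _depth_rows(sid: str, length: int, mean_depth: float, breadth: float,
                read_gc: float):
    """Per-base depth rows realizing the drawn mean and breadth.

    Covered positions are the first round(breadth * length) bases; the
    total depth round(mean * length) is spread as evenly as possible over
    them (each covered base gets at least 1).
    """
    covered = int(round(breadth * length))
    total = int(round(mean_depth * length))
    covered = min(covered, total)
    if covered == 0:
        return
    base, extra = divmod(total, covered)
    for pos in range(1, covered + 1):
        yield sid, pos, base + (1 if pos <= extra else 0), read_gc


def simulate_toy_assembly(
    preset: Union[str, RegimePreset],
    seed: int,
    out_dir: Union[str, Path],
    n_target: int = 10,
    n_contam: int = 10,
) -> dict:
    """Write a small, fully consistent file bundle for end-to-end runs.

    Scaffold lengths are redrawn at toy scale (a few hundred bp). The
    bundle contains ``assembly.fasta`` (sequences realizing each drawn GC
    exactly, up to rounding), ``dna.depth.tsv`` / ``rna.depth.tsv``
    (per-base depth dialect with a read_gc column), ``hits.tsv`` (BLAST
    outfmt 6 + subject title realizing the simulated labels) and
    ``truth.tsv``. Re-deriving the predictor table from these files
    reproduces the drawn table up to rounding. Deterministic per seed.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_predictor_table(preset, seed, n_target, n_contam)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]).generate_state(1)[0])
    # toy-scale lengths, deterministic given the seed
    lengths = rng.integers(300, 800, size=len(table))
    table = table.copy()
    table["length"] = lengths.astype(float)

    fasta = out / "assembly.fasta"
    with open(fasta, "w") as fh:
        for sid, row in table.iterrows():
            seq = _exact_gc_sequence(rng, int(row["length"]), row["gc"])
            # keep the table exactly consistent with the written sequence
            table.loc[sid, "gc"] = seq.count("G") + seq.count("C")
            table.loc[sid, "gc"] /= len(seq)
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    for kind in ("dna", "rna"):
        with open(out / f"{kind}.depth.tsv", "w") as fh:
            fh.write("scaffold_id\tpos\tdepth\tread_gc\n")
            for sid, row in table.iterrows():
                for rec in _depth_rows(
                    sid, int(row["length"]), row[f"{kind}_mean_depth"],
                    row[f"{kind}_breadth"], row[f"{kind}_read_gc"],
                ):
                    fh.write("%s\t%d\t%d\t%.6f\n" % rec)

    labels = simulate_blast_labels(
        truth, preset.unknown_fraction, preset.label_noise, seed + 1
    )
    with open(out / "hits.tsv", "w") as fh:
        for i, sid in enumerate(table.index):
            if sid in labels.unknown_ids:
                continue
            taxon = (
                preset.target_taxon
                if labels.entries[sid] == TARGET
                else preset.contaminant_taxa[i % len(preset.contaminant_taxa)]
            )
            fh.write(
                "\t".join(
                    [sid, f"subj_{i:04d}", "98.5", "200", "3", "0", "1", "200",
                     "1", "200", "1e-50", "370.0", taxon]
                )
                + "\n"
            )

    truth.to_csv(out / "truth.tsv", sep="\t")
    return {
        "fasta": fasta,
        "dna_depth": out / "dna.depth.tsv",
        "rna_depth": out / "rna.depth.tsv",
        "hits": out / "hits.tsv",
        "truth": out / "truth.tsv",
        "table": table,
        "truth_table": truth,
        "labels": labels,
    }
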