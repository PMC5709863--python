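"""End-to-end decontamination workflow.

Given an assembly FASTA, DNA/RNA alignment evidence and BLAST tabular
results, the pipeline computes the eight predictor variables, derives
target/contaminant/unknown labels, trains a model on a random fraction of
the labeled scaffolds, reports held-out test metrics, classifies every
scaffold (including those with no BLAST hit), and writes the kept FASTA,
the removed-id list, a per-scaffold report TSV and a machine-readable run
manifest.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .cart import CLASS_NAMES, PREDICTOR_NAMES
from .evaluation import confusion, metrics
from .models import make_model
from .predictors import (
    AlignmentFilter,
    build_predictor_table,
    compute_scaffold_stats,
    load_alignment_evidence,
    write_predictor_table,
)
from .taxonomy import (
    CONTAMINANT,
    TARGET,
    assign_labels,
    read_blast_tsv,
    select_best_hit,
    split_training,
)

REPORT_COLUMNS = (
    ("scaffold_id",)
    + PREDICTOR_NAMES
    + ("label_source", "predicted_class", "target_score")
)

#: Exit codes surfaced by the CLI for distinct failure modes.
EXIT_MISSING_INPUT = 3
EXIT_EMPTY_LABELS = 4
EXIT_SINGLE_CLASS = 5


class MissingInputError(FileNotFoundError):
    exit_code = EXIT_MISSING_INPUT


class EmptyLabelsError(ValueError):
    exit_code = EXIT_EMPTY_LABELS


class SingleClassError(ValueError):
    exit_code = EXIT_SINGLE_CLASS


@dataclass
class RunConfig:
    """Inputs, curation and model settings for one decontamination run."""

    fasta: str
    dna_evidence: str
    rna_evidence: str
    blast_tsv: str
    out_dir: str
    target_genus: str
    contaminant_overrides: tuple = ()
    target_overrides: tuple = ()
    train_fraction: float = 0.5
    model_kind: str = "bagging"
    model_params: dict = field(default_factory=dict)
    seed: int = 0
    exclude_read_groups: tuple = ()

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("contaminant_overrides", "target_overrides",
                    "exclude_read_groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def validate(self) -> None:
        for key in ("fasta", "dna_evidence", "rna_evidence", "blast_tsv"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise MissingInputError(f"{key} does not exist: {p}")


@dataclass
class ClassificationReport:
    """Per-scaffold classifications plus run-level summary."""

    rows: pd.DataFrame  # indexed by scaffold_id, REPORT_COLUMNS[1:]
    kept: int
    removed: int
    kept_mb: float
    removed_mb: float
    test_metrics: dict

    def summary_text(self) -> str:
        m = self.test_metrics
        lines = [
            f"scaffolds kept:    {self.kept} ({self.kept_mb:.2f} Mb)",
            f"scaffolds removed: {self.removed} ({self.removed_mb:.2f} Mb)",
            "held-out test metrics (BLAST-labeled scaffolds only):",
        ]
        for k in ("accuracy", "error", "sensitivity", "specificity"):
            v = m.get(k)
            lines.append(f"  {k:<12s} {'undefined' if v is None else f'{v:.4f}'}")
        return "\n".join(lines)


def write_report(report: ClassificationReport, path: Union[str, Path]) -> None:
    df = report.rows.reset_index()
    df = df[list(REPORT_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report is missing column(s): {sorted(missing)}")
    return df.set_index("scaffold_id")


def run_decontam(config: RunConfig) -> ClassificationReport:
    """Execute the full workflow and write all outputs under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stats = compute_scaffold_stats(config.fasta)
    opts = AlignmentFilter(exclude_read_groups=tuple(config.exclude_read_groups))
    dna = load_alignment_evidence(config.dna_evidence, stats, opts)
    rna = load_alignment_evidence(config.rna_evidence, stats, opts)
    table = build_predictor_table(stats, dna, rna)
    write_predictor_table(table, out / "predictors.tsv")

    hits = read_blast_tsv(config.blast_tsv)
    best = {s.scaffold_id: select_best_hit(hits.get(s.scaffold_id, []))
            for s in stats}
    labeled = assign_labels(best, config.target_genus,
                            config.contaminant_overrides,
                            config.target_overrides)
    counts = labeled.class_counts()
    if not labeled.entries:
        raise EmptyLabelsError("no scaffold received a BLAST-derived label")
    if min(counts.values()) == 0:
        raise SingleClassError(f"labels contain a single class: {counts}")

    split = split_training(labeled, config.train_fraction, config.seed)
    labels = pd.Series(labeled.entries)
    model = make_model(config.model_kind, table.loc[list(split.train_ids)],
                       labels.loc[list(split.train_ids)],
                       seed=config.seed, **config.model_params)
    res = model.fit()
    res.save(out / "model.json")

    test_ids = list(split.test_ids)
    test_metrics = metrics(confusion(res.predict(table.loc[test_ids]),
                                     labels.loc[test_ids]))

    scored = res.score_table(table)
    source = pd.Series("no-hit", index=table.index, name="label_source")
    for sid, cls in labeled.entries.items():
        source[sid] = f"blast-{cls}"
    rows = table.copy()
    rows["label_source"] = source
    rows["predicted_class"] = scored["predicted_class"]
    rows["target_score"] = scored["target_score"]

    keep_mask = rows["predicted_class"] == TARGET
    kept_ids = set(rows.index[keep_mask])
    with open(out / "kept.fasta", "w") as fh:
        for rec in SeqIO.parse(config.fasta, "fasta"):
            if rec.id in kept_ids:
                SeqIO.write(rec, fh, "fasta")
    (out / "removed_ids.txt").write_text(
        "".join(f"{sid}\n" for sid in rows.index[~keep_mask])
    )

    report = ClassificationReport(
        rows=rows,
        kept=int(keep_mask.sum()),
        removed=int((~keep_mask).sum()),
        kept_mb=float(rows.loc[keep_mask, "length"].sum() / 1e6),
        removed_mb=float(rows.loc[~keep_mask, "length"].sum() / 1e6),
        test_metrics={
            "accuracy": test_metrics.accuracy,
            "error": test_metrics.error,
            "sensitivity": test_metrics.sensitivity,
            "specificity": test_metrics.specificity,
            "n_test": len(test_ids),
        },
    )
    write_report(report, out / "report.tsv")
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_scaffolds": len(table),
        "label_counts": counts,
        "n_unknown": len(labeled.unknown_ids),
        "kept": report.kept,
        "removed": report.removed,
        "kept_mb": round(report.kept_mb, 2),
        "removed_mb": round(report.removed_mb, 2),
        "test_metrics": report.test_metrics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report
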