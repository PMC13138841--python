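"""Readers and writers for the pipeline's external formats.

Formats touched: TSV/GAF annotation tables, HDF5 embedding stores
(groups ``/seq``, ``/dom``, ``/label`` keyed by entity id, float32),
CAFA-style prediction TSV (3-decimal scores on disk, full precision in
memory), FASTA sequences, YAML run configs and JSON reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ontology import AnnotationTable, LabelPartition

__all__ = [
    "EmbeddingSet",
    "RunConfig",
    "read_annotations",
    "write_annotations",
    "write_embeddings",
    "read_embeddings",
    "read_fasta",
    "write_fasta",
    "write_predictions",
    "read_predictions",
    "write_partition",
    "read_run_config",
]

MODALITIES = ("seq", "dom", "label")


@dataclass
class EmbeddingSet:
    """Pooled embedding vectors keyed by entity id, one dict per modality.

    ``seq`` and ``dom`` are keyed by protein id, ``label`` by GO term id.
    Encoders run at most once per entity: everything downstream (training,
    batched inference) reads these persisted vectors.
    """

    seq: dict[str, np.ndarray] = field(default_factory=dict)
    dom: dict[str, np.ndarray] = field(default_factory=dict)
    label: dict[str, np.ndarray] = field(default_factory=dict)


def write_embeddings(path, embeddings: EmbeddingSet) -> None:
    """Persist to HDF5 (float32, one dataset per entity id per modality)."""
    with h5py.File(path, "w") as fh:
        for modality in MODALITIES:
            grp = fh.create_group(modality)
            for key, vec in getattr(embeddings, modality).items():
                grp.create_dataset(key, data=np.asarray(vec, dtype=np.float32))


def read_embeddings(path, expected_widths: dict[str, int] | None = None) -> EmbeddingSet:
    """Load an HDF5 embedding store; optionally check per-modality widths."""
    out = EmbeddingSet()
    with h5py.File(path, "r") as fh:
        for modality in MODALITIES:
            if modality not in fh:
                continue
            store = getattr(out, modality)
            for key in fh[modality]:
                vec = fh[modality][key][()]
                if expected_widths and modality in expected_widths:
                    if vec.shape[0] != expected_widths[modality]:
                        raise ValueError(
                            f"{modality}/{key}: width {vec.shape[0]} != "
                            f"configured {expected_widths[modality]}"
                        )
                store[key] = vec
    return out


def read_annotations(path, fmt: str = "tsv", namespace: str = "BP") -> AnnotationTable:
    """Read a protein→GO mapping from TSV (protein_id, go_id) or GAF 2.x.

    GAF: column 2 (DB object id) and column 5 (GO id) are used; rows with a
    ``NOT`` qualifier (column 4) are skipped, as are comment lines.
    Duplicates are collapsed.
    """
    mapping: dict[str, set[str]] = {}
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(
                f"expected ≥2 tab-separated columns in {path}; "
                f"first row: {df.iloc[0].tolist()}"
            )
        for protein, term in zip(df[0], df[1]):
            mapping.setdefault(protein, set()).add(term)
    elif fmt == "gaf":
        df = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
        if df.shape[1] < 5:
            raise ValueError(
                f"GAF needs ≥5 columns, got {df.shape[1]} in {path}; "
                f"first row: {df.iloc[0].tolist()}"
            )
        for _, row in df.iterrows():
            qualifier = row[3] if not pd.isna(row[3]) else ""
            if "NOT" in str(qualifier).split("|"):
                continue
            mapping.setdefault(row[1], set()).add(row[4])
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return AnnotationTable(mapping, namespace)


def write_annotations(path, table: AnnotationTable) -> None:
    with open(path, "w") as fh:
        for protein in sorted(table.annotations):
            for term in sorted(table.annotations[protein]):
                fh.write(f"{protein}\t{term}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_predictions(path, scores) -> None:
    """CAFA-style prediction TSV: protein_id, go_id, score (3 decimals)."""
    with open(path, "w") as fh:
        for i, protein in enumerate(scores.protein_ids):
            for j, term in enumerate(scores.term_ids):
                fh.write(f"{protein}\t{term}\t{scores.values[i, j]:.3f}\n")


def read_predictions(path):
    from .evaluation import ScoreMatrix

    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "term", "score"])
    proteins = sorted(df["protein"].unique())
    terms = sorted(df["term"].unique())
    p_idx = {p: i for i, p in enumerate(proteins)}
    t_idx = {t: j for j, t in enumerate(terms)}
    values = np.zeros((len(proteins), len(terms)))
    for protein, term, score in df.itertuples(index=False):
        values[p_idx[protein], t_idx[term]] = score
    return ScoreMatrix(values, proteins, terms)


def write_partition(path, partition: LabelPartition) -> None:
    """Label partition as TSV with a category column."""
    with open(path, "w") as fh:
        fh.write("go_id\tcategory\n")
        for category in ("shared", "unseen", "training_only", "zero_shot"):
            for term in sorted(getattr(partition, category)):
                fh.write(f"{term}\t{category}\n")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for a train/predict/evaluate run."""

    namespace: str = "BP"
    seed: int = 0
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    loss: dict = field(default_factory=dict)  # LossConfig overrides
    training: dict = field(default_factory=dict)  # TrainConfig overrides
    evaluation: dict = field(default_factory=dict)  # postprocess, aupr_mode, ...
    paths: dict = field(default_factory=dict)

    def require_paths_exist(self) -> None:
        missing = [
            f"{k}: {v}" for k, v in self.paths.items() if not Path(v).exists()
        ]
        if missing:
            raise FileNotFoundError("missing inputs: " + "; ".join(missing))


def read_run_config(path, check_paths: bool = True) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        namespace=raw.get("namespace", "BP"),
        seed=int(raw.get("seed", 0)),
        model=raw.get("model", {}),
        loss=raw.get("loss", {}),
        training=raw.get("training", {}),
        evaluation=raw.get("evaluation", {}),
        paths=raw.get("paths", {}),
    )
    if check_paths:
        cfg.require_paths_exist()
    return cfg


def write_report(path, report) -> None:
    with open(path, "w") as fh:
        fh.write(report.to_json())


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
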