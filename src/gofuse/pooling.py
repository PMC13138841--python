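"""Pooling of token-level encoder output into fixed-length modality vectors.

Any encoder (a protein language model for sequences, a text embedding model
for GO definitions and domain descriptions) produces one embedding row per
token. Downstream, the fusion model consumes exactly three fixed-length
vectors per protein–term pair:

* ``E_seq`` — arithmetic mean over residue embeddings,
* ``E_label`` — arithmetic mean over the GO definition's token embeddings,
* ``E_dom`` — two-level mean: tokens are averaged within each domain
  description first, then the per-domain vectors are averaged; a protein
  with no annotated domains gets an all-zero placeholder.

Token matrices are assumed to exclude padding and special tokens (BOS/EOS/
CLS); adapters are responsible for stripping those rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TokenEmbeddingMatrix",
    "ModalityVector",
    "EmbeddingTriple",
    "EncoderAdapter",
    "mean_pool",
    "pool_domains",
    "build_triple",
]


@dataclass(frozen=True)
class TokenEmbeddingMatrix:
    """Per-token embedding rows for one sequence or text."""

    rows: np.ndarray  # (n_tokens, width)
    source_tag: str = "sequence"  # sequence | label_text | domain_text

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 2:
            raise ValueError(f"token matrix must be 2-D, got shape {rows.shape}")
        if not np.all(np.isfinite(rows)):
            raise ValueError("token matrix contains non-finite values")
        object.__setattr__(self, "rows", rows)

    @property
    def width(self) -> int:
        return self.rows.shape[1]


@dataclass(frozen=True)
class ModalityVector:
    values: np.ndarray
    modality: str  # seq | dom | label

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("modality vector must be a finite 1-D array")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EmbeddingTriple:
    """The model's input unit: pooled (E_seq, E_dom, E_label) for one pair."""

    e_seq: np.ndarray
    e_dom: np.ndarray
    e_label: np.ndarray


@dataclass(frozen=True)
class EncoderAdapter:
    """Contract for plugging in an external encoder.

    ``encode`` maps raw text or an amino-acid sequence to a
    :class:`TokenEmbeddingMatrix` of constant ``width``; it must be
    deterministic for a fixed input and must strip special-token rows.
    """

    encode: Callable[[str], TokenEmbeddingMatrix]
    width: int


def mean_pool(tokens: TokenEmbeddingMatrix) -> ModalityVector:
    """Average the token rows into one vector.

    Raises on an empty matrix: absent data is only legal for the domain
    modality, which goes through :func:`pool_domains`' placeholder path.
    """
    if tokens.rows.shape[0] == 0:
        raise ValueError("cannot mean-pool an empty token matrix")
    modality = {"sequence": "seq", "label_text": "label", "domain_text": "dom"}.get(
        tokens.source_tag, "seq"
    )
    return ModalityVector(tokens.rows.mean(axis=0), modality)


def pool_domains(
    domain_matrices: Sequence[TokenEmbeddingMatrix], d_text: int
) -> ModalityVector:
    """Two-level mean pooling of a protein's domain descriptions.

    Each domain's tokens are averaged first, then the per-domain vectors are
    averaged, so a short domain description carries the same weight as a long
    one. An empty list yields the zero-vector placeholder of width ``d_text``.
    """
    if len(domain_matrices) == 0:
        return ModalityVector(np.zeros(d_text), "dom")
    widths = {m.width for m in domain_matrices}
    if widths != {d_text}:
        raise ValueError(f"domain matrices have widths {sorted(widths)}, expected {d_text}")
    per_domain = np.stack([m.rows.mean(axis=0) for m in domain_matrices])
    return ModalityVector(per_domain.mean(axis=0), "dom")


def build_triple(
    seq_tokens: TokenEmbeddingMatrix,
    domain_matrices: Sequence[TokenEmbeddingMatrix],
    label_tokens: TokenEmbeddingMatrix,
    d_text: int | None = None,
) -> EmbeddingTriple:
    """Pool all three modalities for one protein–term pair."""
    if d_text is None:
        d_text = label_tokens.width
    e_seq = mean_pool(seq_tokens)
    e_dom = pool_domains(domain_matrices, d_text)
    e_label = mean_pool(label_tokens)
    return EmbeddingTriple(e_seq.values, e_dom.values, e_label.values)
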