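"""Fully synthetic multimodal worlds for end-to-end testing without any
external encoder or database.

The generative story: each GO-like term ``t`` owns a latent semantic vector
``z_t`` (i.i.d. standard normal). A protein's latent position is the mean of
the ``z_t`` of its annotated terms. Three fixed random linear maps (one per
modality) project latents into observation spaces, scaled by an alignment
strength ``s`` and corrupted with isotropic Gaussian noise ``σ``:

* ``E_label(t) = s·A_text z_t + σ·ε``
* ``E_seq(p)  = s·A_seq mean_t(z_t) + σ·ε``
* ``E_dom(p)  = s·A_text mean_t(z_t) + σ·ε`` (zeroed with the missing-domain
  probability, mirroring that not every protein has domain annotations)

Domain descriptions and label definitions share one map ``A_text`` because a
single text encoder embeds both in the real pipeline — this is what makes a
domain vector directly comparable (cosine) to a label vector. The sequence
modality has its own map ``A_seq``: a different encoder, a different space.

Under this world, "semantic similarity implies functional match" holds by
construction, which is exactly the structure a zero-shot matcher must
exploit: a held-out term's label embedding lives in the same latent space,
so a model that learned the cross-modal map can score it sensibly despite
never seeing it as a training label.

This is a modelling convenience, not a claim about real encoder geometry:
real embedding spaces are anisotropic and real annotation sets follow GO's
topology, neither of which is emulated here.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import EmbeddingSet
from .ontology import AnnotationTable, OntologyGraph, Term, propagate_true_path
from .pooling import EncoderAdapter, TokenEmbeddingMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "WorldView",
    "generate_world",
    "split_zero_shot",
    "toy_identity_filter",
    "kmer_identity",
    "random_protein_sequences",
    "one_hot_labels",
    "synthetic_encoder",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generated world.

    Defaults give a CPU-scale zero-shot benchmark: 2000 proteins, 50 terms
    of which a fifth are held out as "new", perfect latent alignment (s=1)
    with mild noise (σ=0.1), ~4 annotations per protein, and a fifth of
    proteins lacking domain information.
    """

    n_proteins: int = 2000
    n_terms: int = 50
    latent_dim: int = 16
    d_seq: int = 64
    d_text: int = 96
    alignment: float = 1.0  # s ∈ [0, 1]
    noise: float = 0.1  # σ ≥ 0
    mean_annotations: float = 3.0  # λ of the Poisson(λ)+1 annotation count
    zero_shot_fraction: float = 0.2
    test_protein_fraction: float = 0.2
    missing_domain_prob: float = 0.2
    with_dag: bool = False
    namespace: str = "BP"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_proteins, self.n_terms, self.latent_dim, self.d_seq, self.d_text) < 1:
            raise ValueError("all counts and widths must be positive")
        for name in ("alignment", "zero_shot_fraction", "test_protein_fraction",
                     "missing_domain_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.mean_annotations >= self.n_terms:
            raise ValueError("mean_annotations must be < n_terms")


@dataclass
class WorldView:
    """One side (train or test) of a zero-shot split."""

    annotations: AnnotationTable
    proteins: list[str]
    term_universe: set[str]


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    term_ids: list[str]
    protein_ids: list[str]
    latents: np.ndarray  # (n_terms, latent_dim)
    annotations: AnnotationTable
    embeddings: EmbeddingSet
    train_proteins: list[str]
    test_proteins: list[str]
    zero_shot_terms: set[str]
    graph: OntologyGraph | None = None
    token_matrices: dict = field(default_factory=dict)

    def make_ontology_pair(self) -> tuple[OntologyGraph, OntologyGraph]:
        """Toy old/new ontology releases: the held-out terms exist only in
        the new release, so they satisfy the temporal zero-shot definition."""
        new = self.graph if self.graph is not None else _edgeless_graph(
            self.term_ids, self.config.namespace, "new"
        )
        old = OntologyGraph(namespace=new.namespace, version_tag="old")
        for tid, term in new.terms.items():
            if tid in self.zero_shot_terms:
                continue
            old.terms[tid] = term
            old.dag.add_node(tid)
        for child, parent in new.dag.edges:
            if child in old.dag and parent in old.dag:
                old.dag.add_edge(child, parent)
        return old, new


def _edgeless_graph(term_ids, namespace, tag) -> OntologyGraph:
    g = OntologyGraph(namespace=namespace, version_tag=tag)
    for tid in term_ids:
        g.terms[tid] = Term(id=tid)
        g.dag.add_node(tid)
    return g


def _toy_dag(term_ids: list[str], namespace: str, rng) -> OntologyGraph:
    """Random tree: term 0 is the root, every later term picks one parent."""
    g = _edgeless_graph(term_ids, namespace, "new")
    for i in range(1, len(term_ids)):
        parent = int(rng.integers(0, i))
        g.dag.add_edge(term_ids[i], term_ids[parent])
    return g


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Draw one complete world from the seed; bitwise-reproducible."""
    rng = np.random.default_rng(cfg.seed)
    term_ids = [f"GO:{i:07d}" for i in range(1, cfg.n_terms + 1)]
    protein_ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]

    graph = _toy_dag(term_ids, cfg.namespace, rng) if cfg.with_dag else None

    z = rng.standard_normal((cfg.n_terms, cfg.latent_dim))
    a_seq = rng.normal(0, 1 / np.sqrt(cfg.latent_dim), (cfg.latent_dim, cfg.d_seq))
    # one shared text-space map: domain texts and label definitions are
    # embedded by the same encoder in the real pipeline
    a_text = rng.normal(0, 1 / np.sqrt(cfg.latent_dim), (cfg.latent_dim, cfg.d_text))

    # annotations: Poisson(λ)+1 distinct terms per protein
    raw: dict[str, set[str]] = {}
    for pid in protein_ids:
        k = min(int(rng.poisson(cfg.mean_annotations)) + 1, cfg.n_terms)
        chosen = rng.choice(cfg.n_terms, size=k, replace=False)
        raw[pid] = {term_ids[i] for i in chosen}
    annotations = AnnotationTable(raw, cfg.namespace)
    if graph is not None:
        annotations = propagate_true_path(annotations, graph)

    term_index = {t: i for i, t in enumerate(term_ids)}
    s, sigma = cfg.alignment, cfg.noise
    label_emb = s * (z @ a_text) + sigma * rng.standard_normal(
        (cfg.n_terms, cfg.d_text)
    )
    seq_emb = np.empty((cfg.n_proteins, cfg.d_seq))
    dom_emb = np.empty((cfg.n_proteins, cfg.d_text))
    has_domains = rng.uniform(size=cfg.n_proteins) >= cfg.missing_domain_prob
    for i, pid in enumerate(protein_ids):
        mean_z = z[[term_index[t] for t in annotations.annotations[pid]]].mean(axis=0)
        seq_emb[i] = s * (mean_z @ a_seq) + sigma * rng.standard_normal(cfg.d_seq)
        if has_domains[i]:
            dom_emb[i] = s * (mean_z @ a_text) + sigma * rng.standard_normal(cfg.d_text)
        else:
            dom_emb[i] = 0.0

    embeddings = EmbeddingSet(
        seq={p: seq_emb[i] for i, p in enumerate(protein_ids)},
        dom={p: dom_emb[i] for i, p in enumerate(protein_ids)},
        label={t: label_emb[i] for i, t in enumerate(term_ids)},
    )

    # held-out ("new") terms: leaves only when a DAG is present, so the old
    # release stays a valid sub-DAG
    n_held = int(round(cfg.zero_shot_fraction * cfg.n_terms))
    if graph is not None:
        candidates = [t for t in term_ids if graph.dag.in_degree(t) == 0]
    else:
        candidates = list(term_ids)
    n_held = min(n_held, len(candidates))
    held = rng.choice(len(candidates), size=n_held, replace=False)
    zero_shot_terms = {candidates[i] for i in held}

    n_test = int(round(cfg.test_protein_fraction * cfg.n_proteins))
    perm = rng.permutation(cfg.n_proteins)
    test_proteins = [protein_ids[i] for i in sorted(perm[:n_test])]
    train_proteins = [protein_ids[i] for i in sorted(perm[n_test:])]

    return SyntheticWorld(
        config=cfg,
        term_ids=term_ids,
        protein_ids=protein_ids,
        latents=z,
        annotations=annotations,
        embeddings=embeddings,
        train_proteins=train_proteins,
        test_proteins=test_proteins,
        zero_shot_terms=zero_shot_terms,
        graph=graph,
    )


def make_token_matrices(
    targets: dict[str, np.ndarray], rng, min_tokens: int = 3, max_tokens: int = 8
) -> dict[str, TokenEmbeddingMatrix]:
    """Token matrices whose rows mean-pool (to rounding) to the targets."""
    out = {}
    for key, target in targets.items():
        n_tok = int(rng.integers(min_tokens, max_tokens + 1))
        rows = rng.standard_normal((n_tok, target.shape[0]))
        rows = rows - rows.mean(axis=0) + target
        out[key] = TokenEmbeddingMatrix(rows)
    return out


def split_zero_shot(
    world: SyntheticWorld,
    fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[WorldView, WorldView]:
    """Build disjoint train/test views with the zero-shot terms held out.

    Held-out terms are erased from the training annotations and the training
    term universe; test proteins are disjoint from training proteins and keep
    their full annotation sets (including held-out terms).
    """
    if fraction is None:
        held = set(world.zero_shot_terms)
    else:
        rng = rng or np.random.default_rng(world.config.seed + 1)
        n_held = int(round(fraction * world.config.n_terms))
        if fraction > 0 and n_held == 0:
            raise ValueError("fraction leaves no held-out term")
        candidates = (
            [t for t in world.term_ids if world.graph.dag.in_degree(t) == 0]
            if world.graph is not None
            else list(world.term_ids)
        )
        idx = rng.choice(len(candidates), size=min(n_held, len(candidates)), replace=False)
        held = {candidates[i] for i in idx}

    train_universe = set(world.term_ids) - held
    train_ann = AnnotationTable(
        {
            p: world.annotations.annotations[p]
            for p in world.train_proteins
        },
        world.config.namespace,
    ).restrict_terms(train_universe)
    if not train_ann.annotations:
        raise ValueError("hold-out fraction leaves no training positives")
    test_ann = AnnotationTable(
        {p: world.annotations.annotations[p] for p in world.test_proteins},
        world.config.namespace,
    )
    return (
        WorldView(train_ann, list(train_ann.annotations), train_universe),
        WorldView(test_ann, list(test_ann.annotations), set(world.term_ids)),
    )


# --------------------------------------------------------------------- tools
def random_protein_sequences(
    ids, rng, min_len: int = 50, max_len: int = 200
) -> dict[str, str]:
    """Uniform-random amino-acid strings (toy sequences for format tests)."""
    out = {}
    for pid in ids:
        n = int(rng.integers(min_len, max_len + 1))
        out[pid] = "".join(rng.choice(AMINO_ACIDS, size=n))
    return out


def kmer_identity(a: str, b: str, k: int = 3) -> float:
    """Shared k-mer containment |K(a) ∩ K(b)| / min(|K(a)|, |K(b)|).

    A crude stand-in for alignment-based percent identity, adequate only for
    synthetic sequences; real pipelines should supply a precomputed table.
    """
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def toy_identity_filter(
    test_records: dict[str, str],
    train_records: dict[str, str],
    identity_table: dict[tuple[str, str], float] | None = None,
    cutoff: float = 0.30,
) -> list[str]:
    """Homology reduction: drop test proteins with identity strictly above
    ``cutoff`` against any training protein.

    With a precomputed ``identity_table`` (keys ``(test_id, train_id)``),
    missing pairs count as identity 0 (with a warning); otherwise identities
    are estimated by 3-mer containment on the sequences themselves.
    """
    if identity_table is not None:
        bad = [v for v in identity_table.values() if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError("identity values must lie in [0, 1]")
    retained = []
    missing = 0
    for tid, tseq in test_records.items():
        max_ident = 0.0
        for rid, rseq in train_records.items():
            if identity_table is not None:
                if (tid, rid) in identity_table:
                    ident = identity_table[(tid, rid)]
                else:
                    ident = 0.0
                    missing += 1
            else:
                ident = kmer_identity(tseq, rseq)
            max_ident = max(max_ident, ident)
        if not max_ident > cutoff:  # strict: "over 30%" is removed
            retained.append(tid)
    if missing:
        warnings.warn(f"{missing} test/train pairs missing from identity table; treated as 0")
    return retained


def one_hot_labels(term_ids: list[str], d_text: int) -> dict[str, np.ndarray]:
    """One-hot label 'embeddings' (the identifier-only ablation).

    Stripping the semantics from the label modality: each term becomes an
    arbitrary basis vector, so nothing ties an unseen term to any protein.
    """
    if len(term_ids) > d_text:
        raise ValueError("d_text too small for one-hot encoding")
    out = {}
    for i, t in enumerate(term_ids):
        v = np.zeros(d_text)
        v[i] = 1.0
        out[t] = v
    return out


def synthetic_encoder(
    width: int, seed: int = 0, source_tag: str = "sequence"
) -> EncoderAdapter:
    """Deterministic stand-in encoder: text → token embedding matrix.

    Each whitespace token's row is drawn from an rng seeded by a hash of
    (seed, token), so identical inputs always encode identically.
    """

    def encode(text: str) -> TokenEmbeddingMatrix:
        tokens = text.split() or [text]
        rows = []
        for tok in tokens:
            h = hashlib.sha256(f"{seed}:{tok}".encode()).digest()
            tok_seed = int.from_bytes(h[:4], "little")
            rows.append(np.random.default_rng(tok_seed).standard_normal(width))
        return TokenEmbeddingMatrix(np.stack(rows), source_tag)

    return EncoderAdapter(encode=encode, width=width)
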