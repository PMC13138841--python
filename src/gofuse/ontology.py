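"""Gene Ontology handling: OBO parsing, temporal diffing, true-path
propagation, label-space partitioning and hierarchical score consistency.

The GO is a directed acyclic graph per namespace (BP/MF/CC). Edges run
child → parent and the hierarchy is defined by ``is_a`` and ``part_of``
relations only (``regulates``-family edges are ignored, the common choice
in CAFA-style pipelines). Obsolete terms are flagged on load and excluded
from the DAG and from every downstream set.

Temporal diffing of two ontology releases yields the "zero-shot" terms:
terms that exist in the newer release but not in the older one, so a model
trained before the update can never have seen them as labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import numpy as np

__all__ = [
    "NAMESPACES",
    "Term",
    "OntologyGraph",
    "AnnotationTable",
    "LabelPartition",
    "parse_obo",
    "temporal_label_diff",
    "propagate_true_path",
    "partition_labels",
    "hierarchical_postprocess",
]

#: short code -> OBO namespace string
NAMESPACES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}

HIERARCHY_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class Term:
    id: str
    name: str = ""
    definition: str = ""
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """One namespace of one ontology release.

    ``dag`` holds only non-obsolete terms, with child → parent edges.
    """

    namespace: str
    version_tag: str = ""
    terms: dict[str, Term] = field(default_factory=dict)
    dag: nx.DiGraph = field(default_factory=nx.DiGraph)

    def term_ids(self) -> set[str]:
        """Non-obsolete term ids (the DAG node set)."""
        return set(self.dag.nodes)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` by is_a/part_of, exclusive."""
        if term_id not in self.dag:
            raise KeyError(f"unknown term id: {term_id}")
        return set(nx.descendants(self.dag, term_id))  # edges point to parents

    def roots(self) -> set[str]:
        return {n for n in self.dag.nodes if self.dag.out_degree(n) == 0}

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            cycle = nx.find_cycle(self.dag)
            raise ValueError(f"ontology contains a cycle: {cycle}")


class OboParseError(ValueError):
    pass


def parse_obo(
    obo_stream: TextIO | Iterable[str] | str,
    namespace: str,
    version_tag: str = "",
) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text, keeping one namespace.

    Only ``is_a`` and ``relationship: part_of`` edges are retained. Obsolete
    terms are kept in ``terms`` with ``obsolete=True`` but excluded from the
    DAG. Edges to terms outside the requested namespace are dropped.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"namespace must be one of {sorted(NAMESPACES)}, got {namespace!r}")
    ns_long = NAMESPACES[namespace]

    if isinstance(obo_stream, str):
        lines = obo_stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in obo_stream]

    graph = OntologyGraph(namespace=namespace, version_tag=version_tag)
    stanza: dict | None = None
    stanzas: list[dict] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if stanza is not None:
                stanzas.append(stanza)
            stanza = {"_type": line, "_line": lineno} if line == "[Term]" else None
            continue
        if stanza is None:
            continue  # header or non-Term stanza
        if ":" not in line:
            raise OboParseError(f"malformed stanza line {lineno}: {raw!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "id":
            stanza["id"] = value
        elif key == "name":
            stanza["name"] = value
        elif key == "namespace":
            stanza["namespace"] = value
        elif key == "def":
            stanza["def"] = value.split('"')[1] if value.count('"') >= 2 else value
        elif key == "is_obsolete":
            stanza["obsolete"] = value.lower() == "true"
        elif key == "is_a":
            stanza.setdefault("parents", []).append(value.split()[0])
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                stanza.setdefault("parents", []).append(parts[1])
    if stanza is not None:
        stanzas.append(stanza)

    pending_edges: list[tuple[str, str]] = []
    for st in stanzas:
        if "id" not in st:
            raise OboParseError(f"[Term] stanza at line {st['_line']} has no id")
        if st.get("namespace") != ns_long:
            continue
        term = Term(
            id=st["id"],
            name=st.get("name", ""),
            definition=st.get("def", ""),
            obsolete=st.get("obsolete", False),
        )
        graph.terms[term.id] = term
        if term.obsolete:
            continue  # obsolete terms carry no edges
        graph.dag.add_node(term.id)
        for parent in st.get("parents", ()):
            pending_edges.append((term.id, parent))

    for child, parent in pending_edges:
        if parent in graph.dag:
            graph.dag.add_edge(child, parent)

    graph.validate()
    return graph


@dataclass
class AnnotationTable:
    """protein id → set of GO term ids, within one namespace."""

    annotations: dict[str, set[str]]
    namespace: str

    def __post_init__(self):
        self.annotations = {p: set(ts) for p, ts in self.annotations.items()}

    def proteins(self) -> list[str]:
        return list(self.annotations)

    def term_universe(self) -> set[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return out

    def restrict_terms(self, keep: set[str]) -> "AnnotationTable":
        """Drop terms outside ``keep``; proteins left empty are removed."""
        kept = {
            p: ts & keep for p, ts in self.annotations.items() if ts & keep
        }
        return AnnotationTable(kept, self.namespace)


def temporal_label_diff(old: OntologyGraph, new: OntologyGraph) -> set[str]:
    """Non-obsolete term ids present in ``new`` but absent from ``old``.

    These are the candidate zero-shot labels: functions that did not exist
    (as terms) when the training ontology release was cut.
    """
    if old.namespace != new.namespace:
        raise ValueError(
            f"namespace mismatch: {old.namespace} vs {new.namespace}"
        )
    return new.term_ids() - old.term_ids()


def propagate_true_path(
    annotations: AnnotationTable, graph: OntologyGraph
) -> AnnotationTable:
    """Close each protein's term set under is_a/part_of ancestors.

    Annotation to a term implies annotation to every ancestor of that term
    (the true-path rule). Idempotent by construction.
    """
    unknown = annotations.term_universe() - graph.term_ids()
    if unknown:
        raise KeyError(f"terms not in ontology: {sorted(unknown)}")
    closure_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for protein, terms in annotations.annotations.items():
        closed: set[str] = set()
        for t in terms:
            if t not in closure_cache:
                closure_cache[t] = {t} | graph.ancestors(t)
            closed |= closure_cache[t]
        out[protein] = closed
    return AnnotationTable(out, annotations.namespace)


@dataclass(frozen=True)
class LabelPartition:
    """Disjoint split of the label space for seen/unseen evaluation.

    shared        — terms annotated in both training and test sets
    unseen        — test-only terms that already existed in the old release
    training_only — training terms absent from the test set
    zero_shot     — test terms created by the ontology update
    """

    shared: frozenset[str]
    unseen: frozenset[str]
    training_only: frozenset[str]
    zero_shot: frozenset[str]

    def __post_init__(self):
        sets = [self.shared, self.unseen, self.training_only, self.zero_shot]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def test_terms(self) -> frozenset[str]:
        return self.shared | self.unseen | self.zero_shot


def partition_labels(
    train_terms: set[str],
    test_terms: set[str],
    old: OntologyGraph,
    new: OntologyGraph,
) -> LabelPartition:
    """Partition the label space into shared / unseen / training-only /
    zero-shot categories.

    Zero-shot takes precedence over unseen when a test term qualifies for
    both (it cannot be a training term, since training terms predate the
    ontology update).
    """
    train_terms, test_terms = set(train_terms), set(test_terms)
    outside = train_terms - old.term_ids()
    if outside:
        raise ValueError(
            f"training terms missing from the old ontology: {sorted(outside)}"
        )
    diff = temporal_label_diff(old, new)
    zero_shot = test_terms & diff
    shared = train_terms & test_terms
    unseen = test_terms - train_terms - zero_shot
    training_only = train_terms - test_terms
    return LabelPartition(
        shared=frozenset(shared),
        unseen=frozenset(unseen),
        training_only=frozenset(training_only),
        zero_shot=frozenset(zero_shot),
    )


def hierarchical_postprocess(scores, graph: OntologyGraph):
    """Enforce true-path consistency on a score matrix.

    Each term's score becomes the max over itself and all its descendants,
    so every edge satisfies score(parent) ≥ score(child). Already-consistent
    scores pass through unchanged; no score is ever lowered.
    """
    from .evaluation import ScoreMatrix  # local import to avoid a cycle

    if not isinstance(scores, ScoreMatrix):
        raise TypeError("scores must be a ScoreMatrix")
    missing = set(scores.term_ids) - graph.term_ids()
    if missing:
        raise ValueError(f"score columns not in ontology: {sorted(missing)}")
    col = {t: j for j, t in enumerate(scores.term_ids)}
    values = scores.values.copy()
    # children before parents: iterate terms in topological order of the
    # child->parent DAG so each max is final when read
    for term in nx.topological_sort(graph.dag):
        if term not in col:
            continue
        j = col[term]
        for child in graph.dag.predecessors(term):
            if child in col:
                np.maximum(values[:, j], values[:, col[child]], out=values[:, j])
    return ScoreMatrix(values, list(scores.protein_ids), list(scores.term_ids))


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize an OntologyGraph back to minimal OBO text (round-trip aid)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        if graph.version_tag:
            fh.write(f"data-version: {graph.version_tag}\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            fh.write(f"\n[Term]\nid: {term.id}\n")
            if term.name:
                fh.write(f"name: {term.name}\n")
            fh.write(f"namespace: {NAMESPACES[graph.namespace]}\n")
            if term.definition:
                fh.write(f'def: "{term.definition}" []\n')
            if term.obsolete:
                fh.write("is_obsolete: true\n")
            elif term.id in graph.dag:
                for parent in sorted(graph.dag.successors(term.id)):
                    fh.write(f"is_a: {parent}\n")
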