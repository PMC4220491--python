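"""Ontology handling: loading, annotation propagation, size filtering and
Jaccard redundancy pruning of biological-process gene sets.

A gene directly annotated to a term is implicitly annotated to every
ancestor of that term along ``is_a``/``part_of`` edges.  After propagation,
only "specific" terms (fewer than 1,500 genes, at least ``min_size``) are
kept, and near-duplicate terms are pruned: walking the terms from largest
to smallest, a later term is removed when it differs from an earlier
retained term by fewer than 5 genes AND overlaps it with Jaccard >= 0.9.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .exceptions import DataError

RELATIONS = ("is_a", "part_of")

_STANZA_RE = re.compile(r"^\[[A-Za-z_]+\]$")
_TAG_RE = re.compile(r"^[A-Za-z_-]+:\s?.*$")


@dataclass
class GeneSetCollection:
    """term id -> gene-id set mapping with provenance flags.

    ``provenance`` records which processing steps produced the collection
    (any of ``"propagated"``, ``"filtered"``, ``"pruned"``).
    """

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    provenance: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def term_ids(self) -> list[str]:
        return list(self.sets)

    def restrict_to_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe (e.g. the array genes)."""
        uni = frozenset(universe)
        return GeneSetCollection(
            {t: s & uni for t, s in self.sets.items()}, dict(self.names), self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (term_id, gene_id) table."""
        rows = [(t, g) for t, genes in self.sets.items() for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def _validate_obo_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if _STANZA_RE.match(stripped) or _TAG_RE.match(stripped):
            continue
        raise DataError(f"malformed OBO stanza line {lineno}: {stripped!r}")


def load_ontology(source: str | Path) -> nx.MultiDiGraph:
    """Parse an OBO 1.2 subset into a child -> parent MultiDiGraph.

    Only ``is_a`` and ``relationship: part_of`` edges are retained; obsolete
    terms are excluded.  Raises :class:`DataError` on malformed stanzas (with
    line number) or if the retained relations form a cycle.
    """
    path = Path(source)
    text = path.read_text()
    _validate_obo_text(text)
    import io

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = obonet.read_obo(io.StringIO(text))
    drop = [
        (u, v, k) for u, v, k in graph.edges(keys=True) if k not in RELATIONS
    ]
    graph.remove_edges_from(drop)
    if not nx.is_directed_acyclic_graph(graph):
        raise DataError("cycle detected in ontology is_a/part_of relations")
    return graph


def load_annotations(
    source: str | Path, graph: nx.MultiDiGraph
) -> tuple[pd.DataFrame, int]:
    """Read direct gene -> term annotations; returns (table, n_dropped).

    Accepts the two-column ``gene_id<TAB>term_id`` dialect, or GAF-style rows
    (>= 15 tab-separated fields; gene id in column 2, term id in column 5).
    Rows naming a term absent from the ontology are dropped and counted.
    """
    rows: list[tuple[str, str]] = []
    dropped = 0
    with open(source) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("!", "#", "gene_id\t")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 15:
                gene, term = fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                raise DataError(f"annotation row with <2 columns: {line!r}")
            if term in graph:
                rows.append((gene, term))
            else:
                dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} annotation row(s) to unknown terms", stacklevel=2)
    return pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates(), dropped


def propagate_annotations(
    graph: nx.MultiDiGraph, direct: pd.DataFrame
) -> GeneSetCollection:
    """Annotate every gene to the ancestors of its direct terms.

    ``genes(term)`` becomes the union of direct annotations of the term and
    of every ontology descendant reachable via is_a/part_of (sets, so a
    diamond contributes each gene once).
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise DataError("ontology graph must be acyclic")
    direct_sets: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for gene, term in direct.itertuples(index=False):
        direct_sets.setdefault(term, set()).add(gene)
    sets: dict[str, frozenset[str]] = {}
    for term in graph.nodes:
        genes = set(direct_sets.get(term, ()))
        # edges run child -> parent, so graph-theoretic ancestors of a node
        # are its ontology descendants
        for descendant in nx.ancestors(graph, term):
            genes |= direct_sets.get(descendant, set())
        sets[term] = frozenset(genes)
    names = {t: d.get("name", t) for t, d in graph.nodes(data=True)}
    return GeneSetCollection(sets, names, frozenset({"propagated"}))


def filter_specific_terms(
    collection: GeneSetCollection, max_size: int = 1500, min_size: int = 5
) -> GeneSetCollection:
    """Keep terms with min_size <= |genes| < max_size (strict upper bound)."""
    kept = {
        t: s for t, s in collection.sets.items() if min_size <= len(s) < max_size
    }
    return GeneSetCollection(
        kept, dict(collection.names), collection.provenance | {"filtered"}
    )


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A n B| / |A u B|; raises if both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise DataError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def prune_redundant_terms(
    collection: GeneSetCollection,
    size_diff: int = 5,
    jaccard_threshold: float = 0.9,
    descending: bool = True,
) -> GeneSetCollection:
    """Remove near-duplicate terms in a single ordered pass.

    Terms are sorted by gene-set size (descending by default, so the larger,
    more general term of a redundant pair is retained; ties broken by term id
    ascending).  A later term B is removed w.r.t. an earlier *retained* term
    A iff ``||A|-|B|| < size_diff`` and ``jaccard(A,B) >= jaccard_threshold``.
    Removed terms never trigger further removals; the pass is idempotent.
    """
    order = sorted(
        collection.sets,
        key=lambda t: ((-len(collection.sets[t])) if descending else len(collection.sets[t]), t),
    )
    retained: list[str] = []
    for term in order:
        genes = collection.sets[term]
        redundant = False
        for kept in retained:
            kept_genes = collection.sets[kept]
            if abs(len(kept_genes) - len(genes)) < size_diff and jaccard(
                kept_genes, genes
            ) >= jaccard_threshold:
                redundant = True
                break
        if not redundant:
            retained.append(term)
    kept_sets = {t: collection.sets[t] for t in collection.sets if t in set(retained)}
    return GeneSetCollection(
        kept_sets, dict(collection.names), collection.provenance | {"pruned"}
    )


def build_gene_sets(
    graph: nx.MultiDiGraph,
    direct: pd.DataFrame,
    universe: Iterable[str] | None = None,
    max_size: int = 1500,
    min_size: int = 5,
    size_diff: int = 5,
    jaccard_threshold: float = 0.9,
) -> GeneSetCollection:
    """Full pipeline: propagate -> (restrict to universe) -> filter -> prune."""
    coll = propagate_annotations(graph, direct)
    if universe is not None:
        coll = coll.restrict_to_universe(universe)
    coll = filter_specific_terms(coll, max_size=max_size, min_size=min_size)
    return prune_redundant_terms(coll, size_diff=size_diff, jaccard_threshold=jaccard_threshold)


def write_gene_sets_tsv(collection: GeneSetCollection, path: str | Path) -> None:
    collection.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_sets_tsv(path: str | Path) -> GeneSetCollection:
    df = pd.read_csv(path, sep="\t")
    sets: dict[str, set[str]] = {}
    for term, gene in df.itertuples(index=False):
        sets.setdefault(term, set()).add(gene)
    return GeneSetCollection({t: frozenset(s) for t, s in sets.items()})
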