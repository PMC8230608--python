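"""Gene Ontology cellular-component annotation and branch filtering.

Differential glycosites are checked for association with the plasma
membrane by testing whether any GO cellular-component (GOCC) term assigned
to the peptide's gene equals GO:0005886 ("plasma membrane") or lies among
its offspring — all direct and indirect children reached through ``is_a``
and ``part_of`` edges of the ontology's directed acyclic graph.
Regulates-type relations are not treated as parent/child links.

OBO parsing is delegated to :mod:`obonet`; the offspring closure itself is
computed here by a memoized traversal and is cross-checked in the test
suite against naive reachability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import obonet
import pandas as pd

from .io_tables import TableFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneOntologyDag",
    "CycleError",
    "PLASMA_MEMBRANE",
    "load_obo",
    "offspring",
    "load_gene_annotation",
    "gocc_terms_for_genes",
    "annotate_and_flag",
]

#: GOCC id of the "plasma membrane" term, the default branch root.
PLASMA_MEMBRANE = "GO:0005886"

#: relationship types that define the parent/child hierarchy
CHILD_RELATIONS = ("is_a", "part_of")


class CycleError(ValueError):
    """The ontology's is_a/part_of graph contains a cycle."""


@dataclass
class GeneOntologyDag:
    """Terms plus child->parent edges restricted to is_a/part_of."""

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)
    parents: dict[str, frozenset[str]]
    children: dict[str, frozenset[str]] = field(init=False)
    _offspring_cache: dict[str, frozenset[str]] = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge from unknown term {child!r}")
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"edge to unknown term {p!r}")
        inv: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                inv[p].add(child)
        self.children = {t: frozenset(c) for t, c in inv.items()}
        self._check_acyclic()

    @classmethod
    def from_edges(
        cls,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str]],
    ) -> "GeneOntologyDag":
        """Build from (child, parent) pairs; handy for tests and fixtures."""
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
        return cls(terms=dict(terms), parents={c: frozenset(p) for c, p in parents.items()})

    def _check_acyclic(self) -> None:
        # iterative three-colour DFS over child -> parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.terms}
        for start in self.terms:
            if colour[start] != WHITE:
                continue
            stack = [(start, iter(self.parents.get(start, ())))]
            colour[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if colour[nxt] == GREY:
                        raise CycleError(f"is_a/part_of cycle through {nxt!r}")
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, iter(self.parents.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()


def load_obo(path) -> GeneOntologyDag:
    """Parse a go-basic-style OBO file into a :class:`GeneOntologyDag`.

    Obsolete terms are excluded entirely (they never appear in offspring
    sets).  Only ``is_a`` and ``relationship: part_of`` count as edges.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted parse errors
        raise TableFormatError(f"{path}: malformed OBO file ({exc})") from exc
    terms = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", ""), data.get("namespace", ""))
    parents: dict[str, set[str]] = {}
    for child, parent, relation in graph.edges(keys=True):
        if relation in CHILD_RELATIONS and parent in terms:
            parents.setdefault(child, set()).add(parent)
    return GeneOntologyDag(terms=terms, parents={c: frozenset(p) for c, p in parents.items()})


def offspring(dag: GeneOntologyDag, root: str) -> frozenset[str]:
    """Root-inclusive set of all terms on the branch below ``root``.

    Transitive closure of the inverted is_a/part_of edges, memoized per
    node so repeated queries on large ontologies stay cheap.
    """
    if root not in dag.terms:
        raise ValueError(f"unknown ontology term {root!r}")
    cached = dag._offspring_cache.get(root)
    if cached is not None:
        return cached
    # iterative post-order so deep branches do not hit the recursion limit
    stack, order, seen = [root], [], set()
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        order.append(node)
        for child in dag.children.get(node, ()):
            if child not in seen and child not in dag._offspring_cache:
                stack.append(child)
    for node in reversed(order):
        if node in dag._offspring_cache:
            continue
        members = {node}
        for child in dag.children.get(node, ()):
            members.update(dag._offspring_cache.get(child) or offspring(dag, child))
        dag._offspring_cache[node] = frozenset(members)
    return dag._offspring_cache[root]


ANNOTATION_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "gene": ("gene", "gene name", "symbol", "gene symbol"),
    "term": ("term", "go_id", "go id", "gocc id", "go term", "term id"),
}


def load_gene_annotation(path) -> tuple[dict[str, tuple[str, ...]], dict[str, str]]:
    """Load a gene -> GOCC annotation TSV.

    Returns (gene -> sorted term ids, term id -> textual name).  A third
    column with term names is optional.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower().strip(): c for c in df.columns}
    cols = {}
    for canonical, spellings in ANNOTATION_COLUMN_ALIASES.items():
        for s in spellings:
            if s in lower:
                cols[canonical] = lower[s]
                break
    missing = [c for c in ANNOTATION_COLUMN_ALIASES if c not in cols]
    if missing:
        raise TableFormatError(f"{path}: missing annotation column(s) {missing}")
    name_col = lower.get("term name") or lower.get("name")
    genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.to_dict("records"):
        gene = str(row[cols["gene"]]).strip()
        term = str(row[cols["term"]]).strip()
        if not gene or not term:
            continue
        genes.setdefault(gene, set()).add(term)
        if name_col and str(row[name_col]).strip():
            names[term] = str(row[name_col]).strip()
    return {g: tuple(sorted(t)) for g, t in genes.items()}, names


def gocc_terms_for_genes(
    gene_names: Sequence[str],
    annotation: Mapping[str, tuple[str, ...]],
) -> tuple[str, ...]:
    """GOCC terms for a peptide with possibly several gene names.

    The first gene (in the order given) with a non-empty annotation wins;
    genes without any annotation yield the empty tuple.
    """
    for gene in gene_names:
        terms = annotation.get(gene, ())
        if terms:
            return tuple(terms)
    return ()


def annotate_and_flag(
    gene_name_lists: Iterable[Sequence[str]],
    annotation: Mapping[str, tuple[str, ...]],
    dag: GeneOntologyDag,
    root: str = PLASMA_MEMBRANE,
) -> list[tuple[tuple[str, ...], bool]]:
    """Per peptide: (assigned GOCC ids, membrane-branch flag).

    The flag is true iff any assigned term equals ``root`` or lies in its
    offspring.  Terms absent from the ontology are kept in the output but
    can never set the flag.
    """
    branch = offspring(dag, root)
    out = []
    for genes in gene_name_lists:
        terms = gocc_terms_for_genes(genes, annotation)
        out.append((terms, any(t in branch for t in terms)))
    return out
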