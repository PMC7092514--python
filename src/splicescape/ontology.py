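"""Gene Ontology parent-term abstraction and deviation tests.

Leaf GO annotations are rolled up to "parent terms": the depth-1 children
of each namespace root (the granularity of PANTHER-style summaries, e.g.
"binding" or "catalytic activity" under molecular_function).  A leaf
reachable from several depth-1 terms counts toward each; deduplication
happens at the gene × parent level, so a gene with five leaves under one
parent contributes once to that parent.

Observed parent-term counts among spliced genes are compared with
genome-wide expected abundances by 1-df chi-square (term vs complement);
parents annotated to < 2% of the genome are excluded from reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy import stats as sps

from .annotation import ExpectationModel
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDag",
    "GoDeviation",
    "read_gene_associations",
    "abstract_term",
    "abstract_gene_terms",
    "go_deviation_test",
]

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class OntologyDag:
    """An is_a DAG over GO-like terms with one root per namespace.

    ``graph`` has child→parent edges (is_a, optionally part_of); ``roots``
    maps namespace → root term id.
    """

    graph: nx.DiGraph
    namespaces: dict[str, str]
    roots: dict[str, str]

    @classmethod
    def from_obo(cls, path: str | Path, include_part_of: bool = False) -> "OntologyDag":
        """Load an OBO file, keeping is_a (and optionally part_of) edges."""
        multi = obonet.read_obo(str(path))
        graph = nx.DiGraph()
        namespaces: dict[str, str] = {}
        for node, data in multi.nodes(data=True):
            graph.add_node(node)
            namespaces[node] = data.get("namespace", NAMESPACES[0])
        keep = {"is_a"} | ({"part_of"} if include_part_of else set())
        for u, v, key in multi.edges(keys=True):
            if key in keep:
                graph.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValidationError("ontology contains a cycle")
        roots = {}
        for node in graph.nodes:
            if graph.out_degree(node) == 0:
                ns = namespaces[node]
                if ns in roots:
                    raise ValidationError(f"namespace {ns} has two roots")
                roots[ns] = node
        dag = cls(graph=graph, namespaces=namespaces, roots=roots)
        dag.validate()
        return dag

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("ontology contains a cycle")
        for node in self.graph.nodes:
            root = self.roots.get(self.namespaces[node])
            if root is None:
                raise ValidationError(f"no root for namespace of {node}")
            if node != root and not nx.has_path(self.graph, node, root):
                raise ValidationError(f"term {node} cannot reach its namespace root")

    def depth1_terms(self, namespace: str) -> set[str]:
        """Direct children of the namespace root."""
        root = self.roots[namespace]
        return set(self.graph.predecessors(root))

    def ancestors_or_self(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term) | {term}


@dataclass
class GoDeviation:
    """Observed-vs-expected abundance of one GO parent term among spliced genes."""

    parent: str
    observed: int
    expected: float
    normalized_deviation: float  # (observed - expected) / tissue event total
    p: float
    genome_proportion: float


def read_gene_associations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene↔term TSV into gene → set-of-terms."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need two columns (gene, term)")
    assoc: dict[str, set[str]] = {}
    for gene, term in df.iloc[:, :2].itertuples(index=False):
        assoc.setdefault(gene, set()).add(term)
    return assoc


def abstract_term(term: str, dag: OntologyDag) -> set[str]:
    """Roll a term up to its parent terms.

    Returns the depth-1 children of the term's namespace root that are
    ancestors-or-equal of the term (depth-1 terms map to themselves; the
    root maps to the empty set).  Unknown terms are skipped with a warning.
    """
    if term not in dag.graph:
        logger.warning("unknown ontology term %s skipped", term)
        return set()
    ns = dag.namespaces[term]
    return dag.ancestors_or_self(term) & dag.depth1_terms(ns)


def abstract_gene_terms(terms: Iterable[str], dag: OntologyDag) -> set[str]:
    """The union of parent terms of all of a gene's leaf annotations."""
    parents: set[str] = set()
    for t in terms:
        parents |= abstract_term(t, dag)
    return parents


def go_deviation_test(
    spliced_genes: Iterable[str],
    assoc: Mapping[str, set[str]],
    dag: OntologyDag,
    expectation: ExpectationModel,
    tissue_total: int,
    min_genome_fraction: float = 0.02,
) -> list[GoDeviation]:
    """Per-parent-term deviation of spliced genes from genomic expectation.

    observed = spliced genes annotated to the parent (each gene once per
    parent); expected = genome parent proportion × number of spliced genes;
    p from a 1-df term-vs-complement chi-square; normalized deviation is
    (observed − expected) / tissue event total, the scale reported in
    figure-style summaries.  Parents annotated to < ``min_genome_fraction``
    of the genome are filtered from the output.
    """
    genes = sorted(set(spliced_genes))
    if not genes:
        logger.warning("empty spliced gene set; no GO deviations computed")
        return []
    if tissue_total < 1:
        raise ValidationError("tissue_total must be >= 1")
    n = len(genes)
    observed: dict[str, int] = {}
    for gene in genes:
        for parent in abstract_gene_terms(assoc.get(gene, set()), dag):
            observed[parent] = observed.get(parent, 0) + 1

    out = []
    for parent, genome_prop in sorted(expectation.go_parent_proportions.items()):
        if genome_prop < min_genome_fraction:
            continue
        obs = observed.get(parent, 0)
        exp = genome_prop * n
        if exp == 0:
            continue
        # 1-df chi-square: annotated vs not-annotated among spliced genes
        comp_exp = n - exp
        if comp_exp <= 0:
            stat, p = 0.0, 1.0
        else:
            stat = (obs - exp) ** 2 / exp + ((n - obs) - comp_exp) ** 2 / comp_exp
            p = float(sps.chi2.sf(stat, 1)) if stat > 0 else 1.0
        out.append(
            GoDeviation(
                parent=parent,
                observed=obs,
                expected=exp,
                normalized_deviation=(obs - exp) / tissue_total,
                p=p,
                genome_proportion=genome_prop,
            )
        )
    return out
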