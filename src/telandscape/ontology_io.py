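"""Gene Ontology input: gene2go mappings, the GO DAG, and slim vocabularies.

Neighbor-gene ontology summaries project detailed GO annotations onto a small
"slim" vocabulary by walking ancestor links (``is_a`` and ``part_of``) in the
DAG.  Three slim choices are supported: a packaged generic list, and the two
vocabularies derived from the DAG itself — the direct children of the
namespace roots ("TreeLevel1") and their children ("TreeLevel2").

The packaged generic list (``data/generic_slim_synthetic.txt``) is a
synthetic stand-in assembled from broad, widely used GO terms; regenerate it
from the EBI QuickGO generic slim to match a specific release.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Optional, Set

import obonet

GO_ID_RE = re.compile(r"^GO:[0-9]{7}$")

#: GO namespace root accessions (biological_process, molecular_function,
#: cellular_component) — treated as roots when present in a DAG.
NAMESPACE_ROOTS = ("GO:0008150", "GO:0003674", "GO:0005575")

_SLIM_EDGE_TYPES = {"is_a", "part_of"}


class OntologyFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GeneGOMap:
    """gene numeric id -> set of GO term accessions (deduplicated)."""

    mapping: Dict[int, FrozenSet[str]]
    taxon: Optional[int] = None

    def terms_for(self, gene_id: Optional[int]) -> FrozenSet[str]:
        if gene_id is None:
            return frozenset()
        return self.mapping.get(gene_id, frozenset())


@dataclass(frozen=True)
class GOTerm:
    term_id: str
    name: str = ""
    namespace: str = ""
    parents: FrozenSet[str] = frozenset()


class GODag:
    """The GO graph restricted to is_a/part_of parent links, cycle-checked."""

    def __init__(self, terms: Dict[str, GOTerm]):
        self.terms = dict(terms)
        self._children: Dict[str, Set[str]] = {t: set() for t in self.terms}
        for term in self.terms.values():
            for p in term.parents:
                if p in self._children:
                    self._children[p].add(term.term_id)
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.terms}
        for root in self.terms:
            if color[root] != WHITE:
                continue
            stack = [(root, iter(self.terms[root].parents))]
            color[root] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in self.terms:
                        continue
                    if color[parent] == GRAY:
                        raise OntologyFormatError(f"cycle through {parent} in GO graph")
                    if color[parent] == WHITE:
                        color[parent] = GRAY
                        stack.append((parent, iter(self.terms[parent].parents)))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    @classmethod
    def from_parent_map(cls, parents: Dict[str, Iterable[str]], names=None, namespaces=None) -> "GODag":
        """Build a DAG from a plain id -> parent-ids mapping (tests, fixtures)."""
        names = names or {}
        namespaces = namespaces or {}
        terms = {
            tid: GOTerm(
                term_id=tid,
                name=names.get(tid, ""),
                namespace=namespaces.get(tid, ""),
                parents=frozenset(ps),
            )
            for tid, ps in parents.items()
        }
        return cls(terms)

    @classmethod
    def read_obo(cls, path) -> "GODag":
        """Load an OBO 1.2 file (obsolete terms are dropped)."""
        graph = obonet.read_obo(str(path))
        terms: Dict[str, GOTerm] = {}
        for node, data in graph.nodes(data=True):
            parents = {
                parent
                for _, parent, rel in graph.out_edges(node, keys=True)
                if rel in _SLIM_EDGE_TYPES
            }
            terms[node] = GOTerm(
                term_id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", ""),
                parents=frozenset(parents),
            )
        return cls(terms)

    def roots(self) -> Set[str]:
        named = {r for r in NAMESPACE_ROOTS if r in self.terms}
        if named:
            return named
        return {t for t, term in self.terms.items() if not (term.parents & self.terms.keys())}

    def children(self, term_id: str) -> Set[str]:
        return set(self._children.get(term_id, set()))

    def ancestors_or_self(self, term_id: str) -> Set[str]:
        """Transitive closure over parent links, including the term itself."""
        if term_id not in self.terms:
            return set()
        seen = {term_id}
        frontier = [term_id]
        while frontier:
            node = frontier.pop()
            for p in self.terms[node].parents:
                if p in self.terms and p not in seen:
                    seen.add(p)
                    frontier.append(p)
        return seen

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class SlimSet:
    """A named reduced GO vocabulary used for pie-chart style summaries."""

    name: str
    terms: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.terms and self.name not in ("TreeLevel1", "TreeLevel2"):
            raise OntologyFormatError(f"slim set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_gene2go(path, taxon: Optional[int] = None) -> GeneGOMap:
    """Parse an NCBI gene2go TSV (tax_id, GeneID, GO_ID, ... columns).

    A leading '#' header is allowed.  When ``taxon`` is given, rows of other
    taxa are dropped.  Duplicate (gene, term) pairs collapse to one entry.
    """
    mapping: Dict[int, Set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OntologyFormatError(
                    f"{path}:{lineno}: need at least tax_id, GeneID, GO_ID columns"
                )
            try:
                tax_id, gene_id = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise OntologyFormatError(f"{path}:{lineno}: bad numeric id") from exc
            go_id = fields[2]
            if not GO_ID_RE.match(go_id):
                raise OntologyFormatError(
                    f"{path}:{lineno}: malformed GO id {go_id!r}"
                )
            if taxon is not None and tax_id != taxon:
                continue
            mapping.setdefault(gene_id, set()).add(go_id)
    return GeneGOMap(
        mapping={g: frozenset(ts) for g, ts in mapping.items()}, taxon=taxon
    )


def read_slim_list(path, name: str = "custom") -> SlimSet:
    """A slim file is one GO accession per line; '#' comments allowed."""
    terms: Set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[0]
            if not GO_ID_RE.match(token):
                raise OntologyFormatError(f"{path}:{lineno}: malformed GO id {token!r}")
            terms.add(token)
    return SlimSet(name=name, terms=frozenset(terms))


def load_generic_slim() -> SlimSet:
    """The packaged generic slim (synthetic stand-in; see module docstring)."""
    ref = resources.files("telandscape").joinpath("data/generic_slim_synthetic.txt")
    terms = {
        line.split()[0]
        for line in ref.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return SlimSet(name="GenericEBI", terms=frozenset(terms))


# ---------------------------------------------------------------------------
# slim derivation and mapping
# ---------------------------------------------------------------------------

def derive_tree_level_slim(dag: GODag, level: int) -> SlimSet:
    """Slim vocabulary from the top of the DAG itself.

    Level 1 is the set of direct children of the namespace roots; level 2 the
    children of level-1 terms, minus roots and level-1 terms (so the two
    levels are disjoint).
    """
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")
    roots = dag.roots()
    level1: Set[str] = set()
    for r in roots:
        level1 |= dag.children(r)
    level1 -= roots
    if level == 1:
        return SlimSet(name="TreeLevel1", terms=frozenset(level1))
    level2: Set[str] = set()
    for t in level1:
        level2 |= dag.children(t)
    level2 -= roots | level1
    return SlimSet(name="TreeLevel2", terms=frozenset(level2))


def map_to_slim(dag: GODag, terms: Iterable[str], slim: SlimSet) -> Set[str]:
    """Slim terms that are ancestors-or-self of at least one input term.

    Unknown input terms are skipped (the caller may warn); the result is
    monotone in ``terms``.
    """
    hits: Set[str] = set()
    for t in terms:
        if t not in dag:
            continue
        hits |= dag.ancestors_or_self(t) & slim.terms
    return hits
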