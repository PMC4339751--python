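"""In-memory named-graph quad store with Bio2RDF-convention identifiers.

Every entity across the seven source graphs is named by a single URI of the
form ``http://bio2rdf.org/<namespace>:<local_id>`` so that the same gene,
protein or GO term can be joined across graphs without any mapping table.
The store keeps quads grouped by named graph and answers conjunctive
graph-pattern queries (a small, fully deterministic subset of SPARQL basic
graph patterns plus VALUES-style set filters and numeric comparison filters).

Serialization to and from Turtle and N-Quads is delegated to :mod:`rdflib`;
the pattern matcher itself is implemented here.
"""

from __future__ import annotations

import operator as _operator
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import rdflib
from rdflib import Dataset, Graph, URIRef
from rdflib import Literal as RdfLiteral
from rdflib.namespace import XSD

BIO2RDF_BASE = "http://bio2rdf.org/"


class GeroscoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GeroscoreError):
    """Malformed configuration, pattern filter, or unknown format."""


class NonConvertibleURIError(GeroscoreError):
    """A URI does not follow the ``http://bio2rdf.org/ns:id`` convention."""


# ---------------------------------------------------------------------------
# Identifiers and literals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Identifier:
    """A namespaced identifier, e.g. ``wormbase:WBGene00008205``.

    The full URI form expands deterministically to
    ``http://bio2rdf.org/<namespace>:<local_id>`` and the expansion round-trips
    exactly through :func:`contract`.
    """

    namespace: str
    local_id: str

    def __post_init__(self) -> None:
        # a colon inside the namespace would make URI expansion ambiguous
        if ":" in self.namespace:
            raise ConfigurationError(
                f"identifier namespace may not contain ':': {self.namespace!r}")

    @property
    def uri(self) -> str:
        return f"{BIO2RDF_BASE}{self.namespace}:{self.local_id}"

    @property
    def curie(self) -> str:
        return f"{self.namespace}:{self.local_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


def mint(namespace: str, local_id: str) -> Identifier:
    """Mint an :class:`Identifier`; the namespace must be non-empty."""
    if not namespace:
        raise ConfigurationError("identifier namespace must be non-empty")
    return Identifier(str(namespace), str(local_id))


def expand(ident: Identifier) -> str:
    """Expand an identifier to its full Bio2RDF URI."""
    return ident.uri


def contract(uri: str) -> Identifier:
    """Contract a Bio2RDF URI back to an :class:`Identifier`.

    Raises :class:`NonConvertibleURIError` for URIs outside the convention.
    """
    if not uri.startswith(BIO2RDF_BASE):
        raise NonConvertibleURIError(f"not a Bio2RDF-convention URI: {uri!r}")
    rest = uri[len(BIO2RDF_BASE):]
    namespace, sep, local = rest.partition(":")
    if not sep or not namespace:
        raise NonConvertibleURIError(f"missing namespace:local form: {uri!r}")
    return Identifier(namespace, local)


@dataclass(frozen=True, order=True)
class Literal:
    """A typed RDF literal.

    ``datatype`` is one of ``string``, ``integer`` or ``decimal``; it is
    inferred from the Python value when not given.  Numeric filters compare
    numerically, string values lexically.
    """

    value: Union[str, int, float]
    datatype: str = ""

    def __post_init__(self) -> None:
        if not self.datatype:
            if isinstance(self.value, bool):
                raise ConfigurationError("boolean literals are not supported")
            if isinstance(self.value, int):
                object.__setattr__(self, "datatype", "integer")
            elif isinstance(self.value, float):
                object.__setattr__(self, "datatype", "decimal")
            else:
                object.__setattr__(self, "datatype", "string")

    @property
    def is_numeric(self) -> bool:
        return self.datatype in ("integer", "decimal")


Term = Union[Identifier, Literal]


@dataclass(frozen=True, order=True)
class Quad:
    """One statement in one named graph."""

    subject: Identifier
    predicate: Identifier
    obj: Term
    graph: Identifier

    def __post_init__(self) -> None:
        if not isinstance(self.subject, Identifier):
            raise ConfigurationError("quad subject must be an Identifier")
        if not isinstance(self.predicate, Identifier):
            raise ConfigurationError("quad predicate must be an Identifier")


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------

class KnowledgeBase:
    """A set of named graphs, each a quad multiset.

    The expected graph roles for the aging rule are ``wormbase``, ``genage``,
    ``gendr``, ``ppi``, ``goa``, ``expression`` and ``go_cooccurrence``
    (see :data:`geroscore.vocab.GRAPHS`), plus hypothesis and provenance
    graphs.  The same identifier may appear in any number of graphs — that is
    the integration mechanism the pattern matcher exploits.
    """

    def __init__(self) -> None:
        self._graphs: Dict[Identifier, List[Quad]] = {}

    # -- construction ------------------------------------------------------

    def add(self, quad: Quad) -> None:
        self._graphs.setdefault(quad.graph, []).append(quad)

    def add_triple(self, graph: Identifier, s: Identifier, p: Identifier,
                   o: Term) -> None:
        self.add(Quad(s, p, o, graph))

    def extend(self, quads: Iterable[Quad]) -> None:
        for q in quads:
            self.add(q)

    def merge(self, other: "KnowledgeBase") -> None:
        self.extend(other.quads())

    # -- inspection --------------------------------------------------------

    @property
    def graph_names(self) -> List[Identifier]:
        return sorted(self._graphs)

    def quads(self, graph: Optional[Identifier] = None) -> Iterator[Quad]:
        if graph is not None:
            yield from self._graphs.get(graph, [])
        else:
            for name in sorted(self._graphs):
                yield from self._graphs[name]

    def count(self, graph: Optional[Identifier] = None) -> int:
        if graph is not None:
            return len(self._graphs.get(graph, []))
        return sum(len(v) for v in self._graphs.values())

    def multiset(self, graph: Optional[Identifier] = None) -> Dict[Quad, int]:
        counts: Dict[Quad, int] = {}
        for q in self.quads(graph):
            counts[q] = counts.get(q, 0) + 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self.multiset() == other.multiset()


# ---------------------------------------------------------------------------
# Graph patterns
# ---------------------------------------------------------------------------

def is_var(term: object) -> bool:
    """Pattern variables are plain strings starting with ``?``."""
    return isinstance(term, str) and term.startswith("?")


PatternTerm = Union[str, Identifier, Literal]
TriplePattern = Tuple[PatternTerm, PatternTerm, PatternTerm]

_COMPARATORS = {
    "<": _operator.lt,
    "<=": _operator.le,
    ">": _operator.gt,
    ">=": _operator.ge,
    "==": _operator.eq,
    "!=": _operator.ne,
}


@dataclass(frozen=True)
class ValueFilter:
    """VALUES-style set membership: the variable must bind to one of ``allowed``."""

    var: str
    allowed: frozenset

    def __init__(self, var: str, allowed: Iterable[Term]) -> None:
        object.__setattr__(self, "var", var)
        object.__setattr__(self, "allowed", frozenset(allowed))

    def accepts(self, binding: Mapping[str, Term]) -> bool:
        return binding[self.var] in self.allowed


@dataclass(frozen=True)
class CompareFilter:
    """Numeric comparison on a bound literal, e.g. ``?p < 0.05``."""

    var: str
    op: str
    value: float

    def __post_init__(self) -> None:
        if self.op not in _COMPARATORS:
            raise ConfigurationError(f"unknown comparison operator {self.op!r}")

    def accepts(self, binding: Mapping[str, Term]) -> bool:
        bound = binding[self.var]
        if not isinstance(bound, Literal) or not bound.is_numeric:
            return False
        return _COMPARATORS[self.op](float(bound.value), float(self.value))


Filter = Union[ValueFilter, CompareFilter]


@dataclass
class GraphPattern:
    """A conjunctive pattern: ordered triple templates + optional filters.

    Any of the three positions may be a ``?var`` string.  Solutions are the
    bindings a naive nested-loop join over the quad multiset would produce
    (duplicates removed); a pattern with no variables acts as an ASK.
    """

    triples: Sequence[TriplePattern]
    graph: Optional[Identifier] = None
    filters: Sequence[Filter] = field(default_factory=tuple)

    def variables(self) -> List[str]:
        seen: List[str] = []
        for t in self.triples:
            for term in t:
                if is_var(term) and term not in seen:
                    seen.append(term)
        return seen


def _unify(pattern_term: PatternTerm, term: Term,
           binding: Dict[str, Term]) -> Optional[Dict[str, Term]]:
    if is_var(pattern_term):
        bound = binding.get(pattern_term)
        if bound is None:
            new = dict(binding)
            new[pattern_term] = term
            return new
        return binding if bound == term else None
    return binding if pattern_term == term else None


def match(kb: KnowledgeBase, pattern: GraphPattern) -> List[Dict[str, Term]]:
    """Solve a conjunctive graph pattern by nested-loop join.

    Returns the distinct variable bindings; a nonexistent graph restriction
    simply yields no solutions.  Malformed filters (a filter variable never
    bound by any triple template) raise :class:`ConfigurationError`.
    """
    bound_vars = set(pattern.variables())
    for f in pattern.filters:
        if f.var not in bound_vars:
            raise ConfigurationError(
                f"filter variable {f.var!r} is not bound by the pattern")

    quads = list(kb.quads(pattern.graph))
    solutions: List[Dict[str, Term]] = [{}]
    for s, p, o in pattern.triples:
        next_solutions: List[Dict[str, Term]] = []
        for binding in solutions:
            for q in quads:
                b = _unify(s, q.subject, binding)
                if b is None:
                    continue
                b = _unify(p, q.predicate, b)
                if b is None:
                    continue
                b = _unify(o, q.obj, b)
                if b is None:
                    continue
                next_solutions.append(b)
        solutions = next_solutions
        if not solutions:
            return []

    out: List[Dict[str, Term]] = []
    seen = set()
    for binding in solutions:
        if not all(f.accepts(binding) for f in pattern.filters):
            continue
        key = tuple(sorted(binding.items()))
        if key not in seen:
            seen.add(key)
            out.append(binding)
    return out


def ask(kb: KnowledgeBase, pattern: GraphPattern) -> bool:
    """Boolean form of :func:`match`."""
    return bool(match(kb, pattern))


# ---------------------------------------------------------------------------
# Serialization (rdflib-backed)
# ---------------------------------------------------------------------------

_XSD_BY_DATATYPE = {
    "string": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.double,
}


def _to_rdflib(term: Term) -> rdflib.term.Node:
    if isinstance(term, Identifier):
        return URIRef(term.uri)
    if term.datatype == "integer":
        return RdfLiteral(int(term.value), datatype=XSD.integer)
    if term.datatype == "decimal":
        return RdfLiteral(float(term.value), datatype=XSD.double)
    return RdfLiteral(str(term.value))


def _from_rdflib(node: rdflib.term.Node) -> Term:
    if isinstance(node, URIRef):
        return contract(str(node))
    if isinstance(node, RdfLiteral):
        if node.datatype in (XSD.integer, XSD.int, XSD.long):
            return Literal(int(node))
        if node.datatype in (XSD.double, XSD.decimal, XSD.float):
            return Literal(float(node))
        return Literal(str(node))
    raise NonConvertibleURIError(f"unsupported RDF node: {node!r}")


def load_graph(kb: KnowledgeBase, path: str, format: str,
               graph_name: Identifier) -> int:
    """Parse a Turtle or N-Quads file into ``graph_name``; return quads added.

    For N-Quads input the graph component of each statement is ignored in
    favour of ``graph_name`` (one file per graph role is the convention).
    Parse failures surface rdflib's error, which names the offending
    line/offset; an unknown format raises :class:`ConfigurationError`.
    """
    if format == "turtle":
        g = Graph()
        g.parse(path, format="turtle")
        triples = list(g)
    elif format == "nquads":
        ds = Dataset()
        ds.parse(path, format="nquads")
        triples = [(s, p, o) for s, p, o, _ in ds.quads((None, None, None, None))]
    else:
        raise ConfigurationError(f"unknown serialization format {format!r}")
    added = 0
    for s, p, o in triples:
        kb.add(Quad(_from_rdflib(s), _from_rdflib(p),  # type: ignore[arg-type]
                    _from_rdflib(o), graph_name))
        added += 1
    return added


def save_graph(kb: KnowledgeBase, path: str, format: str,
               graph_name: Identifier) -> int:
    """Serialize one named graph as Turtle (or its quads as N-Quads)."""
    if format == "turtle":
        g = Graph()
        for q in kb.quads(graph_name):
            g.add((_to_rdflib(q.subject), _to_rdflib(q.predicate),
                   _to_rdflib(q.obj)))
        g.serialize(destination=path, format="turtle")
        return len(g)
    if format == "nquads":
        ds = Dataset()
        ctx = ds.graph(URIRef(graph_name.uri))
        for q in kb.quads(graph_name):
            ctx.add((_to_rdflib(q.subject), _to_rdflib(q.predicate),
                     _to_rdflib(q.obj)))
        ds.serialize(destination=path, format="nquads")
        return kb.count(graph_name)
    raise ConfigurationError(f"unknown serialization format {format!r}")


def save_kb(kb: KnowledgeBase, path: str) -> int:
    """Serialize the whole knowledge base as N-Quads."""
    ds = Dataset()
    for name in kb.graph_names:
        ctx = ds.graph(URIRef(name.uri))
        for q in kb.quads(name):
            ctx.add((_to_rdflib(q.subject), _to_rdflib(q.predicate),
                     _to_rdflib(q.obj)))
    ds.serialize(destination=path, format="nquads")
    return kb.count()


def load_kb(path: str) -> KnowledgeBase:
    """Load an N-Quads file written by :func:`save_kb`, preserving graphs."""
    ds = Dataset()
    ds.parse(path, format="nquads")
    kb = KnowledgeBase()
    for s, p, o, ctx in ds.quads((None, None, None, None)):
        name = str(ctx.identifier if hasattr(ctx, "identifier") else ctx)
        if name == str(rdflib.graph.DATASET_DEFAULT_GRAPH_ID):
            continue
        kb.add(Quad(_from_rdflib(s), _from_rdflib(p),  # type: ignore[arg-type]
                    _from_rdflib(o), contract(name)))
    return kb
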