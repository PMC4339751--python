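"""Hypothesis data model: events, propositions, and hypothesis trees.

A hypothesis is a finite tree of propositions whose leaves are typed events.
For the aging domain the canonical hypothesis is "gene G is the agent of an
aging event" (event type ``go:0007568``): a single event wrapped in an XOR
proposition, so that every hypothesis has a uniform tree for the score
propagation engine.  Propositions combine members with AND / OR / XOR; XOR
holds exactly one member, AND and OR at least two.

Hypotheses serialize to and from a quad multiset (the RDF shape used by the
``hypotheses`` graph role) and the round trip is the identity up to node
renaming — node identifiers are minted deterministically from the hypothesis
identifier and tree path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Tuple, Union

from . import vocab
from .kb import GeroscoreError, Identifier, Literal, Quad

GO_AGING = vocab.GO_AGING


class ValidationError(GeroscoreError):
    """Structurally invalid hypothesis graph or tree."""


class AmbiguityError(ValidationError):
    """More than one hypothesis root in a graph that must hold exactly one."""


class Operator(str, Enum):
    AND = "AND"
    OR = "OR"
    XOR = "XOR"


@dataclass(frozen=True)
class Event:
    """A typed process with an agent and optional extra participants."""

    event_type: Identifier
    agent: Identifier
    targets: Tuple[Identifier, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.event_type, Identifier):
            raise ValidationError("event_type must be an Identifier")
        if not isinstance(self.agent, Identifier):
            raise ValidationError("event agent must be an Identifier")


@dataclass(frozen=True)
class Proposition:
    """Logical combination of events and/or nested propositions."""

    operator: Operator
    members: Tuple[Union[Event, "Proposition"], ...]

    def __post_init__(self) -> None:
        n = len(self.members)
        if self.operator is Operator.XOR and n != 1:
            raise ValidationError(f"XOR proposition must have exactly 1 member, got {n}")
        if self.operator in (Operator.AND, Operator.OR) and n < 2:
            raise ValidationError(
                f"{self.operator.value} proposition needs >= 2 members, got {n}")


@dataclass(frozen=True)
class Hypothesis:
    id: Identifier
    root: Proposition

    def events(self) -> List[Event]:
        out: List[Event] = []

        def walk(node: Union[Event, Proposition]) -> None:
            if isinstance(node, Event):
                out.append(node)
            else:
                for m in node.members:
                    walk(m)

        walk(self.root)
        return out


def make_gene_aging_hypothesis(gene: Identifier) -> Hypothesis:
    """The canonical single-event aging hypothesis for one gene.

    Hypothesis identifiers are minted deterministically from the gene
    identifier so that batch runs produce reproducible provenance.  A
    non-wormbase gene namespace is allowed (future taxa) but warned about.
    """
    if gene.namespace != "wormbase":
        warnings.warn(
            f"aging hypotheses are tuned for wormbase genes; got namespace "
            f"{gene.namespace!r}", stacklevel=2)
    event = Event(event_type=GO_AGING, agent=gene)
    root = Proposition(Operator.XOR, (event,))
    hid = Identifier("hypothesis", f"aging-{gene.local_id}")
    return Hypothesis(id=hid, root=root)


# ---------------------------------------------------------------------------
# RDF shape
# ---------------------------------------------------------------------------

def serialize_hypothesis(h: Hypothesis,
                         graph: Identifier = vocab.GRAPHS["hypotheses"],
                         ) -> List[Quad]:
    """Emit the hypothesis as quads; node ids are minted from tree paths."""
    quads: List[Quad] = [
        Quad(h.id, vocab.HO_TYPE, vocab.HO_CLASS_HYPOTHESIS, graph)]

    def node_id(path: str) -> Identifier:
        return Identifier("hypothesis", f"{h.id.local_id}-{path}")

    def emit(node: Union[Event, Proposition], path: str,
             parent: Identifier) -> None:
        nid = node_id(path)
        quads.append(Quad(parent, vocab.HO_MEMBER, nid, graph))
        if isinstance(node, Event):
            quads.append(Quad(nid, vocab.HO_TYPE, vocab.HO_CLASS_EVENT, graph))
            quads.append(Quad(nid, vocab.HO_EVENT_TYPE, node.event_type, graph))
            quads.append(Quad(nid, vocab.HO_AGENT, node.agent, graph))
            for t in node.targets:
                quads.append(Quad(nid, vocab.HO_TARGET, t, graph))
        else:
            quads.append(Quad(nid, vocab.HO_TYPE, vocab.HO_CLASS_PROPOSITION, graph))
            quads.append(Quad(nid, vocab.HO_OPERATOR,
                              Literal(node.operator.value), graph))
            for i, m in enumerate(node.members):
                child = node_id(f"{path}.{i}")
                quads.append(Quad(child, vocab.HO_MEMBER_INDEX, Literal(i), graph))
                emit(m, f"{path}.{i}", nid)

    root_id = node_id("p")
    quads.append(Quad(h.id, vocab.HO_PROPOSITION, root_id, graph))
    quads.append(Quad(root_id, vocab.HO_TYPE, vocab.HO_CLASS_PROPOSITION, graph))
    quads.append(Quad(root_id, vocab.HO_OPERATOR,
                      Literal(h.root.operator.value), graph))
    for i, m in enumerate(h.root.members):
        child = node_id(f"p.{i}")
        quads.append(Quad(child, vocab.HO_MEMBER_INDEX, Literal(i), graph))
        emit(m, f"p.{i}", root_id)
    return quads


def parse_hypothesis(quads: Iterable[Quad]) -> Hypothesis:
    """Rebuild a hypothesis tree from its quad shape.

    The graph must contain exactly one hypothesis node; missing event types
    or agents raise :class:`ValidationError` naming the offending node.
    """
    quads = list(quads)
    by_subject: dict = {}
    for q in quads:
        by_subject.setdefault(q.subject, []).append(q)

    roots = [q.subject for q in quads
             if q.predicate == vocab.HO_TYPE and q.obj == vocab.HO_CLASS_HYPOTHESIS]
    if not roots:
        raise ValidationError("graph contains no hypothesis node")
    if len(roots) > 1:
        raise AmbiguityError(
            f"graph contains {len(roots)} hypothesis nodes: "
            + ", ".join(sorted(r.curie for r in roots)))
    hid = roots[0]

    def prop_of(node: Identifier) -> Identifier:
        for q in by_subject.get(node, []):
            if q.predicate == vocab.HO_PROPOSITION:
                return q.obj  # type: ignore[return-value]
        raise ValidationError(f"hypothesis {node.curie} has no root proposition")

    def get_one(node: Identifier, pred: Identifier, what: str):
        vals = [q.obj for q in by_subject.get(node, []) if q.predicate == pred]
        if not vals:
            raise ValidationError(f"node {node.curie} is missing {what}")
        return vals[0]

    def build(node: Identifier) -> Union[Event, Proposition]:
        types = [q.obj for q in by_subject.get(node, [])
                 if q.predicate == vocab.HO_TYPE]
        if vocab.HO_CLASS_EVENT in types:
            etype = get_one(node, vocab.HO_EVENT_TYPE, "an event type")
            agent = get_one(node, vocab.HO_AGENT, "an agent")
            targets = tuple(sorted(
                q.obj for q in by_subject.get(node, [])
                if q.predicate == vocab.HO_TARGET))
            return Event(etype, agent, targets)  # type: ignore[arg-type]
        if vocab.HO_CLASS_PROPOSITION in types:
            op_lit = get_one(node, vocab.HO_OPERATOR, "an operator")
            operator = Operator(str(op_lit.value))  # type: ignore[union-attr]
            members = [q.obj for q in by_subject.get(node, [])
                       if q.predicate == vocab.HO_MEMBER]
            def index_of(m: Identifier) -> int:
                for q in by_subject.get(m, []):
                    if q.predicate == vocab.HO_MEMBER_INDEX:
                        return int(q.obj.value)  # type: ignore[union-attr]
                return 0
            members.sort(key=index_of)
            return Proposition(operator, tuple(build(m) for m in members))
        raise ValidationError(f"node {node.curie} has no recognized type")

    root = build(prop_of(hid))
    if isinstance(root, Event):
        root = Proposition(Operator.XOR, (root,))
    return Hypothesis(id=hid, root=root)


def load_gene_list(path: str) -> List[Identifier]:
    """Batch input: one gene identifier (CURIE or bare WBGene id) per line."""
    genes: List[Identifier] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                ns, _, local = line.partition(":")
                genes.append(Identifier(ns, local))
            else:
                genes.append(Identifier("wormbase", line))
    return genes
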