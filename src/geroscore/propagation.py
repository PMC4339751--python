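"""Score propagation: events -> propositions -> overall hypothesis score.

Scores flow bottom-up: each event is scored by the domain rule registered
for its event type (for aging events, the nine-DEF scorer), then proposition
scores are combined — AND takes the arithmetic mean of its members, OR the
maximum, XOR passes its single member through — and the root proposition
score is the overall hypothesis score.

Every evaluation carries ovopub-style provenance: an assertion graph holding
the evaluation node, its creation time and creator, links to the input
hypothesis and the rule used, one contribution node per evaluation function
with its 0/1 value and the retrieval functions it called, and one node-score
statement per tree node.  Reloading the emitted graph reconstructs all
scores exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

from . import vocab
from .evaluation import (ContractViolation, EvaluationConfig, EventScore,
                         display_score, score_gene)
from .hypothesis import Event, Hypothesis, Operator, Proposition
from .kb import GeroscoreError, Identifier, KnowledgeBase, Literal, Quad

CREATOR = "geroscore"
#: stable URI handle for the aging domain rule (module + function + version)
AGING_RULE = Identifier("rule", "geroscore.evaluation.score_gene.v1")


class UnsupportedEventError(GeroscoreError):
    """No domain rule is registered for an event type."""


EventScorer = Callable[[KnowledgeBase, EvaluationConfig, Event],
                       Tuple[Fraction, Optional[EventScore]]]


def _aging_event_scorer(kb: KnowledgeBase, cfg: EvaluationConfig,
                        event: Event) -> Tuple[Fraction, Optional[EventScore]]:
    es = score_gene(kb, cfg, event.agent)
    return es.normalized, es


#: event type -> (scorer, rule URI)
RULE_REGISTRY: Dict[Identifier, Tuple[EventScorer, Identifier]] = {
    vocab.GO_AGING: (_aging_event_scorer, AGING_RULE),
}


def score_proposition(op: Operator, member_scores: Sequence[Fraction],
                      ) -> Fraction:
    """AND -> mean, OR -> max, XOR -> the single member score."""
    n = len(member_scores)
    if op is Operator.XOR:
        if n != 1:
            raise ContractViolation(f"XOR needs exactly 1 member score, got {n}")
        return member_scores[0]
    if n < 2:
        raise ContractViolation(f"{op.value} needs >= 2 member scores, got {n}")
    if op is Operator.AND:
        return sum(member_scores, Fraction(0)) / n
    return max(member_scores)


@dataclass
class HypothesisEvaluation:
    hypothesis: Identifier
    overall_score: Fraction
    node_scores: Dict[str, Fraction]
    event_scores: Dict[str, EventScore]      # tree path -> event detail
    rules_used: Tuple[Identifier, ...]
    created: str
    creator: str = CREATOR
    config: Optional[dict] = None

    @property
    def displayed(self) -> str:
        return display_score(self.overall_score)

    @property
    def evaluation_id(self) -> Identifier:
        return Identifier("evaluation", f"eval-{self.hypothesis.local_id}")


def evaluate_hypothesis(kb: KnowledgeBase, cfg: EvaluationConfig,
                        h: Hypothesis,
                        fixed_clock: Optional[str] = None,
                        ) -> HypothesisEvaluation:
    """Score a hypothesis tree bottom-up.

    Deterministic given (kb, cfg, h) apart from the creation timestamp;
    pass ``fixed_clock`` (an ISO string) to make output byte-stable.
    """
    node_scores: Dict[str, Fraction] = {}
    event_scores: Dict[str, EventScore] = {}
    rules: List[Identifier] = []

    def walk(node: Union[Event, Proposition], path: str) -> Fraction:
        if isinstance(node, Event):
            entry = RULE_REGISTRY.get(node.event_type)
            if entry is None:
                raise UnsupportedEventError(
                    f"no domain rule for event type {node.event_type.curie}")
            scorer, rule = entry
            if rule not in rules:
                rules.append(rule)
            score, detail = scorer(kb, cfg, node)
            if detail is not None:
                event_scores[path] = detail
            node_scores[path] = score
            return score
        members = [walk(m, f"{path}.{i}") for i, m in enumerate(node.members)]
        score = score_proposition(node.operator, members)
        node_scores[path] = score
        return score

    overall = walk(h.root, "p")
    created = fixed_clock or _dt.datetime.now(_dt.timezone.utc).isoformat()
    return HypothesisEvaluation(
        hypothesis=h.id, overall_score=overall, node_scores=node_scores,
        event_scores=event_scores, rules_used=tuple(rules), created=created,
        config=cfg.to_dict())


def evaluate_gene(kb: KnowledgeBase, cfg: EvaluationConfig, gene: Identifier,
                  fixed_clock: Optional[str] = None) -> HypothesisEvaluation:
    """Evaluate the canonical aging hypothesis for one gene."""
    from .hypothesis import make_gene_aging_hypothesis
    return evaluate_hypothesis(kb, cfg, make_gene_aging_hypothesis(gene),
                               fixed_clock=fixed_clock)


# ---------------------------------------------------------------------------
# Provenance emission and reconstruction
# ---------------------------------------------------------------------------

def emit_provenance(ev: HypothesisEvaluation,
                    graph: Identifier = vocab.GRAPHS["provenance"],
                    ) -> List[Quad]:
    """Serialize an evaluation as an ovopub-style assertion graph."""
    eid = ev.evaluation_id
    quads = [
        Quad(eid, vocab.EV_TYPE, vocab.EV_CLASS_EVALUATION, graph),
        Quad(eid, vocab.EV_CREATED, Literal(ev.created), graph),
        Quad(eid, vocab.EV_CREATOR, Literal(ev.creator), graph),
        Quad(eid, vocab.EV_HYPOTHESIS, ev.hypothesis, graph),
        Quad(eid, vocab.EV_OVERALL_SCORE, Literal(str(ev.overall_score)), graph),
    ]
    for rule in ev.rules_used:
        quads.append(Quad(eid, vocab.EV_RULE, rule, graph))
    for path in sorted(ev.node_scores):
        nid = Identifier("evaluation", f"{eid.local_id}-node-{path}")
        quads.append(Quad(eid, vocab.EV_NODE_SCORE, nid, graph))
        quads.append(Quad(nid, vocab.EV_NODE, Literal(path), graph))
        quads.append(Quad(nid, vocab.EV_SCORE,
                          Literal(str(ev.node_scores[path])), graph))
    for path in sorted(ev.event_scores):
        es = ev.event_scores[path]
        quads.append(Quad(eid, vocab.EV_AGENT_GENE, es.gene, graph))
        for r in es.def_results:
            cid = Identifier(
                "evaluation", f"{eid.local_id}-node-{path}-def{r.def_id}")
            quads.append(Quad(eid, vocab.EV_CONTRIBUTION, cid, graph))
            quads.append(Quad(cid, vocab.EV_NODE, Literal(path), graph))
            quads.append(Quad(cid, vocab.EV_DEF_ID, Literal(r.def_id), graph))
            quads.append(Quad(cid, vocab.EV_VALUE,
                              Literal(r.score_contribution), graph))
            for drf in r.drfs_called:
                quads.append(Quad(cid, vocab.EV_DRF, Literal(drf), graph))
    return quads


@dataclass
class ReconstructedEvaluation:
    """Scores read back from an emitted provenance graph."""

    hypothesis: Identifier
    gene: Optional[Identifier]
    overall_score: Fraction
    node_scores: Dict[str, Fraction]
    def_values: Dict[int, int] = field(default_factory=dict)

    @property
    def mask(self) -> Tuple[bool, ...]:
        return tuple(bool(self.def_values.get(k, 0)) for k in range(1, 10))


def reconstruct_evaluations(quads: Sequence[Quad],
                            ) -> Dict[Identifier, ReconstructedEvaluation]:
    """Rebuild all scores from a provenance quad multiset (lossless audit)."""
    by_subject: Dict[Identifier, List[Quad]] = {}
    for q in quads:
        by_subject.setdefault(q.subject, []).append(q)

    out: Dict[Identifier, ReconstructedEvaluation] = {}
    for subject, stmts in by_subject.items():
        preds = {q.predicate: q.obj for q in stmts}
        if preds.get(vocab.EV_TYPE) != vocab.EV_CLASS_EVALUATION:
            continue
        node_scores: Dict[str, Fraction] = {}
        def_values: Dict[int, int] = {}
        for q in stmts:
            if q.predicate == vocab.EV_NODE_SCORE:
                node = {s.predicate: s.obj for s in by_subject.get(q.obj, [])}
                node_scores[str(node[vocab.EV_NODE].value)] = Fraction(
                    str(node[vocab.EV_SCORE].value))
            elif q.predicate == vocab.EV_CONTRIBUTION:
                node = {s.predicate: s.obj for s in by_subject.get(q.obj, [])}
                def_values[int(node[vocab.EV_DEF_ID].value)] = int(
                    node[vocab.EV_VALUE].value)
        gene = preds.get(vocab.EV_AGENT_GENE)
        out[subject] = ReconstructedEvaluation(
            hypothesis=preds[vocab.EV_HYPOTHESIS],  # type: ignore[arg-type]
            gene=gene if isinstance(gene, Identifier) else None,
            overall_score=Fraction(str(preds[vocab.EV_OVERALL_SCORE].value)),
            node_scores=node_scores, def_values=def_values)
    return out


def evaluations_to_tsv(evals: Sequence[HypothesisEvaluation]) -> str:
    """Flat per-gene table: gene, def1..def9, raw, normalized (displayed)."""
    lines = ["gene\t" + "\t".join(f"def{k}" for k in range(1, 10))
             + "\traw\tnormalized"]
    for ev in evals:
        for es in ev.event_scores.values():
            bits = "\t".join(str(r.score_contribution)
                             for r in sorted(es.def_results,
                                             key=lambda r: r.def_id))
            lines.append(f"{es.gene.curie}\t{bits}\t{es.raw}\t{es.displayed}")
    return "\n".join(lines) + "\n"
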