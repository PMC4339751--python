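"""Batch evaluation and downstream analytics.

Covers the whole-genome style analyses: the score histogram, per-function
satisfaction frequencies, independence-model probabilities of observing a
given combination of satisfied functions by chance, identification of
candidate genes whose high scores come without curated aging annotations,
two-sample Kolmogorov–Smirnov comparison of score distributions, and the GO
annotation co-occurrence table consumed by DEF9.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.stats

from . import vocab
from .evaluation import EvaluationConfig, EventScore, display_score
from .hypothesis import make_gene_aging_hypothesis
from .kb import GeroscoreError, Identifier, KnowledgeBase, Literal, Quad
from .propagation import HypothesisEvaluation, evaluate_hypothesis

logger = logging.getLogger("geroscore")


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def batch_evaluate(kb: KnowledgeBase, cfg: EvaluationConfig,
                   genes: Sequence[Identifier],
                   fixed_clock: Optional[str] = None,
                   progress_every: int = 1000,
                   ) -> List[HypothesisEvaluation]:
    """Evaluate the aging hypothesis for every gene.

    Per-gene failures are logged and skipped; the run continues and the
    failure count is reported at the end.
    """
    if not genes:
        raise GeroscoreError("batch_evaluate requires a non-empty gene list")
    out: List[HypothesisEvaluation] = []
    failures = 0
    for i, gene in enumerate(genes, start=1):
        try:
            h = make_gene_aging_hypothesis(gene)
            out.append(evaluate_hypothesis(kb, cfg, h, fixed_clock=fixed_clock))
        except GeroscoreError:
            failures += 1
            logger.exception("evaluation failed for %s", gene.curie)
        if progress_every and i % progress_every == 0:
            logger.info("evaluated %d/%d genes", i, len(genes))
    if failures:
        logger.warning("%d of %d evaluations failed", failures, len(genes))
    return out


def _event_scores(evals: Iterable[HypothesisEvaluation]) -> List[EventScore]:
    out = []
    for ev in evals:
        out.extend(ev.event_scores.values())
    return out


# ---------------------------------------------------------------------------
# Distribution and frequency tables
# ---------------------------------------------------------------------------

def score_distribution(evals: Sequence[HypothesisEvaluation],
                       ) -> Dict[str, int]:
    """Histogram of displayed overall scores (counts sum to len(evals))."""
    hist: Dict[str, int] = {}
    for ev in evals:
        key = display_score(ev.overall_score)
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items(), reverse=True))


@dataclass(frozen=True)
class DefFrequencyTable:
    """Per-function satisfaction counts and proportions over a batch."""

    n_genes: int
    counts: Tuple[int, ...]          # index k-1 -> count for function k

    @property
    def proportions(self) -> Tuple[float, ...]:
        return tuple(c / self.n_genes for c in self.counts)

    def proportion(self, def_id: int) -> float:
        if not 1 <= def_id <= 9:
            raise GeroscoreError(f"evaluation function id {def_id} not in 1..9")
        return self.counts[def_id - 1] / self.n_genes

    @classmethod
    def from_proportions(cls, proportions: Sequence[float],
                         n_genes: int) -> "DefFrequencyTable":
        """Build a table from published proportions (counts are rounded)."""
        return cls(n_genes=n_genes,
                   counts=tuple(round(p * n_genes) for p in proportions))


def def_frequencies(evals: Sequence[HypothesisEvaluation],
                    ) -> DefFrequencyTable:
    scores = _event_scores(evals)
    counts = [0] * 9
    for es in scores:
        for k, bit in enumerate(es.mask):
            counts[k] += bit
    return DefFrequencyTable(n_genes=len(scores), counts=tuple(counts))


# ---------------------------------------------------------------------------
# Combination probabilities under independence
# ---------------------------------------------------------------------------

def combination_probability(proportions: Sequence[float],
                            combo: Iterable[int],
                            include_unsatisfied: bool = False) -> float:
    """Chance probability of one gene satisfying a given function combination.

    Under the independence model the probability is the product of the
    satisfaction proportions of the functions in ``combo``.  With
    ``include_unsatisfied`` the (1 - p) factors of the functions outside the
    combination are multiplied in as well (exact-mask probability); the
    default reproduces the published at-least-these-functions figure.
    """
    combo = sorted(set(combo))
    if not combo:
        raise GeroscoreError("combination must be non-empty")
    if any(k < 1 or k > 9 for k in combo):
        raise GeroscoreError(f"evaluation function ids must be in 1..9: {combo}")
    if len(proportions) != 9:
        raise GeroscoreError("need 9 proportions")
    p = 1.0
    for k in combo:
        p *= proportions[k - 1]
    if include_unsatisfied:
        for k in range(1, 10):
            if k not in combo:
                p *= 1.0 - proportions[k - 1]
    return p


def expected_count(p: float, n_genes: int) -> float:
    """Expected number of genes showing the combination by chance."""
    return p * n_genes


# ---------------------------------------------------------------------------
# Candidate identification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    gene: Identifier
    score: Fraction
    satisfied: FrozenSet[int]

    @property
    def displayed(self) -> str:
        return display_score(self.score)


def identify_candidates(evals: Sequence[HypothesisEvaluation],
                        max_tiers: Optional[int] = None) -> List[Candidate]:
    """Highest-scoring genes without curated aging annotations.

    Genes whose score includes a contribution from DEF1 (curated lifespan
    annotation) or DEF5 (lifespan phenotype) are excluded — their role in
    aging is already characterized.  The remainder are ranked by exact
    rational score, ties broken by gene identifier; ``max_tiers`` limits the
    output to the top score tiers.
    """
    pool: List[Candidate] = []
    for es in _event_scores(evals):
        mask = es.mask
        if mask[0] or mask[4]:
            continue
        if es.raw == 0:
            continue
        satisfied = frozenset(k for k in range(1, 10) if mask[k - 1])
        pool.append(Candidate(es.gene, es.normalized, satisfied))
    pool.sort(key=lambda c: (-c.score, c.gene.curie))
    if max_tiers is not None:
        tiers = sorted({c.score for c in pool}, reverse=True)[:max_tiers]
        pool = [c for c in pool if c.score in set(tiers)]
    return pool


# ---------------------------------------------------------------------------
# Distribution comparison
# ---------------------------------------------------------------------------

def compare_distributions(scores_a: Sequence[float],
                          scores_b: Sequence[float],
                          ) -> Tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: statistic D and asymptotic p.

    D is computed directly as the maximum absolute difference between the
    two empirical CDFs; the p-value uses the asymptotic Kolmogorov
    distribution with the standard two-sample effective size.
    """
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise GeroscoreError("both score samples must be non-empty")
    a = np.sort(np.asarray(scores_a, dtype=float))
    b = np.sort(np.asarray(scores_b, dtype=float))
    support = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, support, side="right") / a.size
    cdf_b = np.searchsorted(b, support, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(scipy.stats.kstwobign.sf(d * math.sqrt(n_eff)))
    return d, min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# GO co-occurrence
# ---------------------------------------------------------------------------

def go_cooccurrence(kb: KnowledgeBase,
                    ) -> Dict[Tuple[Identifier, Identifier], int]:
    """Count, for every unordered GO term pair, the entities annotated with
    both.

    Each entity contributes at most 1 to a pair regardless of duplicate
    annotation rows.  Annotations are read from the GOA graph (all aspects)
    and the gene-level GO annotations of the WormBase-like graph.
    """
    entity_terms: Dict[Identifier, set] = {}

    for q in kb.quads(vocab.GRAPHS["goa"]):
        if q.predicate in (vocab.GOA_PROCESS, vocab.GOA_FUNCTION,
                           vocab.GOA_COMPONENT):
            entity_terms.setdefault(q.subject, set()).add(q.obj)

    ann_entity: Dict[Identifier, Identifier] = {}
    ann_terms: Dict[Identifier, set] = {}
    for q in kb.quads(vocab.GRAPHS["wormbase"]):
        if q.predicate == vocab.WB_GO_ANNOTATION:
            ann_entity[q.obj] = q.subject  # type: ignore[index]
        elif q.predicate == vocab.WB_ANNOTATION_TERM:
            ann_terms.setdefault(q.subject, set()).add(q.obj)
    for ann, entity in ann_entity.items():
        for term in ann_terms.get(ann, ()):
            entity_terms.setdefault(entity, set()).add(term)

    table: Dict[Tuple[Identifier, Identifier], int] = {}
    for terms in entity_terms.values():
        ordered = sorted(terms)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                pair = (ordered[i], ordered[j])
                table[pair] = table.get(pair, 0) + 1
    return table


def cooccurrence_to_graph(table: Dict[Tuple[Identifier, Identifier], int],
                          kb: KnowledgeBase) -> int:
    """Serialize a co-occurrence table into the graph role DEF9 consumes."""
    added = 0
    for (a, b), count in sorted(table.items()):
        pair = Identifier("gocooc", f"{a.local_id}-{b.local_id}")
        kb.add_triple(vocab.GRAPHS["go_cooccurrence"], pair, vocab.CO_TERM_A, a)
        kb.add_triple(vocab.GRAPHS["go_cooccurrence"], pair, vocab.CO_TERM_B, b)
        kb.add_triple(vocab.GRAPHS["go_cooccurrence"], pair, vocab.CO_COUNT,
                      Literal(count))
        added += 3
    return added
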