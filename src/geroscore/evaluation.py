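"""The nine evidence-evaluation functions (DEFs) and the event scorer.

Each DEF answers one boolean question about a gene's involvement in aging:

1. curated lifespan annotation ("increase") in the GenAge-like graph;
2. significant differential expression when aging-pathway genes are perturbed;
3. gene or asserted homolog differentially expressed under dietary
   restriction across multiple studies (GenDR-like multi-study list);
4. gene essential for dietary-restriction lifespan extension;
5. extended / shortened lifespan phenotype (on the gene or its knockdown);
6. experimentally evidenced aging-related GO annotation;
7. protein product interacts (via a high-confidence detection method) with a
   protein carrying an aging-related GO process annotation;
8. genetic interaction with a gene that has a lifespan phenotype;
9. GO annotations that co-occur with aging-related GO terms.

An event score is the number of satisfied functions divided by 9, kept as an
exact rational internally and displayed rounded (half away from zero) to two
decimals — 8/9 prints as 0.89, 7/9 as 0.78, 6/9 as 0.67.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Callable, Dict, FrozenSet, List, Sequence, Tuple

import yaml

from . import retrieval, vocab
from .kb import ConfigurationError, GeroscoreError, Identifier, KnowledgeBase

N_DEFS = 9


class ContractViolation(GeroscoreError):
    """A caller broke an operation's precondition."""


@dataclass(frozen=True)
class EvaluationConfig:
    """Tunable thresholds and vocabularies of the aging rule.

    All defaults are the values the nine evidence questions imply; every run
    embeds its effective config in provenance output so evaluations remain
    auditable.
    """

    aging_go_terms: FrozenSet[Identifier] = vocab.AGING_GO_TERMS
    lifespan_phenotypes: FrozenSet[Identifier] = vocab.LIFESPAN_PHENOTYPES
    high_confidence_methods: FrozenSet[Identifier] = vocab.HIGH_CONFIDENCE_METHODS
    expression_p_threshold: float = 0.05
    cooccurrence_min_count: int = 1
    genage_positive_effect: str = "increase"
    #: when True, a curated "decrease" effect also satisfies DEF1
    count_decrease_as_aging: bool = False

    def __post_init__(self) -> None:
        if not self.aging_go_terms:
            raise ConfigurationError("aging_go_terms must be non-empty")
        if not 0.0 < self.expression_p_threshold < 1.0:
            raise ConfigurationError("expression_p_threshold must be in (0,1)")
        if self.cooccurrence_min_count < 1:
            raise ConfigurationError("cooccurrence_min_count must be >= 1")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "aging_go_terms": sorted(t.curie for t in self.aging_go_terms),
            "lifespan_phenotypes": sorted(t.curie for t in self.lifespan_phenotypes),
            "high_confidence_methods": sorted(
                t.curie for t in self.high_confidence_methods),
            "expression_p_threshold": self.expression_p_threshold,
            "cooccurrence_min_count": self.cooccurrence_min_count,
            "genage_positive_effect": self.genage_positive_effect,
            "count_decrease_as_aging": self.count_decrease_as_aging,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationConfig":
        def idents(key):
            return frozenset(Identifier(*c.split(":", 1)) for c in d[key])
        kwargs: dict = {}
        for key in ("aging_go_terms", "lifespan_phenotypes",
                    "high_confidence_methods"):
            if key in d:
                kwargs[key] = idents(key)
        for key in ("expression_p_threshold", "cooccurrence_min_count",
                    "genage_positive_effect", "count_decrease_as_aging"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "EvaluationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class EvidenceResult:
    """One DEF's verdict plus the retrieved facts that back it."""

    def_id: int
    satisfied: bool
    supporting_facts: Tuple = ()
    drfs_called: Tuple[str, ...] = ()

    @property
    def score_contribution(self) -> int:
        return 1 if self.satisfied else 0


@dataclass(frozen=True)
class EventScore:
    gene: Identifier
    def_results: Tuple[EvidenceResult, ...]
    raw: int
    normalized: Fraction

    @property
    def mask(self) -> Tuple[bool, ...]:
        return tuple(r.satisfied for r in sorted(self.def_results,
                                                 key=lambda r: r.def_id))

    @property
    def displayed(self) -> str:
        return display_score(self.normalized)


def display_score(score: Fraction) -> str:
    """Two-decimal display, rounding half away from zero (0.445 -> 0.45)."""
    d = Decimal(score.numerator) / Decimal(score.denominator)
    return str(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# The nine evaluation functions
# ---------------------------------------------------------------------------

def def1_curated_lifespan(kb: KnowledgeBase, cfg: EvaluationConfig,
                          gene: Identifier) -> EvidenceResult:
    """Curated GenAge lifespan effect equals the positive effect string."""
    annotations = retrieval.drf3_genage_lifespan(kb, gene)
    accepted = {cfg.genage_positive_effect}
    if cfg.count_decrease_as_aging:
        accepted.add("decrease")
    hits = tuple(a for a in annotations if a.effect in accepted)
    return EvidenceResult(1, bool(hits), hits,
                          ("drf6_gene_symbol", "drf3_genage_lifespan"))


def def2_differential_expression(kb: KnowledgeBase, cfg: EvaluationConfig,
                                 gene: Identifier) -> EvidenceResult:
    """Significant expression change in an aging-pathway perturbation
    experiment; the direction of the fold change is ignored."""
    hits = tuple(retrieval.get_expression_changes(
        kb, gene, max_p=cfg.expression_p_threshold))
    return EvidenceResult(2, bool(hits), hits, ("get_expression_changes",))


def def3_dr_expression_multistudy(kb: KnowledgeBase, cfg: EvaluationConfig,
                                  gene: Identifier) -> EvidenceResult:
    ok = retrieval.get_gendr_multistudy(kb, gene)
    return EvidenceResult(3, ok, ((gene, "dr_expression_multi_study"),) if ok else (),
                          ("get_gendr_multistudy",))


def def4_dr_essential(kb: KnowledgeBase, cfg: EvaluationConfig,
                      gene: Identifier) -> EvidenceResult:
    ok = retrieval.get_gendr_dr_essential(kb, gene)
    return EvidenceResult(4, ok, ((gene, "dr_essential"),) if ok else (),
                          ("get_gendr_dr_essential",))


def def5_lifespan_phenotype(kb: KnowledgeBase, cfg: EvaluationConfig,
                            gene: Identifier) -> EvidenceResult:
    phenos = retrieval.get_phenotypes(kb, gene)
    hits = tuple(p for p in phenos if p in cfg.lifespan_phenotypes)
    return EvidenceResult(5, bool(hits), hits, ("get_phenotypes",))


def def6_experimental_aging_annotation(kb: KnowledgeBase, cfg: EvaluationConfig,
                                       gene: Identifier) -> EvidenceResult:
    annotations = retrieval.get_gene_go_with_evidence(kb, gene)
    hits = tuple(a for a in annotations
                 if a.term in cfg.aging_go_terms and a.evidence == "experimental")
    return EvidenceResult(6, bool(hits), hits, ("get_gene_go_with_evidence",))


def def7_ppi_aging_neighbors(kb: KnowledgeBase, cfg: EvaluationConfig,
                             gene: Identifier) -> EvidenceResult:
    """A high-confidence physical interactor annotated with an aging process.

    Satisfied iff some interaction record of the gene's protein products uses
    a whitelisted PSI-MI detection method AND its partner carries an aging GO
    process annotation; supporting facts are the witnessing
    (partner, method, term) triples.
    """
    witnesses = []
    for rec in retrieval.drf12_gene_ppi(kb, gene):
        if rec.method not in cfg.high_confidence_methods:
            continue
        for ann in retrieval.drf9_go_process(kb, rec.partner):
            if ann.term in cfg.aging_go_terms:
                witnesses.append((rec.partner, rec.method, ann.term))
    return EvidenceResult(7, bool(witnesses), tuple(witnesses),
                          ("drf12_gene_ppi", "drf9_go_process"))


def def8_interactor_lifespan_phenotype(kb: KnowledgeBase, cfg: EvaluationConfig,
                                       gene: Identifier) -> EvidenceResult:
    hits = []
    for partner, phenos in retrieval.get_gene_interactions(kb, gene):
        lifespan = [p for p in phenos if p in cfg.lifespan_phenotypes]
        if lifespan:
            hits.append((partner, tuple(lifespan)))
    return EvidenceResult(8, bool(hits), tuple(hits), ("get_gene_interactions",))


def def9_cooccurring_annotations(kb: KnowledgeBase, cfg: EvaluationConfig,
                                 gene: Identifier) -> EvidenceResult:
    """Some GO annotation of the gene co-occurs with an aging GO term at
    least ``cooccurrence_min_count`` times in the co-occurrence graph."""
    hits = []
    for ann in retrieval.get_gene_go_with_evidence(kb, gene):
        for aging_term in sorted(cfg.aging_go_terms):
            n = retrieval.get_cooccurrence(kb, ann.term, aging_term)
            if n >= cfg.cooccurrence_min_count:
                hits.append((ann.term, aging_term, n))
    return EvidenceResult(9, bool(hits), tuple(hits),
                          ("get_gene_go_with_evidence", "get_cooccurrence"))


DefFunction = Callable[[KnowledgeBase, EvaluationConfig, Identifier],
                       EvidenceResult]

DEF_REGISTRY: Dict[int, DefFunction] = {
    1: def1_curated_lifespan,
    2: def2_differential_expression,
    3: def3_dr_expression_multistudy,
    4: def4_dr_essential,
    5: def5_lifespan_phenotype,
    6: def6_experimental_aging_annotation,
    7: def7_ppi_aging_neighbors,
    8: def8_interactor_lifespan_phenotype,
    9: def9_cooccurring_annotations,
}


def evaluate_defs(kb: KnowledgeBase, cfg: EvaluationConfig,
                  gene: Identifier) -> List[EvidenceResult]:
    """Run all nine evaluation functions for one gene, in order."""
    return [DEF_REGISTRY[k](kb, cfg, gene) for k in range(1, N_DEFS + 1)]


def score_event(gene: Identifier,
                def_results: Sequence[EvidenceResult]) -> EventScore:
    """Aggregate nine DEF verdicts: raw count and exact normalized score."""
    ids = sorted(r.def_id for r in def_results)
    if ids != list(range(1, N_DEFS + 1)):
        raise ContractViolation(
            f"need exactly one result per evaluation function 1..{N_DEFS}, "
            f"got ids {ids}")
    raw = sum(r.score_contribution for r in def_results)
    return EventScore(gene=gene, def_results=tuple(def_results), raw=raw,
                      normalized=Fraction(raw, N_DEFS))


def score_gene(kb: KnowledgeBase, cfg: EvaluationConfig,
               gene: Identifier) -> EventScore:
    """Convenience: run the nine DEFs and aggregate."""
    return score_event(gene, evaluate_defs(kb, cfg, gene))
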