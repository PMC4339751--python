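"""Data-retrieval functions (DRFs): pure, gene-centric knowledge-base queries.

Each DRF reads one (or, for the composed ones, several) named graphs through
the conjunctive pattern matcher and returns plain records.  Absence of data
is an empty result, never an error — the evidence-evaluation layer decides
what absence means.  Repeated calls on an unchanged knowledge base return
identical results.

Numbered DRFs follow the published subset (DRF1, 3, 6, 8, 9 and the composed
DRF12); the remaining retrievals are named for what they fetch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from . import vocab
from .kb import (CompareFilter, GraphPattern, Identifier, KnowledgeBase,
                 Literal, match)


@dataclass(frozen=True, order=True)
class LifespanAnnotation:
    genage_gene_id: Identifier
    effect: str


@dataclass(frozen=True, order=True)
class InteractionRecord:
    partner: Identifier            # uniprot namespace
    method: Identifier             # psi-mi namespace
    article_count: int


@dataclass(frozen=True, order=True)
class GoAnnotationRecord:
    entity: Identifier
    term: Identifier
    evidence: str                  # "experimental" | "non-experimental"


@dataclass(frozen=True)
class ExpressionChangeRecord:
    gene: Identifier
    cosmid: str
    fold_change: float
    p_value: float
    experiment: Identifier
    derived_from: Tuple[Identifier, ...]


# ---------------------------------------------------------------------------
# Published retrievals
# ---------------------------------------------------------------------------

def drf6_gene_symbol(kb: KnowledgeBase, gene: Identifier) -> Optional[str]:
    """Approved gene symbol for a WormBase gene; ``None`` when absent."""
    sols = match(kb, GraphPattern(
        triples=[(gene, vocab.WB_APPROVED_NAME, "?name")],
        graph=vocab.GRAPHS["wormbase"]))
    if not sols:
        return None
    return str(sols[0]["?name"].value)  # type: ignore[union-attr]


def drf3_genage_lifespan(kb: KnowledgeBase,
                         gene: Identifier) -> List[LifespanAnnotation]:
    """Curated lifespan effects: join the gene's approved symbol to GenAge.

    The join is by exact, case-sensitive symbol string, mirroring the
    published query; a fuzzier join would change results silently.
    """
    symbol = drf6_gene_symbol(kb, gene)
    if symbol is None:
        return []
    sols = match(kb, GraphPattern(
        triples=[("?rec", vocab.GA_GENE_SYMBOL, Literal(symbol)),
                 ("?rec", vocab.GA_LIFESPAN_EFFECT, "?effect")],
        graph=vocab.GRAPHS["genage"]))
    return sorted(LifespanAnnotation(s["?rec"], str(s["?effect"].value))
                  for s in sols)


def drf1_uniprot_ids(kb: KnowledgeBase, symbol: str) -> List[Identifier]:
    """UniProt protein identifiers linked to a gene symbol in the GOA graph."""
    sols = match(kb, GraphPattern(
        triples=[("?prot", vocab.GOA_GENE_SYMBOL, Literal(symbol))],
        graph=vocab.GRAPHS["goa"]))
    return sorted({s["?prot"] for s in sols})


def drf8_ppi(kb: KnowledgeBase, protein: Identifier) -> List[InteractionRecord]:
    """Interactions of one protein: (partner, detection method, article count).

    Interaction records are stored directed (as published) but queried
    symmetrically, so partners are returned whichever side of the record the
    query protein sits on.
    """
    records = set()
    for me, other in ((vocab.IR_INTERACTOR_A, vocab.IR_INTERACTOR_B),
                      (vocab.IR_INTERACTOR_B, vocab.IR_INTERACTOR_A)):
        sols = match(kb, GraphPattern(
            triples=[("?i", me, protein),
                     ("?i", other, "?partner"),
                     ("?i", vocab.IR_METHOD, "?method"),
                     ("?i", vocab.IR_ARTICLE_COUNT, "?n")],
            graph=vocab.GRAPHS["ppi"]))
        for s in sols:
            records.add(InteractionRecord(
                partner=s["?partner"], method=s["?method"],
                article_count=int(s["?n"].value)))  # type: ignore[union-attr]
    return sorted(records)


def drf9_go_process(kb: KnowledgeBase,
                    protein: Identifier) -> List[GoAnnotationRecord]:
    """Biological-process GO annotations of a protein (GOA graph only)."""
    sols = match(kb, GraphPattern(
        triples=[(protein, vocab.GOA_PROCESS, "?term")],
        graph=vocab.GRAPHS["goa"]))
    return sorted(GoAnnotationRecord(protein, s["?term"], "experimental")
                  for s in sols)


@dataclass
class CompositionTrace:
    """Which stage of a composed retrieval emptied, for provenance."""
    symbol: Optional[str] = None
    proteins: List[Identifier] = field(default_factory=list)
    empty_stage: Optional[str] = None


def drf12_gene_ppi(kb: KnowledgeBase, gene: Identifier,
                   trace: Optional[CompositionTrace] = None,
                   ) -> List[InteractionRecord]:
    """Gene-level PPIs: the composition drf6 -> drf1 -> drf8.

    The gene symbol resolves the gene to its UniProt protein products, whose
    interactions are unioned.  An empty stage yields ``[]``; when a
    :class:`CompositionTrace` is supplied it records which stage emptied.
    """
    symbol = drf6_gene_symbol(kb, gene)
    if trace is not None:
        trace.symbol = symbol
    if symbol is None:
        if trace is not None:
            trace.empty_stage = "drf6_gene_symbol"
        return []
    proteins = drf1_uniprot_ids(kb, symbol)
    if trace is not None:
        trace.proteins = proteins
    if not proteins:
        if trace is not None:
            trace.empty_stage = "drf1_uniprot_ids"
        return []
    records = set()
    for prot in proteins:
        records.update(drf8_ppi(kb, prot))
    if not records and trace is not None:
        trace.empty_stage = "drf8_ppi"
    return sorted(records)


# ---------------------------------------------------------------------------
# Auxiliary retrievals, one per remaining evidence question
# ---------------------------------------------------------------------------

def get_phenotypes(kb: KnowledgeBase, gene: Identifier) -> List[Identifier]:
    """Phenotypes asserted on the gene or on its RNAi knockdown."""
    out = set()
    for pred in (vocab.WB_PHENOTYPE, vocab.WB_RNAI_PHENOTYPE):
        for s in match(kb, GraphPattern(
                triples=[(gene, pred, "?ph")], graph=vocab.GRAPHS["wormbase"])):
            out.add(s["?ph"])
    return sorted(out)


def get_expression_changes(kb: KnowledgeBase, gene: Identifier,
                           max_p: Optional[float] = None,
                           ) -> List[ExpressionChangeRecord]:
    """Fold-change records for a gene, optionally filtered by p-value."""
    filters = [] if max_p is None else [CompareFilter("?p", "<", max_p)]
    sols = match(kb, GraphPattern(
        triples=[("?fc", vocab.EX_GENE, gene),
                 ("?fc", vocab.EX_COSMID, "?cosmid"),
                 ("?fc", vocab.EX_FOLD_CHANGE, "?fold"),
                 ("?fc", vocab.EX_P_VALUE, "?p"),
                 ("?fc", vocab.EX_EXPERIMENT, "?exp")],
        graph=vocab.GRAPHS["expression"], filters=filters))
    records = []
    for s in sols:
        derived = match(kb, GraphPattern(
            triples=[(s["?fc"], vocab.EX_DERIVED_FROM, "?v")],
            graph=vocab.GRAPHS["expression"]))
        records.append(ExpressionChangeRecord(
            gene=gene,
            cosmid=str(s["?cosmid"].value),
            fold_change=float(s["?fold"].value),
            p_value=float(s["?p"].value),
            experiment=s["?exp"],
            derived_from=tuple(sorted(d["?v"] for d in derived))))
    return sorted(records, key=lambda r: (r.p_value, r.cosmid))


def _gendr_member(kb: KnowledgeBase, entity: Identifier,
                  the_list: Identifier) -> bool:
    return bool(match(kb, GraphPattern(
        triples=[(entity, vocab.GD_MEMBER_OF, the_list)],
        graph=vocab.GRAPHS["gendr"])))


def get_gendr_multistudy(kb: KnowledgeBase, gene: Identifier) -> bool:
    """Membership (directly or via an asserted homolog) in the multi-study
    dietary-restriction differential-expression list."""
    if _gendr_member(kb, gene, vocab.GENDR_DR_EXPRESSION_MULTI):
        return True
    homologs = match(kb, GraphPattern(
        triples=[(gene, vocab.GD_HOMOLOG, "?h")], graph=vocab.GRAPHS["gendr"]))
    return any(_gendr_member(kb, s["?h"], vocab.GENDR_DR_EXPRESSION_MULTI)
               for s in homologs)


def get_gendr_dr_essential(kb: KnowledgeBase, gene: Identifier) -> bool:
    """Membership in the DR-essential gene list."""
    return _gendr_member(kb, gene, vocab.GENDR_DR_ESSENTIAL)


def get_gene_go_with_evidence(kb: KnowledgeBase, gene: Identifier,
                              ) -> List[GoAnnotationRecord]:
    """The gene's GO annotations with their ECO-derived evidence class."""
    sols = match(kb, GraphPattern(
        triples=[(gene, vocab.WB_GO_ANNOTATION, "?ann"),
                 ("?ann", vocab.WB_ANNOTATION_TERM, "?term"),
                 ("?ann", vocab.WB_ANNOTATION_EVIDENCE, "?eco")],
        graph=vocab.GRAPHS["wormbase"]))
    out = set()
    for s in sols:
        cls = ("experimental"
               if s["?eco"] in vocab.EXPERIMENTAL_EVIDENCE_CODES
               else "non-experimental")
        out.add(GoAnnotationRecord(gene, s["?term"], cls))
    return sorted(out)


def get_gene_interactions(kb: KnowledgeBase, gene: Identifier,
                          ) -> List[Tuple[Identifier, Tuple[Identifier, ...]]]:
    """Genes the query gene genetically interacts with, each paired with its
    phenotypes.  Interactions are queried symmetrically."""
    partners = set()
    for s, o in ((gene, "?g"), ("?g", gene)):
        for sol in match(kb, GraphPattern(
                triples=[(s, vocab.WB_INTERACTS_WITH, o)],
                graph=vocab.GRAPHS["wormbase"])):
            partners.add(sol["?g"])
    return [(g, tuple(get_phenotypes(kb, g))) for g in sorted(partners)]


def get_cooccurrence(kb: KnowledgeBase, term_a: Identifier,
                     term_b: Identifier) -> int:
    """Co-annotation count for an unordered GO term pair (0 when unrecorded)."""
    a, b = sorted((term_a, term_b))
    sols = match(kb, GraphPattern(
        triples=[("?pair", vocab.CO_TERM_A, a),
                 ("?pair", vocab.CO_TERM_B, b),
                 ("?pair", vocab.CO_COUNT, "?n")],
        graph=vocab.GRAPHS["go_cooccurrence"]))
    return sum(int(s["?n"].value) for s in sols)  # type: ignore[union-attr]


#: name -> callable, for the CLI's `retrieve` subcommand and for provenance.
DRF_REGISTRY = {
    "drf1_uniprot_ids": drf1_uniprot_ids,
    "drf3_genage_lifespan": drf3_genage_lifespan,
    "drf6_gene_symbol": drf6_gene_symbol,
    "drf8_ppi": drf8_ppi,
    "drf9_go_process": drf9_go_process,
    "drf12_gene_ppi": drf12_gene_ppi,
    "get_phenotypes": get_phenotypes,
    "get_expression_changes": get_expression_changes,
    "get_gendr_multistudy": get_gendr_multistudy,
    "get_gendr_dr_essential": get_gendr_dr_essential,
    "get_gene_go_with_evidence": get_gene_go_with_evidence,
    "get_gene_interactions": get_gene_interactions,
    "get_cooccurrence": get_cooccurrence,
}
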