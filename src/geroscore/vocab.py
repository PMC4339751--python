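"""Vocabulary: graph roles, predicates, and fixed domain terms.

Predicate namespaces follow the convention that every predicate lives in the
``<dataset>_vocabulary`` namespace of the dataset it occurs in.  The exact
predicate spellings are this package's own (the source databases' RDF
releases each define their own); the set below is the minimal vocabulary the
nine evidence-evaluation functions need.
"""

from .kb import Identifier


def _graph(role: str) -> Identifier:
    return Identifier("graph", role)


# Named-graph roles.
GRAPHS = {
    "wormbase": _graph("wormbase"),
    "genage": _graph("genage"),
    "gendr": _graph("gendr"),
    "ppi": _graph("ppi"),
    "goa": _graph("goa"),
    "expression": _graph("expression"),
    "go_cooccurrence": _graph("go_cooccurrence"),
    "hypotheses": _graph("hypotheses"),
    "provenance": _graph("provenance"),
}

# -- WormBase-like gene graph ------------------------------------------------
WB = "wormbase_vocabulary"
WB_APPROVED_NAME = Identifier(WB, "approved_gene_name")
WB_PHENOTYPE = Identifier(WB, "phenotype")
WB_RNAI_PHENOTYPE = Identifier(WB, "rnai_phenotype")
WB_INTERACTS_WITH = Identifier(WB, "interacts_with")
WB_GO_ANNOTATION = Identifier(WB, "go_annotation")
WB_ANNOTATION_TERM = Identifier(WB, "annotation_term")
WB_ANNOTATION_EVIDENCE = Identifier(WB, "annotation_evidence")

# -- GenAge-like lifespan graph ---------------------------------------------
GA = "genage_vocabulary"
GA_GENE_SYMBOL = Identifier(GA, "gene_symbol")
GA_LIFESPAN_EFFECT = Identifier(GA, "lifespan_effect")

# -- GenDR-like dietary-restriction graphs ----------------------------------
GD = "gendr_vocabulary"
GD_MEMBER_OF = Identifier(GD, "member_of")
GD_HOMOLOG = Identifier(GD, "homolog")
GENDR_DR_EXPRESSION_MULTI = Identifier("gendr", "dr_expression_multi_study")
GENDR_DR_ESSENTIAL = Identifier("gendr", "dr_essential")

# -- iRefIndex-like PPI graph ------------------------------------------------
IR = "irefindex_vocabulary"
IR_INTERACTOR_A = Identifier(IR, "interactor_a")
IR_INTERACTOR_B = Identifier(IR, "interactor_b")
IR_METHOD = Identifier(IR, "detection_method")
IR_ARTICLE_COUNT = Identifier(IR, "article_count")

# -- GOA-like protein annotation graph --------------------------------------
GO_A = "goa_vocabulary"
GOA_GENE_SYMBOL = Identifier(GO_A, "gene_symbol")
GOA_PROCESS = Identifier(GO_A, "process_annotation")
GOA_FUNCTION = Identifier(GO_A, "function_annotation")
GOA_COMPONENT = Identifier(GO_A, "component_annotation")

# -- Expression fold-change graph -------------------------------------------
EX = "expression_vocabulary"
EX_GENE = Identifier(EX, "gene")
EX_COSMID = Identifier(EX, "cosmid")
EX_FOLD_CHANGE = Identifier(EX, "fold_change")
EX_P_VALUE = Identifier(EX, "p_value")
EX_EXPERIMENT = Identifier(EX, "experiment")
EX_DERIVED_FROM = Identifier(EX, "derived_from")

# -- GO co-occurrence graph ---------------------------------------------------
CO = "gocooccurrence_vocabulary"
CO_TERM_A = Identifier(CO, "term_a")
CO_TERM_B = Identifier(CO, "term_b")
CO_COUNT = Identifier(CO, "cooccurrence_count")

# -- Hypothesis model (HO-style) ---------------------------------------------
HO = "ho_vocabulary"
HO_TYPE = Identifier(HO, "a")
HO_CLASS_HYPOTHESIS = Identifier("ho", "Hypothesis")
HO_CLASS_PROPOSITION = Identifier("ho", "Proposition")
HO_CLASS_EVENT = Identifier("ho", "Event")
HO_PROPOSITION = Identifier(HO, "proposition")
HO_OPERATOR = Identifier(HO, "operator")
HO_MEMBER = Identifier(HO, "member")
HO_MEMBER_INDEX = Identifier(HO, "member_index")
HO_EVENT_TYPE = Identifier(HO, "event_type")
HO_AGENT = Identifier(HO, "agent")
HO_TARGET = Identifier(HO, "target")

# -- Evaluation provenance (ovopub-style assertion + metadata) ---------------
EV = "evaluation_vocabulary"
EV_TYPE = Identifier(EV, "a")
EV_CLASS_EVALUATION = Identifier("evaluation", "HypothesisEvaluation")
EV_CREATED = Identifier(EV, "created")
EV_CREATOR = Identifier(EV, "creator")
EV_HYPOTHESIS = Identifier(EV, "hypothesis")
EV_AGENT_GENE = Identifier(EV, "agent_gene")
EV_OVERALL_SCORE = Identifier(EV, "overall_score")
EV_RULE = Identifier(EV, "rule_used")
EV_CONTRIBUTION = Identifier(EV, "contribution")
EV_DEF_ID = Identifier(EV, "evaluation_function")
EV_VALUE = Identifier(EV, "score_value")
EV_DRF = Identifier(EV, "retrieval_function")
EV_NODE_SCORE = Identifier(EV, "node_score")
EV_NODE = Identifier(EV, "node")
EV_SCORE = Identifier(EV, "score")

# -- Fixed domain terms -------------------------------------------------------
GO_AGING = Identifier("go", "0007568")
GO_CELL_AGING = Identifier("go", "0007569")
GO_BEHAVIORAL_DECLINE = Identifier("go", "0035982")
GO_ORGANISMAL_AGING = Identifier("go", "0010259")
GO_ADULT_LIFESPAN = Identifier("go", "0008340")
AGING_GO_TERMS = frozenset({
    GO_AGING, GO_CELL_AGING, GO_BEHAVIORAL_DECLINE,
    GO_ORGANISMAL_AGING, GO_ADULT_LIFESPAN,
})

# WormBase-style lifespan phenotype classes (extended / shortened / variant).
PHENO_EXTENDED_LIFESPAN = Identifier("wbphenotype", "0000060")
PHENO_SHORTENED_LIFESPAN = Identifier("wbphenotype", "0000061")
PHENO_LIFESPAN_VARIANT = Identifier("wbphenotype", "0000062")
LIFESPAN_PHENOTYPES = frozenset({
    PHENO_EXTENDED_LIFESPAN, PHENO_SHORTENED_LIFESPAN, PHENO_LIFESPAN_VARIANT,
})

# PSI-MI high-confidence interaction-detection methods (default whitelist;
# extendable through the run config).
HIGH_CONFIDENCE_METHODS = frozenset({
    Identifier("psi-mi", "0397"),  # two hybrid array
    Identifier("psi-mi", "0398"),  # two hybrid pooling approach
    Identifier("psi-mi", "0676"),  # tandem affinity purification
    Identifier("psi-mi", "0109"),  # tap tag coimmunoprecipitation
})

# ECO-style evidence classes: experimental codes versus inferred ones.
ECO_EXPERIMENTAL = Identifier("eco", "0000006")
ECO_DIRECT_ASSAY = Identifier("eco", "0000314")
ECO_IEA = Identifier("eco", "0000501")
EXPERIMENTAL_EVIDENCE_CODES = frozenset({ECO_EXPERIMENTAL, ECO_DIRECT_ASSAY})
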