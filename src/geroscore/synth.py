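"""Synthetic knowledge-base generator with plantable per-gene evidence.

Every synthetic gene carries a 9-bit mask of intended evaluation-function
outcomes; the generator plants, across the seven source graphs, facts that
are necessary and sufficient for each function to return exactly its mask
bit, and records the ground truth in a ledger.  Interaction partners needed
for the PPI-based functions are drawn from dedicated helper gene/protein
pools that are never scored, so evidence profiles stay independent across
scored genes.

For functions whose bit is FALSE the generator plants near-miss decoys (a
non-significant expression record, a whitelisted-method interaction with a
non-aging partner, an inferred-only aging annotation, an interaction with a
gene lacking lifespan phenotypes) so the discriminating clause of each
function is exercised, not just absence of data.

Default satisfaction probabilities are the per-function satisfaction
proportions observed across the full C. elegans gene complement (DEF1..9:
6.6e-3, 1.3e-1, 2.1e-5, 1.1e-3, 1.4e-2, 1.8e-2, 2.8e-3, 2.5e-2, 1.4e-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import vocab
from .kb import ConfigurationError, Identifier, KnowledgeBase, Literal

#: per-function satisfaction proportions over 48,231 genes (DEF1..DEF9)
DEFAULT_SATISFACTION_PROBS: Tuple[float, ...] = (
    6.6e-3, 1.3e-1, 2.1e-5, 1.1e-3, 1.4e-2, 1.8e-2, 2.8e-3, 2.5e-2, 1.4e-1)

N_GENES_CELEGANS = 48231

G = vocab.GRAPHS


@dataclass(frozen=True)
class SyntheticProfile:
    """Ground truth for one synthetic gene: identity + intended DEF mask."""

    gene: Identifier
    symbol: str
    mask: Tuple[bool, ...]
    #: plant a curated "decrease" lifespan effect (a refuting fact for DEF1)
    refuting_genage_decrease: bool = False

    def __post_init__(self) -> None:
        if len(self.mask) != 9:
            raise ConfigurationError("profile mask must have exactly 9 bits")

    @property
    def raw_score(self) -> int:
        return sum(self.mask)


@dataclass
class GeneratorSpec:
    n_genes: int = 0
    satisfaction_probs: Sequence[float] = DEFAULT_SATISFACTION_PROBS
    explicit_profiles: Sequence[SyntheticProfile] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if len(self.satisfaction_probs) != 9:
            raise ConfigurationError("need 9 satisfaction probabilities")
        if any(not 0.0 <= p <= 1.0 for p in self.satisfaction_probs):
            raise ConfigurationError("satisfaction probabilities must be in [0,1]")


def make_profile(index: int, mask: Sequence[bool],
                 refuting: bool = False) -> SyntheticProfile:
    """Mint the i-th synthetic gene (WBGene9xxxxxxx, symbol syg-<i+1>)."""
    return SyntheticProfile(
        gene=Identifier("wormbase", f"WBGene9{index:07d}"),
        symbol=f"syg-{index + 1}",
        mask=tuple(bool(b) for b in mask),
        refuting_genage_decrease=refuting)


# ---------------------------------------------------------------------------
# Planting one profile
# ---------------------------------------------------------------------------

def plant_profile(kb: KnowledgeBase, profile: SyntheticProfile) -> None:
    """Plant facts across the seven graphs realizing the profile's mask."""
    gene, symbol, mask = profile.gene, profile.symbol, profile.mask
    local = gene.local_id

    # Identity: every gene has an approved symbol and one protein product.
    kb.add_triple(G["wormbase"], gene, vocab.WB_APPROVED_NAME, Literal(symbol))
    protein = Identifier("uniprot", f"SYNP-{local}")
    kb.add_triple(G["goa"], protein, vocab.GOA_GENE_SYMBOL, Literal(symbol))

    # DEF1 — curated lifespan effect.
    if mask[0]:
        rec = Identifier("genage", f"SYN-{local}")
        kb.add_triple(G["genage"], rec, vocab.GA_GENE_SYMBOL, Literal(symbol))
        kb.add_triple(G["genage"], rec, vocab.GA_LIFESPAN_EFFECT,
                      Literal("increase"))
    if profile.refuting_genage_decrease:
        rec = Identifier("genage", f"SYNREF-{local}")
        kb.add_triple(G["genage"], rec, vocab.GA_GENE_SYMBOL, Literal(symbol))
        kb.add_triple(G["genage"], rec, vocab.GA_LIFESPAN_EFFECT,
                      Literal("decrease"))

    # DEF2 — expression: always one non-significant record (decoy), plus a
    # significant one iff the bit is set.
    def expression_record(tag: str, fold: float, p: float) -> None:
        fc = Identifier("geoexp", f"FC-{local}-{tag}")
        kb.add_triple(G["expression"], fc, vocab.EX_GENE, gene)
        kb.add_triple(G["expression"], fc, vocab.EX_COSMID,
                      Literal(f"SYN{local[-5:]}.{tag}"))
        kb.add_triple(G["expression"], fc, vocab.EX_FOLD_CHANGE, Literal(fold))
        kb.add_triple(G["expression"], fc, vocab.EX_P_VALUE, Literal(p))
        kb.add_triple(G["expression"], fc, vocab.EX_EXPERIMENT,
                      Identifier("geo", "GSE9000001"))
        for rep in ("a", "b"):
            kb.add_triple(G["expression"], fc, vocab.EX_DERIVED_FROM,
                          Identifier("geoexp", f"EV-{local}-{tag}{rep}"))

    expression_record("ns", 0.10, 0.50)
    if mask[1]:
        expression_record("sig", 2.50, 0.001)

    # DEF3 — multi-study DR expression via an asserted homolog.
    if mask[2]:
        homolog = Identifier("ensembl", f"SYNHOM-{local}")
        kb.add_triple(G["gendr"], gene, vocab.GD_HOMOLOG, homolog)
        kb.add_triple(G["gendr"], homolog, vocab.GD_MEMBER_OF,
                      vocab.GENDR_DR_EXPRESSION_MULTI)

    # DEF4 — DR-essential list membership.
    if mask[3]:
        kb.add_triple(G["gendr"], gene, vocab.GD_MEMBER_OF,
                      vocab.GENDR_DR_ESSENTIAL)

    # DEF5 — lifespan phenotype on the gene itself.
    if mask[4]:
        pheno = (vocab.PHENO_EXTENDED_LIFESPAN
                 if int(local[-1]) % 2 == 0 else vocab.PHENO_SHORTENED_LIFESPAN)
        kb.add_triple(G["wormbase"], gene, vocab.WB_PHENOTYPE, pheno)

    # DEF6 — experimentally evidenced aging GO annotation; the FALSE decoy is
    # the same term with inferred-only evidence.
    ann6 = Identifier("wormbase", f"SYNANN6-{local}")
    kb.add_triple(G["wormbase"], gene, vocab.WB_GO_ANNOTATION, ann6)
    kb.add_triple(G["wormbase"], ann6, vocab.WB_ANNOTATION_TERM,
                  vocab.GO_ADULT_LIFESPAN)
    kb.add_triple(G["wormbase"], ann6, vocab.WB_ANNOTATION_EVIDENCE,
                  vocab.ECO_DIRECT_ASSAY if mask[5] else vocab.ECO_IEA)

    # DEF7 — high-confidence PPI with an aging-annotated partner protein.
    def interaction(tag: str, partner: Identifier, method: Identifier) -> None:
        node = Identifier("irefindex", f"SYNI-{local}-{tag}")
        kb.add_triple(G["ppi"], node, vocab.IR_INTERACTOR_A, protein)
        kb.add_triple(G["ppi"], node, vocab.IR_INTERACTOR_B, partner)
        kb.add_triple(G["ppi"], node, vocab.IR_METHOD, method)
        kb.add_triple(G["ppi"], node, vocab.IR_ARTICLE_COUNT, Literal(1))

    if mask[6]:
        partner = Identifier("uniprot", f"SYNQ-{local}")
        interaction("hit", partner, Identifier("psi-mi", "0397"))
        kb.add_triple(G["goa"], partner, vocab.GOA_PROCESS,
                      vocab.GO_ADULT_LIFESPAN)
    else:
        # decoy: whitelisted method but a partner with a non-aging process
        decoy = Identifier("uniprot", f"SYND-{local}")
        interaction("decoy", decoy, Identifier("psi-mi", "0397"))
        kb.add_triple(G["goa"], decoy, vocab.GOA_PROCESS,
                      Identifier("go", "0008150"))

    # DEF8 — genetic interaction with a lifespan-phenotype gene (helper pool).
    if mask[7]:
        helper = Identifier("wormbase", f"WBGene8{local[-7:]}")
        kb.add_triple(G["wormbase"], gene, vocab.WB_INTERACTS_WITH, helper)
        kb.add_triple(G["wormbase"], helper, vocab.WB_PHENOTYPE,
                      vocab.PHENO_SHORTENED_LIFESPAN)
    else:
        helper = Identifier("wormbase", f"WBGene7{local[-7:]}")
        kb.add_triple(G["wormbase"], helper, vocab.WB_INTERACTS_WITH, gene)
        kb.add_triple(G["wormbase"], helper, vocab.WB_PHENOTYPE,
                      Identifier("wbphenotype", "0000100"))

    # DEF9 — a gene GO term recorded as co-occurring with an aging term.
    ann9 = Identifier("wormbase", f"SYNANN9-{local}")
    term9 = Identifier("go", f"99{local[-5:]}" if mask[8] else f"98{local[-5:]}")
    kb.add_triple(G["wormbase"], gene, vocab.WB_GO_ANNOTATION, ann9)
    kb.add_triple(G["wormbase"], ann9, vocab.WB_ANNOTATION_TERM, term9)
    kb.add_triple(G["wormbase"], ann9, vocab.WB_ANNOTATION_EVIDENCE,
                  vocab.ECO_IEA)
    if mask[8]:
        a, b = sorted((term9, vocab.GO_ADULT_LIFESPAN))
        pair = Identifier("gocooc", f"{a.local_id}-{b.local_id}")
        kb.add_triple(G["go_cooccurrence"], pair, vocab.CO_TERM_A, a)
        kb.add_triple(G["go_cooccurrence"], pair, vocab.CO_TERM_B, b)
        kb.add_triple(G["go_cooccurrence"], pair, vocab.CO_COUNT, Literal(3))


def generate(spec: GeneratorSpec) -> Tuple[KnowledgeBase, List[SyntheticProfile]]:
    """Build a knowledge base realizing ``spec``; return it with its ledger.

    Random masks are drawn i.i.d. per function from ``satisfaction_probs``
    with a generator seeded by ``spec.seed``, so identical specs yield
    identical knowledge bases.
    """
    rng = np.random.default_rng(spec.seed)
    ledger: List[SyntheticProfile] = list(spec.explicit_profiles)
    probs = np.asarray(spec.satisfaction_probs, dtype=float)
    if spec.n_genes:
        draws = rng.random((spec.n_genes, 9)) < probs
        for i in range(spec.n_genes):
            ledger.append(make_profile(i, tuple(bool(b) for b in draws[i])))
    kb = KnowledgeBase()
    for profile in ledger:
        plant_profile(kb, profile)
    return kb, ledger


# ---------------------------------------------------------------------------
# The sams-1 worked example
# ---------------------------------------------------------------------------

SAMS1_GENE = Identifier("wormbase", "WBGene00008205")
#: synthetic stand-in for the sams-1 bait protein (the printed interaction
#: table lists only partner accessions)
SAMS1_PROTEIN = Identifier("uniprot", "SAMS1")
SAMS1_GENAGE = Identifier("genage", "0584")
#: (partner accession, PSI-MI method) for the 10 printed interaction records
SAMS1_INTERACTIONS: Tuple[Tuple[str, str], ...] = (
    ("O17680", "0397"), ("O17680", "0398"),
    ("P48181", "0676"), ("P48181", "0109"),
    ("P50305", "0397"), ("P50305", "0398"),
    ("P50306", "0397"), ("P50306", "0398"),
    ("Q27522", "0397"), ("Q27522", "0398"),
)
#: intended satisfaction pattern: everything but DEF7
SAMS1_MASK: Tuple[bool, ...] = (True, True, True, True, True, True, False,
                                True, True)


def plant_worked_example_sams1(kb: Optional[KnowledgeBase] = None,
                               ) -> KnowledgeBase:
    """The sams-1 fixture: curated "increase" lifespan effect, the ten
    published interaction records, and facts satisfying every evaluation
    function except DEF7.

    DEF7 fails not for lack of interactions — all ten records use
    whitelisted detection methods — but because every partner's GO process
    annotation (S-adenosylmethionine biosynthesis, go:0006556) is unrelated
    to aging.
    """
    if kb is None:
        kb = KnowledgeBase()
    gene = SAMS1_GENE

    kb.add_triple(G["wormbase"], gene, vocab.WB_APPROVED_NAME,
                  Literal("sams-1"))
    kb.add_triple(G["goa"], SAMS1_PROTEIN, vocab.GOA_GENE_SYMBOL,
                  Literal("sams-1"))

    # DEF1 (TRUE): the curated lifespan record.
    kb.add_triple(G["genage"], SAMS1_GENAGE, vocab.GA_GENE_SYMBOL,
                  Literal("sams-1"))
    kb.add_triple(G["genage"], SAMS1_GENAGE, vocab.GA_LIFESPAN_EFFECT,
                  Literal("increase"))

    # DEF7 (FALSE) / the interaction table: ten (partner, method) records.
    sam_synthesis = Identifier("go", "0006556")
    for n, (partner_acc, method) in enumerate(SAMS1_INTERACTIONS, start=1):
        node = Identifier("irefindex", f"SAMS1-I{n:02d}")
        partner = Identifier("uniprot", partner_acc)
        kb.add_triple(G["ppi"], node, vocab.IR_INTERACTOR_A, SAMS1_PROTEIN)
        kb.add_triple(G["ppi"], node, vocab.IR_INTERACTOR_B, partner)
        kb.add_triple(G["ppi"], node, vocab.IR_METHOD,
                      Identifier("psi-mi", method))
        kb.add_triple(G["ppi"], node, vocab.IR_ARTICLE_COUNT, Literal(1))
    for partner_acc in sorted({p for p, _ in SAMS1_INTERACTIONS}):
        kb.add_triple(G["goa"], Identifier("uniprot", partner_acc),
                      vocab.GOA_PROCESS, sam_synthesis)

    # DEF2 (TRUE): significant expression change under aging-pathway
    # perturbation.
    fc = Identifier("geoexp", "FC-sams1")
    kb.add_triple(G["expression"], fc, vocab.EX_GENE, gene)
    kb.add_triple(G["expression"], fc, vocab.EX_COSMID, Literal("X12A.1"))
    kb.add_triple(G["expression"], fc, vocab.EX_FOLD_CHANGE, Literal(1.8))
    kb.add_triple(G["expression"], fc, vocab.EX_P_VALUE, Literal(0.002))
    kb.add_triple(G["expression"], fc, vocab.EX_EXPERIMENT,
                  Identifier("geo", "GSE36041"))
    kb.add_triple(G["expression"], fc, vocab.EX_DERIVED_FROM,
                  Identifier("geoexp", "EV-sams1-a"))
    kb.add_triple(G["expression"], fc, vocab.EX_DERIVED_FROM,
                  Identifier("geoexp", "EV-sams1-b"))

    # DEF3 (TRUE): mammalian homolog on the multi-study DR list.
    homolog = Identifier("ensembl", "SYNHOM-sams1")
    kb.add_triple(G["gendr"], gene, vocab.GD_HOMOLOG, homolog)
    kb.add_triple(G["gendr"], homolog, vocab.GD_MEMBER_OF,
                  vocab.GENDR_DR_EXPRESSION_MULTI)

    # DEF4 (TRUE): DR-essential.
    kb.add_triple(G["gendr"], gene, vocab.GD_MEMBER_OF,
                  vocab.GENDR_DR_ESSENTIAL)

    # DEF5 (TRUE): extended lifespan phenotype.
    kb.add_triple(G["wormbase"], gene, vocab.WB_PHENOTYPE,
                  vocab.PHENO_EXTENDED_LIFESPAN)

    # DEF6 (TRUE): experimentally evidenced aging annotation.
    ann = Identifier("wormbase", "SAMS1-ANN6")
    kb.add_triple(G["wormbase"], gene, vocab.WB_GO_ANNOTATION, ann)
    kb.add_triple(G["wormbase"], ann, vocab.WB_ANNOTATION_TERM,
                  vocab.GO_ADULT_LIFESPAN)
    kb.add_triple(G["wormbase"], ann, vocab.WB_ANNOTATION_EVIDENCE,
                  vocab.ECO_DIRECT_ASSAY)

    # DEF8 (TRUE): genetic interactor with a lifespan phenotype.
    helper = Identifier("wormbase", "WBGene89990001")
    kb.add_triple(G["wormbase"], gene, vocab.WB_INTERACTS_WITH, helper)
    kb.add_triple(G["wormbase"], helper, vocab.WB_PHENOTYPE,
                  vocab.PHENO_SHORTENED_LIFESPAN)

    # DEF9 (TRUE): the SAM-synthesis term co-occurs with an aging term.
    ann9 = Identifier("wormbase", "SAMS1-ANN9")
    kb.add_triple(G["wormbase"], gene, vocab.WB_GO_ANNOTATION, ann9)
    kb.add_triple(G["wormbase"], ann9, vocab.WB_ANNOTATION_TERM, sam_synthesis)
    kb.add_triple(G["wormbase"], ann9, vocab.WB_ANNOTATION_EVIDENCE,
                  vocab.ECO_IEA)
    a, b = sorted((sam_synthesis, vocab.GO_ADULT_LIFESPAN))
    pair = Identifier("gocooc", f"{a.local_id}-{b.local_id}")
    kb.add_triple(G["go_cooccurrence"], pair, vocab.CO_TERM_A, a)
    kb.add_triple(G["go_cooccurrence"], pair, vocab.CO_TERM_B, b)
    kb.add_triple(G["go_cooccurrence"], pair, vocab.CO_COUNT, Literal(12))

    return kb
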