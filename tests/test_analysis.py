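"""Batch analytics: distributions, frequencies, combinations, candidates."""

import itertools
import math
import random

import numpy as np
import pytest
import scipy.stats

import geroscore as gs
from geroscore.synth import DEFAULT_SATISFACTION_PROBS, N_GENES_CELEGANS

from conftest import FIXED_CLOCK


@pytest.fixture(scope="module")
def synth_evals(synth_kb, cfg):
    kb, ledger = synth_kb
    evals = gs.batch_evaluate(kb, cfg, [p.gene for p in ledger],
                              fixed_clock=FIXED_CLOCK, progress_every=0)
    return evals, ledger


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def test_single_gene_batch(sams1_kb, cfg):
    evals = gs.batch_evaluate(sams1_kb, cfg, [gs.SAMS1_GENE])
    assert len(evals) == 1
    assert evals[0].displayed == "0.89"


def test_batch_equals_gene_by_gene(synth_kb, cfg):
    kb, ledger = synth_kb
    genes = [p.gene for p in ledger]
    batch = gs.batch_evaluate(kb, cfg, genes, fixed_clock=FIXED_CLOCK,
                              progress_every=0)
    singles = [gs.evaluate_gene(kb, cfg, g, fixed_clock=FIXED_CLOCK)
               for g in genes]
    assert [b.overall_score for b in batch] == \
        [s.overall_score for s in singles]
    assert [b.hypothesis for b in batch] == [s.hypothesis for s in singles]


def test_empty_batch_is_error(cfg):
    with pytest.raises(gs.GeroscoreError):
        gs.batch_evaluate(gs.KnowledgeBase(), cfg, [])


def test_top_tier_structure(cfg):
    """A sams-1-style top scorer plus seven 7/9 genes rank 0.89 then 0.78."""
    kb = gs.plant_worked_example_sams1()
    seven_mask = (1, 1, 1, 1, 1, 1, 0, 1, 0)
    profiles = [gs.make_profile(i, seven_mask) for i in range(7)]
    for p in profiles:
        gs.plant_profile(kb, p)
    genes = [gs.SAMS1_GENE] + [p.gene for p in profiles]
    evals = gs.batch_evaluate(kb, cfg, genes, progress_every=0)
    displayed = sorted((ev.displayed for ev in evals), reverse=True)
    assert displayed == ["0.89"] + ["0.78"] * 7


# ---------------------------------------------------------------------------
# Distribution and frequencies
# ---------------------------------------------------------------------------

def test_score_distribution_matches_ledger(synth_evals):
    evals, ledger = synth_evals
    hist = gs.score_distribution(evals)
    assert sum(hist.values()) == len(ledger)
    from fractions import Fraction
    expected = {}
    for p in ledger:
        key = gs.display_score(Fraction(p.raw_score, 9))
        expected[key] = expected.get(key, 0) + 1
    assert hist == expected


def test_score_distribution_edge_cases(cfg):
    assert gs.score_distribution([]) == {}
    kb, ledger = gs.generate(gs.GeneratorSpec(
        explicit_profiles=[gs.make_profile(i, (False,) * 9) for i in range(5)]))
    evals = gs.batch_evaluate(kb, cfg, [p.gene for p in ledger],
                              progress_every=0)
    assert gs.score_distribution(evals) == {"0.00": 5}


def test_def_frequencies_match_ledger(synth_evals):
    evals, ledger = synth_evals
    table = gs.def_frequencies(evals)
    assert table.n_genes == len(ledger)
    for k in range(1, 10):
        expected = sum(p.mask[k - 1] for p in ledger)
        assert table.counts[k - 1] == expected
        assert table.proportion(k) == expected / len(ledger)


def test_def_frequencies_single_gene(cfg):
    kb, ledger = gs.generate(gs.GeneratorSpec(
        explicit_profiles=[gs.make_profile(0, (0, 1, 0, 0, 0, 0, 0, 0, 0))]))
    evals = gs.batch_evaluate(kb, cfg, [ledger[0].gene], progress_every=0)
    table = gs.def_frequencies(evals)
    assert table.proportions == (0, 1.0, 0, 0, 0, 0, 0, 0, 0)


def test_published_def1_proportion_at_two_significant_figures():
    table = gs.DefFrequencyTable(n_genes=N_GENES_CELEGANS,
                                 counts=(317, 6406, 1, 55, 699, 876, 135,
                                         1216, 6899))
    assert f"{table.proportion(1):.1e}" == "6.6e-03"


def test_invalid_def_id_rejected():
    table = gs.DefFrequencyTable(n_genes=10, counts=(1,) * 9)
    with pytest.raises(gs.GeroscoreError):
        table.proportion(10)


# ---------------------------------------------------------------------------
# Combination probability under independence
# ---------------------------------------------------------------------------

def test_combination_probability_published_figure():
    p = gs.combination_probability(DEFAULT_SATISFACTION_PROBS, {2, 7, 8, 9})
    assert f"{p:.1e}" == "1.3e-06"
    assert gs.expected_count(p, N_GENES_CELEGANS) < 1.0


def test_single_function_combo_is_its_proportion():
    for k in range(1, 10):
        assert gs.combination_probability(DEFAULT_SATISFACTION_PROBS, {k}) == \
            DEFAULT_SATISFACTION_PROBS[k - 1]


def test_combination_probability_monotone_nonincreasing():
    combo = set()
    prev = 1.0
    for k in (9, 2, 8, 5, 1):
        combo.add(k)
        p = gs.combination_probability(DEFAULT_SATISFACTION_PROBS, combo)
        assert p <= prev + 1e-15
        assert p <= min(DEFAULT_SATISFACTION_PROBS[j - 1] for j in combo)
        prev = p


def test_combination_probability_matches_monte_carlo():
    """Independent-draw oracle: frequency of the combo over 10^6 masks."""
    rng = np.random.default_rng(77)
    probs = np.array([0.3, 0.2, 0.5, 0.1, 0.4, 0.25, 0.15, 0.35, 0.45])
    combo = {1, 4, 7}
    n = 10 ** 6
    draws = rng.random((n, 9)) < probs
    freq = np.mean(draws[:, [0, 3, 6]].all(axis=1))
    p = gs.combination_probability(probs, combo)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(freq - p) <= 3 * se


def test_exact_mask_variant_smaller():
    loose = gs.combination_probability(DEFAULT_SATISFACTION_PROBS, {2, 9})
    exact = gs.combination_probability(DEFAULT_SATISFACTION_PROBS, {2, 9},
                                       include_unsatisfied=True)
    assert exact < loose


@pytest.mark.parametrize("combo", [set(), {0}, {10}])
def test_combination_probability_rejects_bad_ids(combo):
    with pytest.raises(gs.GeroscoreError):
        gs.combination_probability(DEFAULT_SATISFACTION_PROBS, combo)


# ---------------------------------------------------------------------------
# Candidate identification
# ---------------------------------------------------------------------------

def _candidate_cohort():
    """31 genes satisfying exactly {2,7,8,9}, plus curated and low scorers."""
    profiles = [gs.make_profile(i, (0, 1, 0, 0, 0, 0, 1, 1, 1))
                for i in range(31)]
    # a curated high scorer (DEF1 set) that must be excluded
    profiles.append(gs.make_profile(31, (1, 1, 1, 1, 1, 1, 1, 1, 0)))
    # lower-tier uncurated genes
    profiles += [gs.make_profile(32 + i, (0, 1, 0, 0, 0, 0, 0, 0, 1))
                 for i in range(4)]
    return profiles


def test_candidate_rule_returns_31_at_tier_044(cfg):
    profiles = _candidate_cohort()
    kb, ledger = gs.generate(gs.GeneratorSpec(explicit_profiles=profiles))
    evals = gs.batch_evaluate(kb, cfg, [p.gene for p in ledger],
                              progress_every=0)
    top = gs.identify_candidates(evals, max_tiers=1)
    assert len(top) == 31
    assert all(c.displayed == "0.44" for c in top)
    assert all(c.satisfied == frozenset({2, 7, 8, 9}) for c in top)
    # removing 7 true positives leaves 24 novel candidates
    true_positives = {c.gene for c in top[:7]}
    assert len([c for c in top if c.gene not in true_positives]) == 24


def test_candidates_never_include_def1_or_def5_genes(synth_evals):
    evals, ledger = synth_evals
    candidates = gs.identify_candidates(evals)
    by_gene = {p.gene: p for p in ledger}
    for c in candidates:
        mask = by_gene[c.gene].mask
        assert not mask[0] and not mask[4]
        assert 1 not in c.satisfied and 5 not in c.satisfied


def test_candidates_equal_brute_force_filter_sort(synth_evals):
    evals, ledger = synth_evals
    got = [(c.gene, c.score) for c in gs.identify_candidates(evals)]
    expected = sorted(
        ((p.gene, p.raw_score) for p in ledger
         if not p.mask[0] and not p.mask[4] and p.raw_score > 0),
        key=lambda t: (-t[1], t[0].curie))
    assert got == [(g, gs.score_event(
        g, [gs.EvidenceResult(k, k <= raw) for k in range(1, 10)]).normalized)
        for g, raw in expected]


# ---------------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------------

def test_ks_identical_samples():
    d, p = gs.compare_distributions([0, 0.44, 0.89], [0, 0.44, 0.89])
    assert d == 0.0
    assert p > 0.99


def test_ks_disjoint_supports():
    d, _ = gs.compare_distributions([0.0] * 10, [1.0] * 10)
    assert d == 1.0


def test_ks_statistic_matches_reference():
    rng = random.Random(5)
    for _ in range(20):
        a = [rng.choice([k / 9 for k in range(10)])
             for _ in range(rng.randint(5, 80))]
        b = [rng.choice([k / 9 for k in range(10)])
             for _ in range(rng.randint(5, 80))]
        d, _ = gs.compare_distributions(a, b)
        ref = scipy.stats.ks_2samp(a, b)
        assert abs(d - ref.statistic) < 1e-10


def test_ks_empty_sample_is_error():
    with pytest.raises(gs.GeroscoreError):
        gs.compare_distributions([], [0.5])


# ---------------------------------------------------------------------------
# GO co-occurrence
# ---------------------------------------------------------------------------

def _kb_with_annotations(annotations):
    kb = gs.KnowledgeBase()
    goa = gs.vocab.GRAPHS["goa"]
    for entity, terms in annotations.items():
        for t in terms:
            kb.add_triple(goa, gs.Identifier("uniprot", entity),
                          gs.vocab.GOA_PROCESS, gs.Identifier("go", t))
    return kb


def test_cooccurrence_triangle():
    kb = _kb_with_annotations({"P1": ["0000001", "0000002", "0000003"]})
    table = gs.go_cooccurrence(kb)
    assert len(table) == 3
    assert all(n == 1 for n in table.values())


def test_cooccurrence_single_term_and_duplicates():
    kb = _kb_with_annotations({"P1": ["0000001"],
                               "P2": ["0000002", "0000002", "0000003"]})
    table = gs.go_cooccurrence(kb)
    pair = (gs.Identifier("go", "0000002"), gs.Identifier("go", "0000003"))
    assert table == {pair: 1}  # duplicate rows deduplicated per entity


def test_cooccurrence_matches_brute_force_and_mass_invariant():
    rng = random.Random(31)
    annotations = {
        f"P{i}": [f"{rng.randint(1, 8):07d}" for _ in range(rng.randint(0, 6))]
        for i in range(25)}
    kb = _kb_with_annotations(annotations)
    table = gs.go_cooccurrence(kb)
    # brute-force double loop over deduplicated annotation sets
    expected = {}
    for terms in annotations.values():
        uniq = sorted({gs.Identifier("go", t) for t in terms})
        for a, b in itertools.combinations(uniq, 2):
            expected[(a, b)] = expected.get((a, b), 0) + 1
    assert table == expected
    mass = sum(math.comb(len({t for t in terms}), 2)
               for terms in annotations.values())
    assert sum(table.values()) == mass
    assert all(a < b for (a, b) in table)  # stored on the canonical order


def test_cooccurrence_graph_round_trip_feeds_def9():
    kb = _kb_with_annotations({"P1": ["0008340", "1234567"]})
    table = gs.go_cooccurrence(kb)
    out = gs.KnowledgeBase()
    gs.cooccurrence_to_graph(table, out)
    assert gs.get_cooccurrence(out, gs.Identifier("go", "1234567"),
                               gs.vocab.GO_ADULT_LIFESPAN) == 1
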