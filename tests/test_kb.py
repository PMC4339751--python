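"""Quad store: identifier convention, pattern matching, serialization."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geroscore as gs
from geroscore.kb import CompareFilter, GraphPattern, ValueFilter, is_var

G = gs.vocab.GRAPHS


# ---------------------------------------------------------------------------
# Identifiers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ns,local,uri", [
    ("ncbigene", "181370", "http://bio2rdf.org/ncbigene:181370"),
    ("wormbase", "WBGene00000898", "http://bio2rdf.org/wormbase:WBGene00000898"),
])
def test_identifier_expansion(ns, local, uri):
    ident = gs.mint(ns, local)
    assert gs.expand(ident) == uri
    assert gs.contract(uri) == ident


@settings(max_examples=200, deadline=None, derandomize=True)
@given(ns=st.text(alphabet="abcdefghijklmnopqrstuvwxyz-", min_size=1, max_size=12),
       local=st.text(alphabet=st.characters(blacklist_categories=("Cs",),
                                            blacklist_characters=""),
                     min_size=0, max_size=20))
def test_identifier_round_trip_property(ns, local):
    ident = gs.mint(ns, local)
    assert gs.contract(gs.expand(ident)) == ident


def test_identifier_expansion_injective():
    pairs = [("a", "b:c"), ("go", "0007568"), ("go", "007568"),
             ("goa", "007568")]
    uris = {gs.Identifier(ns, loc).uri for ns, loc in pairs}
    assert len(uris) == len(pairs)
    # colons in the namespace would break injectivity, so they are rejected
    with pytest.raises(gs.ConfigurationError):
        gs.Identifier("a:b", "c")


@pytest.mark.parametrize("uri", [
    "http://example.org/foo:bar",
    "http://bio2rdf.org/nonamespace",
    "urn:ietf:rfc:3986",
])
def test_contract_rejects_nonconvention_uris(uri):
    with pytest.raises(gs.NonConvertibleURIError):
        gs.contract(uri)


def test_mint_requires_namespace():
    with pytest.raises(gs.ConfigurationError):
        gs.mint("", "x")


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

def test_load_empty_turtle_adds_zero_quads(tmp_path):
    path = tmp_path / "empty.ttl"
    path.write_text("")
    kb = gs.KnowledgeBase()
    assert gs.load_graph(kb, str(path), "turtle", G["wormbase"]) == 0
    assert kb.count() == 0


def test_load_three_triple_turtle(tmp_path):
    path = tmp_path / "three.ttl"
    path.write_text(
        "<http://bio2rdf.org/wormbase:WBGene00000001> "
        "<http://bio2rdf.org/wormbase_vocabulary:approved_gene_name> "
        '"aap-1" ;\n'
        "  <http://bio2rdf.org/wormbase_vocabulary:phenotype> "
        "<http://bio2rdf.org/wbphenotype:0000060> , "
        "<http://bio2rdf.org/wbphenotype:0000061> .\n")
    kb = gs.KnowledgeBase()
    assert gs.load_graph(kb, str(path), "turtle", G["wormbase"]) == 3
    assert kb.count(G["wormbase"]) == 3


def test_unknown_format_is_configuration_error(tmp_path):
    path = tmp_path / "x.ttl"
    path.write_text("")
    with pytest.raises(gs.ConfigurationError):
        gs.load_graph(gs.KnowledgeBase(), str(path), "rdfxml", G["wormbase"])


def test_parse_failure_raises(tmp_path):
    path = tmp_path / "bad.ttl"
    path.write_text("this is not turtle {{{")
    with pytest.raises(Exception):
        gs.load_graph(gs.KnowledgeBase(), str(path), "turtle", G["wormbase"])


def test_serialize_reload_round_trip(tmp_path):
    kb, _ = gs.generate(gs.GeneratorSpec(n_genes=15, seed=5))
    nq = tmp_path / "kb.nq"
    gs.save_kb(kb, str(nq))
    assert gs.load_kb(str(nq)) == kb
    for role, graph in G.items():
        if not kb.count(graph):
            continue
        ttl = tmp_path / f"{role}.ttl"
        gs.save_graph(kb, str(ttl), "turtle", graph)
        fresh = gs.KnowledgeBase()
        gs.load_graph(fresh, str(ttl), "turtle", graph)
        assert fresh.multiset(graph) == kb.multiset(graph)


# ---------------------------------------------------------------------------
# Pattern matching vs brute-force nested-loop join oracle
# ---------------------------------------------------------------------------

def _random_kb(rng, n_quads=50):
    kb = gs.KnowledgeBase()
    nodes = [gs.Identifier("ex", f"n{i}") for i in range(8)]
    preds = [gs.Identifier("ex_vocabulary", f"p{i}") for i in range(4)]
    for _ in range(n_quads):
        s = rng.choice(nodes)
        p = rng.choice(preds)
        o = rng.choice(nodes + [gs.Literal(rng.randint(0, 5))])
        kb.add(gs.Quad(s, p, o, G["wormbase"]))
    return kb


def _brute_force_join(kb, pattern):
    """Independent oracle: enumerate every quad tuple and unify by hand."""
    quads = list(kb.quads(pattern.graph))
    results = set()
    for combo in itertools.product(quads, repeat=len(pattern.triples)):
        binding = {}
        ok = True
        for (s, p, o), q in zip(pattern.triples, combo):
            for template, term in ((s, q.subject), (p, q.predicate), (o, q.obj)):
                if is_var(template):
                    if template in binding and binding[template] != term:
                        ok = False
                        break
                    binding[template] = term
                elif template != term:
                    ok = False
                    break
            if not ok:
                break
        if ok and all(f.accepts(binding) for f in pattern.filters):
            results.add(tuple(sorted(binding.items())))
    return results


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_match_equals_brute_force_join(seed):
    rng = random.Random(seed)
    kb = _random_kb(rng)
    p0, p1 = (gs.Identifier("ex_vocabulary", f"p{i}") for i in (0, 1))
    pattern = GraphPattern(
        triples=[("?a", p0, "?b"), ("?b", p1, "?c"), ("?a", "?p", "?c")],
        graph=G["wormbase"])
    got = {tuple(sorted(b.items())) for b in gs.match(kb, pattern)}
    assert got == _brute_force_join(kb, pattern)


def test_match_with_filters_equals_oracle():
    rng = random.Random(7)
    kb = _random_kb(rng, n_quads=60)
    p0 = gs.Identifier("ex_vocabulary", "p0")
    pattern = GraphPattern(
        triples=[("?a", p0, "?n")],
        graph=G["wormbase"],
        filters=[CompareFilter("?n", "<", 3)])
    got = {tuple(sorted(b.items())) for b in gs.match(kb, pattern)}
    assert got == _brute_force_join(kb, pattern)
    assert all(isinstance(dict(b)["?n"], gs.Literal) for b in got)

    allowed = {gs.Identifier("ex", "n0"), gs.Identifier("ex", "n1")}
    pattern2 = GraphPattern(triples=[("?a", p0, "?b")], graph=G["wormbase"],
                            filters=[ValueFilter("?b", allowed)])
    got2 = {tuple(sorted(b.items())) for b in gs.match(kb, pattern2)}
    assert got2 == _brute_force_join(kb, pattern2)


def test_match_empty_kb_and_missing_graph():
    kb = gs.KnowledgeBase()
    pattern = GraphPattern(triples=[("?s", "?p", "?o")])
    assert gs.match(kb, pattern) == []
    kb.add_triple(G["wormbase"], gs.Identifier("ex", "a"),
                  gs.Identifier("ex_vocabulary", "p"), gs.Literal("x"))
    assert gs.match(kb, GraphPattern(triples=[("?s", "?p", "?o")],
                                     graph=G["genage"])) == []


def test_match_single_planted_quad():
    kb = gs.KnowledgeBase()
    s = gs.Identifier("ex", "a")
    p = gs.Identifier("ex_vocabulary", "p")
    kb.add_triple(G["wormbase"], s, p, gs.Literal("x"))
    sols = gs.match(kb, GraphPattern(triples=[(s, p, "?o")]))
    assert sols == [{"?o": gs.Literal("x")}]
    assert gs.ask(kb, GraphPattern(triples=[(s, p, gs.Literal("x"))]))
    assert not gs.ask(kb, GraphPattern(triples=[(s, p, gs.Literal("y"))]))


def test_unbound_filter_variable_is_configuration_error():
    kb = gs.KnowledgeBase()
    pattern = GraphPattern(triples=[("?s", "?p", "?o")],
                           filters=[CompareFilter("?zzz", "<", 1)])
    with pytest.raises(gs.ConfigurationError):
        gs.match(kb, pattern)
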