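# geroscore

Rule-based evidence scoring of gene involvement in aging, over a linked-data
knowledge base.

Research on aging in *Caenorhabditis elegans* has produced a scatter of
curated databases (lifespan-effect annotations, dietary-restriction gene
lists), genome-scale resources (phenotypes, GO annotations, protein–protein
interactions) and experiment-level data (expression changes under
perturbation of aging pathways). No single source answers "is gene *G*
involved in aging?" — but together they accumulate evidence. `geroscore` is
for computational biologists who want that evidence gathered, scored and
audited automatically: it evaluates the hypothesis *"gene G is the agent of
an aging event"* for any number of genes, returning a normalized evidence
score plus a provenance graph that records exactly which facts produced it.

## The model

The knowledge base is a set of named RDF-style graphs, one per source role
(gene/phenotype/GO graph, lifespan annotations, dietary-restriction lists,
protein interactions with PSI-MI detection-method codes, protein GO
annotations, expression fold changes, GO term co-occurrence counts). Every
entity is named by one Bio2RDF-convention URI
(`http://bio2rdf.org/<namespace>:<id>`), so the same gene joins across
graphs without mapping tables.

Nine boolean **data-evaluation functions** (DEF1–DEF9) each answer one
evidence question for a gene — curated lifespan effect, significant
differential expression, dietary-restriction evidence (two forms), lifespan
phenotype, experimentally evidenced aging GO annotation, high-confidence
interaction with an aging-annotated protein, genetic interaction with a
lifespan-phenotype gene, and GO annotation co-occurrence with aging terms.
Each DEF calls pure **data-retrieval functions** over the graphs. The event
score is

    score(G) = (number of satisfied DEFs) / 9

kept as an exact rational and displayed to two decimals (8/9 → 0.89).
Scores propagate bottom-up through a hypothesis tree: AND propositions take
the mean of member scores, OR the maximum, XOR passes its single member
through. The canonical gene hypothesis is a single aging event under XOR,
so its overall score equals the event score.

Downstream analytics cover score histograms, per-DEF satisfaction
frequencies, the independence-model probability of a DEF combination
arising by chance (the product of the satisfied DEFs' proportions),
candidate identification (top-scoring genes with **no** DEF1 or DEF5
contribution, i.e. no existing curated aging annotation), two-sample
Kolmogorov–Smirnov comparison of score distributions, and computation of
the GO co-occurrence table itself.

A synthetic-data generator builds fully self-contained knowledge bases in
which every gene carries a planted 9-bit evidence mask, so the whole
pipeline is testable offline with exact ground truth.

## Worked example

The repository's fixture reproduces the best-characterized positive case,
the S-adenosylmethionine synthetase gene *sams-1*: a curated "increase"
lifespan effect, ten protein-interaction records over five partners (all by
whitelisted detection methods, but none of the partners aging-annotated, so
DEF7 fails), and evidence satisfying the other seven functions.

```
$ geroscore generate-kb --n-genes 15 --seed 4 --sams1 --out kbdir
wrote 417 quads for 15 genes to kbdir
$ geroscore evaluate wormbase:WBGene00008205 --kb kbdir
gene    wormbase:WBGene00008205
def1    1
def2    1
def3    1
def4    1
def5    1
def6    1
def7    0
def8    1
def9    1
raw     8
score   0.89
```

Eight of nine evidence questions are satisfied, giving the displayed score
8/9 = 0.89 — the strongest evidence profile a real gene has shown. The
chance probability of the characteristic candidate combination
DEF{2,7,8,9}, under genome-wide satisfaction proportions:

```
$ geroscore combo-prob 2 7 8 9
probability     1.3e-06
expected_genes  0.061
```

i.e. fewer than one gene genome-wide would show that combination by chance,
so genes that do show it are strong aging-gene candidates.

Python API equivalent:

```python
import geroscore as gs

kb = gs.plant_worked_example_sams1()
ev = gs.evaluate_gene(kb, gs.EvaluationConfig(), gs.SAMS1_GENE)
print(ev.displayed)          # 0.89
```

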