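# Methods

## Evidence model

A hypothesis is a finite tree: leaves are typed events (here, an aging
event, GO:0007568, with a gene as agent), internal nodes are propositions
combining members with AND, OR or XOR. XOR propositions hold exactly one
member; AND/OR hold two or more. A bare single-event hypothesis is
canonicalized by wrapping the event in an XOR proposition, so every
hypothesis has a uniform tree.

Event scoring runs the nine data-evaluation functions (DEFs); each returns
a strict boolean converted to a 0/1 contribution, and the event score is
the satisfied count divided by 9, held as an exact `Fraction`. Proposition
scores are the mean (AND), maximum (OR) or single member (XOR) of member
scores, computed bottom-up; the root score is the overall score. Exact
rationals are used for all comparisons and ranking; only display output is
rounded, half away from zero, to two decimals (so the reachable display
grid is 0.00, 0.11, 0.22, 0.33, 0.44, 0.56, 0.67, 0.78, 0.89, 1.00).
Rounding therefore never reorders raw scores.

Because all nine functions are booleans aggregated by counting, evidence
that refutes a hypothesis lowers the score only by the absence of the
corresponding supporting bit: a curated "decrease" lifespan effect leaves
DEF1 unsatisfied (scoring strictly below an otherwise-identical gene with
"increase"), it does not subtract. A signed scoring variant was considered
and rejected: every observed score in the domain lies on the k/9 grid, and
a penalty term would break the direct interpretation of the score as a
satisfied-evidence fraction.

## Knowledge representation

The store is a multiset of (subject, predicate, object, graph) quads with
Bio2RDF-convention identifiers (`http://bio2rdf.org/<ns>:<id>`; namespaces
may not contain `:` so that expansion is injective and contraction is
exact). Literals carry string/integer/decimal datatypes; numeric filters
compare numerically, strings lexically. The pattern engine supports exactly
what the retrieval functions need — conjunctive triple patterns, VALUES-style
set filters, numeric comparison filters — with naive nested-loop join
semantics over asserted quads only (no inference, no OPTIONAL/UNION). This
keeps the matcher small enough to verify against brute-force enumeration.
Turtle/N-Quads I/O is delegated to rdflib.

## Retrieval and evaluation parameters

All thresholds live in `EvaluationConfig` and the effective values are
embedded in every run's provenance:

- `aging_go_terms` — {go:0007568 aging, go:0007569 cell aging, go:0035982
  age-dependent behavioral decline, go:0010259 multicellular organismal
  aging, go:0008340 determination of adult lifespan}.
- `lifespan_phenotypes` — extended / shortened / variant lifespan phenotype
  classes; both the gene's own phenotypes and RNAi-knockdown phenotypes
  count (the evidence question names either route).
- `high_confidence_methods` — PSI-MI detection-method whitelist; default
  psi-mi:{0397, 0398, 0676, 0109}. The full curated whitelist is deployment
  configuration; it is overridable in YAML without code change.
- `expression_p_threshold` — 0.05 (unitless p-value cutoff); the standard
  significance convention, config-exposed since the evidence question says
  only "significantly".
- `cooccurrence_min_count` — 1: any recorded co-occurrence of a gene's GO
  term with an aging term counts. Raising it demands stronger annotation
  coupling.
- `genage_positive_effect` — "increase"; the flag
  `count_decrease_as_aging` also accepts "decrease" for the broader reading
  of "aging-associated" (off by default: the curated-lifespan rule as
  published tests for lifespan increase).

The gene→lifespan-annotation join is by exact, case-sensitive approved
gene symbol; protein interactions are stored directed as published and
queried symmetrically; the composed gene-level interaction retrieval
(symbol → protein accessions → interactions) records which stage emptied
when it returns nothing.

## Analytics

- Score distribution: histogram over displayed scores.
- DEF frequencies: per-function satisfied counts and proportions
  (count / n).
- Combination probability: under independence, the chance a single gene
  satisfies a given DEF set is the product of those DEFs' genome-wide
  satisfaction proportions. By default the unsatisfied functions contribute
  no (1−p) factors — the quantity is "at least these functions", matching
  how the published figure for DEF{2,7,8,9} is formed; the exact-mask
  variant is available via a flag. Expected gene count is p × n.
- Candidate identification: drop genes with a DEF1 or DEF5 contribution
  (already curated as aging-related), drop zero-score genes, rank the rest
  by exact rational score with ties ordered by gene identifier (the source
  tables give no order; identifier order makes runs reproducible).
- Distribution comparison: two-sample Kolmogorov–Smirnov. D is computed
  in-package from the two empirical CDFs; the p-value uses the asymptotic
  Kolmogorov distribution with effective size n·m/(n+m). Raw (exact) scores
  are compared by default, displayed scores via a flag — the grid is coarse
  enough that the choice rarely matters, but raw scores avoid rounding ties.
- GO co-occurrence: for each annotated entity, every unordered pair of its
  distinct terms increments that pair's count by one (duplicate annotation
  rows are deduplicated first — the statistic counts entities, not rows).
  The table serializes back into the graph role DEF9 consumes.

## Synthetic knowledge bases

The generator plants, per gene, the minimal facts that make each DEF return
exactly its planted mask bit, and records the ground truth in a ledger.
Defaults emulate the study conditions: masks are drawn i.i.d. per function
with the satisfaction proportions observed across the full 48,231-gene
C. elegans complement (6.6×10⁻³, 1.3×10⁻¹, 2.1×10⁻⁵, 1.1×10⁻³, 1.4×10⁻²,
1.8×10⁻², 2.8×10⁻³, 2.5×10⁻², 1.4×10⁻¹ for DEF1–9).

Design points:

- Interaction partners for DEF7/DEF8 come from dedicated helper
  protein/gene pools that are never scored, so planted profiles are
  independent across scored genes and the independence assumption of the
  combination-probability analytic holds by construction in synthetic runs.
- DEF3 is exercised through minted pseudo-homolog identifiers with
  explicit homology assertions, mirroring how dietary-restriction homolog
  membership is actually recorded.
- FALSE bits are planted with near-miss decoys (a p = 0.5 expression
  record, a whitelisted-method interaction with a non-aging partner, an
  inferred-only aging annotation, an interactor without lifespan
  phenotypes) so each function's discriminating clause is tested, not just
  absence of data.
- Same spec + seed reproduces the knowledge base exactly (quad-for-quad,
  and byte-for-byte on serialization).

What the generator does **not** emulate: realistic PPI topology (no
scale-free structure, no shared hubs), annotation-term hierarchies, or
correlated evidence between functions. Passing tests on synthetic bases
therefore demonstrate the correctness of retrieval, evaluation, scoring and
analytics against known ground truth — not predictive performance on real,
correlated biological data.

The `sams-1` worked-example fixture encodes the published retrieval
results for that gene (the curated "increase" record; the ten interaction
records over partners O17680, P48181, P50305, P50306, Q27522 with methods
psi-mi:{0397,0398,0676,0109}) plus facts realizing its full satisfaction
pattern (every function except DEF7). The bait protein's own accession is
not printed in the source tables, so the fixture mints a synthetic stand-in
(`uniprot:SAMS1`).

## Provenance

Each evaluation is emitted as an ovopub-style assertion graph: a typed
evaluation node with creation time and creator, links to the hypothesis,
the agent gene and the stable rule URI, one contribution node per DEF
(0/1 value plus the retrieval functions called) and one score node per tree
node, scores serialized as exact fraction strings. Reloading the graph
reconstructs every score bit-exactly; timestamps are excluded from equality
and a fixed-clock argument makes output byte-stable. The predicate
vocabulary is this package's own minimal set (`src/geroscore/vocab.py`);
it plays the role of the external provenance vocabulary without depending
on it.

## Problem sizes and numerics

The test suite runs cohorts of 9–500 synthetic genes (500 for the
mask-recovery/sampling property, 100 for the provenance round-trip, 60 for
the oracle equivalences), sizes at which every brute-force oracle
(nested-loop join enumeration, Monte-Carlo combination frequency at 10⁶
draws, double-loop co-occurrence) is itself fast and trustworthy. Scoring
involves no floating-point accumulation — all score arithmetic is exact
rational — so the only tolerances in the system are the statistical ones
(3 binomial standard errors for sampled fractions) and the 10⁻¹⁰ agreement
bound between the in-package KS statistic and the reference
implementation.

## Known limitations

- Only conjunctive graph patterns are supported; rules needing OPTIONAL or
  UNION semantics would require extending the matcher.
- The domain-rule registry covers aging events only; other event types
  raise an explicit unsupported-event error rather than a neutral score.
- The independence combination model ignores real correlations between
  evidence sources (e.g. curated lifespan annotations and lifespan
  phenotypes are strongly coupled); it bounds chance co-occurrence, it does
  not model the joint distribution.
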