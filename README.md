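# litmine

Dictionary-based biomedical text mining over BioC XML: entity
recognition with term normalization and disambiguation, co-occurrence +
dependency-path relation extraction with distant-supervision pattern
learning, confidence-ranked output for assisted curation, sentence
filters, and a small REST service.

## Who this is for

Database curators and text-mining engineers who need a self-contained,
inspectable pipeline that turns free text into ranked candidate
annotations: protein–protein interactions for an interaction database,
chemical–disease co-mentions for toxicogenomics triage, or any
terminology-driven entity set. Lexicons are plain TSV tables (surface
form, concept identifier, entity type, preferred name, source database,
optional organism), so in-house vocabularies plug in directly. All data
interchange is BioC XML — collections of documents with passages,
sentences, offset-anchored annotations, relations, and open `infon`
metadata — with both stand-off and in-line serialization.

## The method

**Recognition.** Text is tokenized (Unicode word boundaries;
hyphen/slash splits; punctuation kept) and matched greedily left-to-right
against a lexicon index keyed by a normalized surface form: NFKC folding,
lowercasing, Greek-letter unification (α ↔ alpha), hyphen/slash/space
removal, trailing-plural stripping. The longest token window wins;
ambiguity (one surface, many concepts) is preserved, one annotation per
candidate.

**Disambiguation** resolves three ambiguity classes in a fixed,
idempotent order:

1. *Common-word collisions* (a gene called **folD**, a chemical called
   **SEX**): short or stoplisted surfaces are case-sensitive — their
   matches survive only when the document spells them exactly as the
   lexicon does.
2. *Cross-type conflicts* (**GFP** the protein vs. GFP the fluorescence
   readout): context rules with cue lemmas in a token window pick the
   type; otherwise all types are kept, flagged ambiguous.
3. *Multi-organism identifiers*: a ranked list of focus organisms is
   computed per document, score(o) ∝ #species mentions of o + γ·#gene
   or protein mentions resolvable to o alone (γ = 0.5); identifiers from
   non-focus organisms are pruned, with a recall-preserving fail-safe.

**Relations.** Candidate interactions are entity pairs co-occurring in a
sentence. For each pair, the dependency path signature — the lemma of
the lowest common ancestor plus the downward edge-label sequences to
each entity head, e.g. *(coimmunoprecipitate, [subj], [pobj])* for
"Tim18p coimmunoprecipitated with Tim12p" — is looked up in a pattern
table learned by **distant supervision**: a gold interaction database
projected onto a parsed corpus labels each co-occurring pair (or
sentence) positive or negative, and every path accumulates n_pos/n_neg
counts. A pattern decides *yes* when n_pos/(n_pos+n_neg) ≥ θ (default
0.5). At scoring time, a yes-hit contributes its ratio, a no-hit 0, an
unseen path a backoff prior β = 0.25. Parses are consumed from 6-column
CoNLL-style tables; no parser is bundled.

**Ranking.** Confidence is a weighted product (log-linear, monotone,
closed over [0,1]) of relative in-document frequency, background-corpus
rarity, the type-ambiguity context factor, the syntactic factor, and a
per-concept prior (1 + #gold relations of c)/(1 + #candidates of c).
Candidates are returned rank-ordered with a curation state
(confirm/reject/undecided) and export to CSV.

**Sentence filters.** Boolean conditions over a sentence's annotations
(`has_type(chemical) AND has_type(disease)`, atoms `has_type`,
`has_concept`, `has_term`, `has_relation`; NOT > AND > OR) select the
sentence subset worth a curator's attention and report the character-level
reduction ratio.

## Worked example

```python
from litmine import read_bioc, write_bioc, load_lexicon, process_collection
from litmine.pipeline import PipelineConfig

lexicon = load_lexicon(
    "surface\tconcept_id\tentity_type\tpreferred_name\tsource_db\n"
    "aspirin\tCHEBI:15365\tchemical\taspirin\tChEBI\n"
    "headache\tD006261\tdisease\theadache\tMeSH\n")
coll = read_bioc(
    "<collection><source/><date/><key/><document><id>ex1</id>"
    "<passage><offset>0</offset><text>aspirin treats headache</text>"
    "</passage></document></collection>")
config = PipelineConfig(relation_pairs={frozenset(("chemical", "disease"))})
result = process_collection(coll, lexicon, config)
for r in result.ranked_interactions:
    pair = r.payload
    print(r.rank, f"{r.score:.4f}",
          pair.a.infons["concept_id"], pair.b.infons["concept_id"])
```

prints

```
1 0.0625 CHEBI:15365 D006261
```

one candidate interaction at rank 1: each term has confidence 0.5 (two
entity mentions in the document, each accounting for half), and with no
dependency parse supplied the syntactic factor backs off to 0.25, giving
(0.5 · 0.5) · 0.25 = 0.0625. `write_bioc(result.collection)` returns the
enriched BioC XML with both annotations and the scored relation.

The same pipeline is reachable from the shell (`litmine annotate`,
`litmine relations`, `litmine filter`, `litmine learn-patterns`,
`litmine rank`, `litmine export-csv`, `litmine serve`,
`litmine gen-fixtures`) and over HTTP (`POST /annotate`,
`GET /lexicons`).

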