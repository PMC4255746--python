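# Methods

This note records the modelling and engineering decisions behind
litmine: what each stage assumes, which parameters matter, what the
synthetic corpus generator does and does not emulate, and the known
limitations.

## Data model and offsets

The interchange unit is a BioC collection: documents → passages →
(optionally) sentences, with annotations anchored by document-relative,
0-based **character** offsets (not bytes) and relations referencing
annotation ids. Character offsets are the conventional choice for BioC
tooling and make the offset contract representation-independent of the
encoding. Unknown `infon` keys are preserved verbatim on every element —
curation logs and third-party metadata ride through the pipeline
untouched. The in-line serialization embeds a single `<mark>` element
per annotation, infons as attributes; overlapping spans cannot nest
markers faithfully, so in-line output either rejects overlaps or, under
the `longest-wins` policy, keeps only the longest span of each
overlapping cluster. Stand-off mode is lossless and is the default.

Input sentence segmentation is always preserved. Unsegmented passages
are split on sentence-final punctuation followed by whitespace (text
with no boundary becomes one sentence); downstream stages — candidate
pairing, filters, distant supervision — are defined per sentence and
need this.

## Term normalization

The normalized key is produced by, in order: NFKC compatibility folding,
lowercasing, Greek symbol → name mapping (α→alpha, …), removal of
hyphens/slashes/whitespace, a second NFKC fold (removal can juxtapose
combining marks with new base characters), and trailing-plural stripping
when the key is longer than 3 characters and does not end in "ss" (the
guard makes stripping idempotent: `class` stays `class`). The whole map
is deterministic and idempotent, property-tested over arbitrary Unicode
input. The exact rule inventory for surface-variant matching is an open
design space; this ordered list covers the variation the matcher is
expected to absorb (case, spacing, hyphenation, Greek letters, plurals)
and is deliberately small enough to reason about.

## Matching

Greedy left-to-right longest match over token windows, at most
`max_span` = 8 tokens per window (long multi-word chemical and disease
names fit comfortably; beyond 8 the false-positive surface grows faster
than coverage). Matching never crosses sentence boundaries. The
`requested_types` restriction is applied at emission, *after* matching,
so restricting types is exactly equivalent to post-hoc filtering of the
unrestricted output — a property the service tests rely on. The matcher
is verified against a brute-force every-window oracle.

Case sensitivity: a lexicon surface is flagged case-sensitive when it
has ≤ 5 characters or its lowercase form is in the common-word stoplist.
The package ships a hand-assembled list of ~1500 common English words
(one per line, configurable path and truncation); it exists to catch
collisions such as a gene named like an ordinary word, not to be an
authoritative frequency list.

## Disambiguation

Fixed order, and the sequence is idempotent: common-word filter →
type-conflict resolution → organism ranking → identifier pruning.

* Common-word filter: case-sensitive entries survive only on exact
  surface equality.
* Type conflicts: rules are (normalized pattern, preferred type, cue
  lemmas, token window). First matching rule with a cue in the window
  wins; with no firing rule every candidate type is kept and flagged
  `ambiguous_type` — the flag later halves the context factor instead of
  discarding a possibly correct reading.
* Organism ranking: score(o) = #species mentions + γ·#gene/protein
  mentions whose candidate set is compatible with o alone, normalized to
  sum 1, ties broken by taxonomy id. γ defaults to 0.5: a gene that can
  only belong to one organism is real evidence, but weaker than an
  explicit species mention. The counting formula is this package's own
  concrete instantiation of focus-organism ranking.
* Pruning: candidates from non-focus organisms are removed; survivors
  sort by organism score. If pruning would empty the list, the unpruned
  list is kept (absent organisms scored 0) — the recognizer is tuned for
  recall and the curator takes the final decision, so silently dropping
  the last candidate would be wrong. The merged annotation records its
  full original candidate set in a bookkeeping infon so a re-run prunes
  from the same set; this is what makes the sequence idempotent.

Organism pruning applies to gene/protein types only; chemicals,
diseases and methods are organism-independent.

## Relation extraction

The path signature is (LCA lemma, downward edge labels to the left
entity head, downward edge labels to the right entity head), left/right
assigned by surface order — edge labels only along the paths, the lemma
only at the top. The head of a multi-token entity is the token whose
governor lies outside the span when the parse determines one uniquely,
else the last token (English biomedical names are head-final). LCA
computation is verified against an ancestor-set-intersection oracle on
random trees.

Pattern statistics are raw ratios n_pos/(n_pos+n_neg) without priors;
θ (yes-decision threshold, default 0.5) and minimum support (default 1)
are configurable. Supervision is pair-level by default (a path counts
positive when its entity pair is a gold interaction for that document);
sentence-level labeling — positive iff the sentence contains at least
one gold pair for its document — is also supported, matching the weaker
signal used for novel/background sentence classification. Scoring:
yes-hit → ratio, no-hit → 0, unseen path → β = 0.25 (a weak prior: an
unknown syntactic configuration is possible evidence, worth a quarter of
a certain one), unparsed sentence → factor absent and the candidate kept
(recall again). The dependency parser itself is out of scope; parses
arrive as 6-column CoNLL-style tables or through any callable producing
the same trees.

## Confidence and ranking

A weighted product was chosen over additive mixing because it is
monotone in every factor, maps [0,1]ⁿ into [0,1], and a zero factor
(e.g. a no-decision pattern) correctly annihilates the score. Exponents
default to 1 and are configurable; fitting them to labeled data is left
as grid search by the caller rather than a learned re-ranker. The
background frequency table defaults to empty (no penalty): corpus-wide
term statistics cannot be assumed, and an absent penalty is the neutral
choice. Confidence values have **ordinal** semantics only — they order
candidates and are not calibrated probabilities. Tie-breaking is
documented and deterministic: score descending, then first mention
offset ascending, then concept id; identical inputs yield byte-identical
output.

The per-concept prior (1 + #gold relations of c)/(1 + #candidate pairs
of c) penalizes concepts that co-occur promiscuously but are rarely
curated; the +1 smoothing keeps unseen concepts at weight ≤ 1 without
zeroing anything.

## Sentence filters

Four atoms (`has_type`, `has_concept`, `has_term`, `has_relation`) with
NOT > AND > OR and parentheses — the minimal language supporting
type-pair triage (e.g. regulatory-interaction curation). `has_relation`
is evaluated structurally (two distinct annotations realizing the type
pair in the sentence) so filters need no prior relation-extraction run.
The reduction ratio is measured in characters, since triage effort
scales with the amount of text read; sentence and word counts are easily
derived by callers who prefer them. The engine is verified against a
per-sentence truth-table oracle on random documents × random ASTs.

## Service and CLI

One code path serves both: the CLI subcommands and the `POST /annotate`
handler call the same `process_collection`. The service is a plain WSGI
application (reference server for `litmine serve`), stateless by
construction, so identical requests produce byte-identical responses.
Parameter names (`types`, `relations`, `mode`, `filter`, `lexicon`,
`include_offsets`) and error codes (400 validation, 413 payload size)
are this artifact's own contract. Fetching documents by PubMed
identifier is a pluggable hook, disabled by default and untested — no
network dependency.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes,
not language: documents of template sentences embedding lexicon surfaces
at exactly known offsets, with

* the three ambiguity classes planted at configurable rates
  (common-word genes with folD-style capitalization plus lowercase
  decoys; protein surfaces doubling as experimental methods, with and
  without context cues; protein names shared across organisms, resolved
  by each document's focus organism, which is itself planted via a
  species mention);
* gold interactions realized through a 3-template positive inventory of
  dependency-path shapes and negative co-occurrences through a
  2-template negative inventory, with per-document gold/negative pair
  assignment guaranteed consistent with the distant-supervision sentence
  rule;
* aligned CoNLL parses generated from the same sentence plans, and a
  ground-truth manifest (entity spans, resolved identifiers, sentence
  labels).

Default conditions: 50 documents × 10 sentences, 30 proteins / 12 genes
/ 12 chemicals / 12 diseases / 6 methods over 3 organisms, ambiguity
rates 0.3/0.3/0.4, relation density 0.1 — sized like a small abstract
corpus and large enough that every template and ambiguity class occurs
many times while the whole suite runs in seconds. Same seed →
byte-identical output (the seed is recorded in the manifest header).

What passing on this corpus shows: the bookkeeping — offsets,
normalization, disambiguation logic, path extraction, supervision
projection, score combination — is correct end to end. What it does not
show: robustness to real linguistic variation (misspellings, anaphora,
coordination ambiguity, parser errors), realistic lexicon noise, or
real-corpus precision/recall; entity precision below 100% on the
fixtures reflects deliberately planted unresolved ambiguity (cue-less
cross-type mentions keep both readings by design), not matcher error.

## Numerical and degenerate-input choices

Organism scores normalize to sum 1 (±1e-9 asserted in tests); empty
evidence yields an empty ranking, and pruning then degenerates to a
concept-id-ordered merge. Degenerate paths (both entities sharing a head
token) raise rather than emit a meaningless signature; candidates in
unparsed sentences carry an absent syntactic factor rather than 0.
Monotonicity assertions tolerate 1e-12 of floating-point slack. All
randomness flows through explicit `random.Random(seed)` streams.

## Known limitations

* The in-line annotation dialect cannot represent overlapping spans
  (longest-wins is lossy by design); use stand-off for round-tripping.
* No machine-learned components: type rules are hand-written, the
  re-ranking is a fixed log-linear form, and pattern matching is exact
  (no soft/partial path matching).
* Cross-sentence relations and nested event structures are out of
  scope.
* The tokenizer's hyphen/slash splitting is aggressive; lexicon keys
  absorb this through normalization, but offset consumers see
  punctuation tokens.
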