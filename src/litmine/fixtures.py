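"""Deterministic synthetic fixtures: lexicons, corpora, parses, gold data.

Everything the pipeline consumes can be generated offline with a seed:

* a lexicon exhibiting, at configurable rates, the three ambiguity
  classes — common-word collisions (a gene spelled like an ordinary word,
  distinguishable only by capitalization), cross-type surfaces (the same
  name as protein and experimental method), and multi-organism
  identifiers (the same protein name in several species);
* a BioC corpus whose sentences embed lexicon surfaces at known offsets,
  with gold interactions realized through a small inventory of positive
  dependency-path templates and negative co-occurrences realized through
  negative templates, plus a ground-truth manifest (entity spans,
  resolved identifiers, per-sentence distant-supervision labels);
* CoNLL-style dependency parses consistent with the planted templates.

Sentence text is template-generated English-like filler: the point is
exact offset/identifier/path bookkeeping, not linguistic realism.  The
same seed always yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .bioc import (BioCAnnotation, BioCCollection, BioCDocument, BioCLocation,
                   BioCPassage, BioCRelation, BioCSentence)
from .disambiguation import TypeContextRule
from .terminology import Lexicon, LexiconEntry, default_stoplist, normalize_surface

__all__ = [
    "CorpusBundle",
    "FixtureSpec",
    "build_corpus",
    "gen_corpus_files",
    "gen_lexicon",
    "random_collection",
    "truth_annotations",
]

DEFAULT_ORGANISMS = (
    ("taxon:4932", "Saccharomyces cerevisiae"),
    ("taxon:9606", "Homo sapiens"),
    ("taxon:10090", "Mus musculus"),
)

_SYL = ("ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
        "pa", "ri", "so", "tu", "va", "ze")


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic corpus.

    Rates are probabilities in [0,1]; ``relation_density`` is the chance
    that a content sentence realizes a planted gold interaction.
    """
    seed: int = 42
    n_docs: int = 50
    sentences_per_doc: int = 10
    n_proteins: int = 30
    n_genes: int = 12
    n_chemicals: int = 12
    n_diseases: int = 12
    n_methods: int = 6
    rate_common_word: float = 0.3    # genes colliding with ordinary words
    rate_cross_type: float = 0.3     # protein surfaces doubling as methods
    rate_cross_id: float = 0.4       # protein surfaces shared across organisms
    relation_density: float = 0.1
    negative_density: float = 0.2
    chemdis_density: float = 0.15
    organisms: Sequence = DEFAULT_ORGANISMS


# ---------------------------------------------------------------------------
# lexicon generation

def _name(rng: random.Random, idx: int, suffix: str = "") -> str:
    return (rng.choice(_SYL) + rng.choice(_SYL)).capitalize() + suffix + str(idx)


def gen_lexicon(spec: FixtureSpec, rng: Optional[random.Random] = None):
    """Generate a lexicon + context rules with planted ambiguity.

    Returns (lexicon, type_rules, meta) where meta records which surfaces
    carry which ambiguity so the corpus generator can exploit them.
    """
    rng = rng or random.Random(spec.seed)
    stop = sorted(default_stoplist())
    entries: List[LexiconEntry] = []
    orgs = [o[0] for o in spec.organisms]
    meta = {"proteins": [], "cross_type": [], "common_word": [], "species": {}}

    for taxon, binomial in spec.organisms:
        entries.append(LexiconEntry(binomial, taxon, "species", binomial,
                                    "TAXDB", organism_id=taxon))
        meta["species"][taxon] = binomial

    template_keys = {normalize_surface(w) for w in _TEMPLATE_WORDS}
    common_pool = [w for w in stop
                   if 4 <= len(w) <= 6 and w.isalpha()
                   and normalize_surface(w) not in template_keys]

    for i in range(spec.n_proteins):
        surface = _name(rng, i + 1, "p")
        home = orgs[i % len(orgs)]
        ids = {home: f"PR{i + 1:03d}.{home.split(':')[1]}"}
        if rng.random() < spec.rate_cross_id and len(orgs) > 1:
            other = rng.choice([o for o in orgs if o != home])
            ids[other] = f"PR{i + 1:03d}.{other.split(':')[1]}"
        for org, cid in sorted(ids.items()):
            entries.append(LexiconEntry(surface, cid, "protein", surface.upper(),
                                        "PROTDB", organism_id=org))
        meta["proteins"].append({"surface": surface, "home": home, "ids": ids})
        if rng.random() < spec.rate_cross_type:
            entries.append(LexiconEntry(surface, f"ME{i + 1:03d}", "experimental_method",
                                        f"{surface} assay", "METHDB"))
            meta["cross_type"].append(surface)

    for i in range(spec.n_genes):
        if rng.random() < spec.rate_common_word and common_pool:
            word = common_pool.pop(rng.randrange(len(common_pool)))
            surface = word[:-1] + word[-1].upper()   # folD-style capitalization
            meta["common_word"].append({"surface": surface, "word": word,
                                        "concept_id": f"GN{i + 1:03d}"})
        else:
            surface = _name(rng, i + 1, "g")
        org = orgs[i % len(orgs)]
        entries.append(LexiconEntry(surface, f"GN{i + 1:03d}", "gene",
                                    surface, "GENEDB", organism_id=org))

    for i in range(spec.n_chemicals):
        entries.append(LexiconEntry(_name(rng, i + 1, "ol"), f"CH{i + 1:03d}",
                                    "chemical", f"chemical {i + 1}", "CHEMDB"))
    for i in range(spec.n_diseases):
        base = _name(rng, i + 1, "osis")
        surface = base if rng.random() < 0.5 else f"{base} syndrome"
        entries.append(LexiconEntry(surface, f"DI{i + 1:03d}", "disease",
                                    f"disease {i + 1}", "DISDB"))
    for i in range(spec.n_methods):
        entries.append(LexiconEntry(_name(rng, i + 1, "scopy"), f"MM{i + 1:03d}",
                                    "experimental_method", f"method {i + 1}", "METHDB"))

    rules = [
        TypeContextRule(term_pattern=normalize_surface(s),
                        preferred_type="experimental_method",
                        trigger_context=frozenset({"microscopy", "visualized", "assay"}),
                        window=6)
        for s in meta["cross_type"]
    ]
    return Lexicon(entries), rules, meta


# ---------------------------------------------------------------------------
# sentence templates

def _w(sid, surface, head, label, lemma=None, pos="NN"):
    return {"kind": "w", "id": sid, "surface": surface,
            "lemma": lemma or surface.lower(), "pos": pos,
            "head": head, "label": label}


def _e(slot, head, label):
    return {"kind": "e", "id": slot, "slot": slot, "head": head, "label": label}


# Positive inventory: paths that realize a curated interaction.
TEMPLATE_POS = {
    "pos_coip": [
        _e("A", "v", "subj"),
        _w("v", "coimmunoprecipitated", None, "root", "coimmunoprecipitate", "VBD"),
        _w("p", "with", "v", "modpp", "with", "IN"),
        _e("B", "v", "pobj"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "pos_interact": [
        _e("A", "v", "subj"),
        _w("v", "interacts", None, "root", "interact", "VBZ"),
        _w("r", "directly", "v", "adv", "directly", "RB"),
        _w("p", "with", "v", "modpp", "with", "IN"),
        _e("B", "v", "pobj"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "pos_phos": [
        _w("d", "The", "n", "det", "the", "DT"),
        _w("n", "kinase", "A", "nn", "kinase", "NN"),
        _e("A", "v", "subj"),
        _w("v", "phosphorylates", None, "root", "phosphorylate", "VBZ"),
        _e("B", "v", "obj"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
}

# Negative inventory: co-occurrence without a curated interaction.
TEMPLATE_NEG = {
    "neg_while": [
        _e("A", "v1", "subj"),
        _w("x1", "was", "v1", "aux", "be", "VBD"),
        _w("v1", "purified", None, "root", "purify", "VBN"),
        _w("m", "while", "v2", "mark", "while", "IN"),
        _e("B", "v2", "subj"),
        _w("x2", "was", "v2", "aux", "be", "VBD"),
        _w("v2", "degraded", "v1", "advcl", "degrade", "VBN"),
        _w(".", ".", "v1", "punct", ".", "."),
    ],
    "neg_whereas": [
        _e("A", "v1", "subj"),
        _w("v1", "localized", None, "root", "localize", "VBD"),
        _w("p", "to", "v1", "modpp", "to", "IN"),
        _w("d", "the", "n", "det", "the", "DT"),
        _w("n", "nucleus", "p", "pobj", "nucleus", "NN"),
        _w("m", "whereas", "v2", "mark", "whereas", "IN"),
        _e("B", "v2", "subj"),
        _w("v2", "remained", "v1", "advcl", "remain", "VBD"),
        _w("j", "cytoplasmic", "v2", "pred", "cytoplasmic", "JJ"),
        _w(".", ".", "v1", "punct", ".", "."),
    ],
}

TEMPLATE_OTHER = {
    "intro": [
        _w("d", "These", "n", "det", "these", "DT"),
        _w("n", "experiments", "v", "subj", "experiment", "NNS"),
        _w("x", "were", "v", "aux", "be", "VBD"),
        _w("v", "performed", None, "root", "perform", "VBN"),
        _w("p", "in", "v", "modpp", "in", "IN"),
        _e("SP", "c", "nn"),
        _w("c", "cells", "p", "pobj", "cell", "NNS"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "single": [
        _e("A", "v", "subj"),
        _w("x", "was", "v", "aux", "be", "VBD"),
        _w("v", "overexpressed", None, "root", "overexpress", "VBN"),
        _w("p", "in", "v", "modpp", "in", "IN"),
        _w("d", "these", "c", "det", "these", "DT"),
        _w("c", "cultures", "p", "pobj", "culture", "NNS"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "crosstype_cue": [
        _e("A", "v", "subj"),
        _w("x", "was", "v", "aux", "be", "VBD"),
        _w("v", "visualized", None, "root", "visualize", "VBN"),
        _w("p", "by", "v", "modpp", "by", "IN"),
        _w("f", "fluorescence", "m", "nn", "fluorescence", "NN"),
        _w("m", "microscopy", "p", "pobj", "microscopy", "NN"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "crosstype_nocue": [
        _e("A", "v", "subj"),
        _w("v", "plays", None, "root", "play", "VBZ"),
        _w("d", "an", "n", "det", "an", "DT"),
        _w("j", "essential", "n", "mod", "essential", "JJ"),
        _w("n", "part", "v", "obj", "part", "NN"),
        _w("h", "here", "v", "adv", "here", "RB"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "decoy": [
        _w("d1", "the", "W", "det", "the", "DT"),
        _e("W", "v", "subj"),
        _w("p", "of", "W", "modpp", "of", "IN"),
        _w("d2", "the", "n", "det", "the", "DT"),
        _w("n", "specimen", "p", "pobj", "specimen", "NN"),
        _w("x", "was", "v", "aux", "be", "VBD"),
        _w("v", "measured", None, "root", "measure", "VBN"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "chemdis": [
        _e("C", "n1", "nn"),
        _w("n1", "administration", "v", "subj", "administration", "NN"),
        _w("v", "alleviated", None, "root", "alleviate", "VBD"),
        _e("D", "n2", "nn"),
        _w("n2", "manifestations", "v", "obj", "manifestation", "NNS"),
        _w(".", ".", "v", "punct", ".", "."),
    ],
    "plain": [
        _w("d", "The", "n", "det", "the", "DT"),
        _w("n", "findings", "j", "subj", "finding", "NNS"),
        _w("x", "were", "j", "aux", "be", "VBD"),
        _w("j", "consistent", None, "root", "consistent", "JJ"),
        _w("p", "across", "j", "modpp", "across", "IN"),
        _w("r", "replicates", "p", "pobj", "replicate", "NNS"),
        _w(".", ".", "j", "punct", ".", "."),
    ],
}

_TEMPLATE_WORDS = {
    item["surface"]
    for tpl in list(TEMPLATE_POS.values()) + list(TEMPLATE_NEG.values())
    + list(TEMPLATE_OTHER.values())
    for item in tpl if item["kind"] == "w"
}

POSITIVE_SIGNATURES = {
    "pos_coip": ("coimmunoprecipitate", ("subj",), ("pobj",)),
    "pos_interact": ("interact", ("subj",), ("pobj",)),
    "pos_phos": ("phosphorylate", ("subj",), ("obj",)),
}


@dataclass
class TokenPlan:
    surface: str
    lemma: str
    pos: str
    head: int    # 1-based, 0 = root
    label: str


@dataclass
class SentencePlan:
    template: str
    tokens: List[TokenPlan]
    text: str
    entities: List[dict]   # {slot, start_tok, end_tok, offset, length, ...}
    label: str = "negative"


def _build_sentence(template_name: str, template: list, slot_surfaces: dict) -> SentencePlan:
    """Expand a template with entity surfaces; multiword entities attach
    head-final (each earlier word -> last word, label nn)."""
    tokens: List[TokenPlan] = []
    index_of: Dict[str, int] = {}
    entities = []
    for item in template:
        if item["kind"] == "w":
            tokens.append(TokenPlan(item["surface"], item["lemma"], item["pos"],
                                    0, item["label"]))
            index_of[item["id"]] = len(tokens)
        else:
            words = slot_surfaces[item["slot"]].split(" ")
            start = len(tokens) + 1
            for w in words:
                tokens.append(TokenPlan(w, w.lower(), "NN", 0, "nn"))
            last = len(tokens)
            index_of[item["id"]] = last   # head-final: the slot id is its last token
            entities.append({"slot": item["slot"], "start_tok": start, "end_tok": last})
    # resolve heads
    for item in template:
        if item["kind"] == "w":
            idx = index_of[item["id"]]
            tokens[idx - 1].head = 0 if item["head"] is None else index_of[item["head"]]
            tokens[idx - 1].label = item["label"]
        else:
            last = index_of[item["id"]]
            words = slot_surfaces[item["slot"]].split(" ")
            first = last - len(words) + 1
            for i in range(first, last):
                tokens[i - 1].head = last
                tokens[i - 1].label = "nn"
            tokens[last - 1].head = 0 if item["head"] is None else index_of[item["head"]]
            tokens[last - 1].label = item["label"]
    # character offsets (single spaces between tokens)
    text_parts = []
    offsets = []
    pos = 0
    for t in tokens:
        if text_parts:
            pos += 1
        offsets.append(pos)
        text_parts.append(t.surface)
        pos += len(t.surface)
    text = " ".join(text_parts)
    for e in entities:
        start = offsets[e["start_tok"] - 1]
        end = offsets[e["end_tok"] - 1] + len(tokens[e["end_tok"] - 1].surface)
        e["offset"] = start
        e["length"] = end - start
        e["surface"] = text[start:end]
    return SentencePlan(template_name, tokens, text, entities)


# ---------------------------------------------------------------------------
# corpus generation

@dataclass
class CorpusBundle:
    """A generated corpus with its complete ground truth."""
    spec: FixtureSpec
    collection: BioCCollection            # clean input (no annotations)
    lexicon: Lexicon
    type_rules: list
    gold: set                             # {(doc_id, concept_id, concept_id)}
    conll: str                            # parses for every sentence, in order
    entities: List[tuple]                 # (doc_id, sent_idx, offset, length,
                                          #  surface, concept_id, entity_type)
    sentence_labels: Dict[Tuple[str, int], str]
    sentence_templates: Dict[Tuple[str, int], str]

    def gold_tsv(self) -> str:
        lines = ["document_id\tid1\tid2"]
        for doc_id, a, b in sorted(self.gold):
            lines.append(f"{doc_id}\t{a}\t{b}")
        return "\n".join(lines) + "\n"

    def manifest_tsv(self) -> str:
        lines = [f"# seed={self.spec.seed}",
                 "record\tdoc\tsentence\toffset\tlength\tsurface\tconcept_id\ttype"]
        for row in self.entities:
            lines.append("entity\t" + "\t".join(str(x) for x in row))
        for (doc_id, idx), label in sorted(self.sentence_labels.items()):
            lines.append(f"sentence\t{doc_id}\t{idx}\t\t\t\t{label}\t")
        return "\n".join(lines) + "\n"


def _plan_document(rng: random.Random, spec: FixtureSpec, meta: dict,
                   doc_index: int) -> Tuple[str, list, set]:
    doc_id = f"20{doc_index + 1:06d}"
    orgs = [o[0] for o in spec.organisms]
    focus = orgs[doc_index % len(orgs)]
    usable = [p for p in meta["proteins"] if focus in p["ids"]]
    cross_type = set(meta["cross_type"])

    n_content = spec.sentences_per_doc - 1
    categories = []
    for _ in range(n_content):
        u = rng.random()
        thresholds = [
            (spec.relation_density, "pos"),
            (spec.negative_density, "neg"),
            (spec.chemdis_density, "chemdis"),
            (0.1 if meta["cross_type"] else 0.0, "crosstype_cue"),
            (0.1 if meta["cross_type"] else 0.0, "crosstype_nocue"),
            (0.05 if meta["common_word"] else 0.0, "decoy"),
            (0.05 if meta["common_word"] else 0.0, "commonword_true"),
            (0.25, "single"),
        ]
        acc = 0.0
        cat = "plain"
        for p, name in thresholds:
            acc += p
            if u < acc:
                cat = name
                break
        categories.append(cat)

    # gold pairs first, then negatives avoiding them (within this document)
    doc_gold: set = set()
    pos_pairs = []
    for cat in categories:
        if cat == "pos" and len(usable) >= 2:
            a, b = rng.sample(usable, 2)
            pos_pairs.append((a, b))
            doc_gold.add(frozenset((a["ids"][focus], b["ids"][focus])))
    neg_pairs = []
    for cat in categories:
        if cat == "neg" and len(usable) >= 2:
            for _attempt in range(50):
                a, b = rng.sample(usable, 2)
                if frozenset((a["ids"][focus], b["ids"][focus])) not in doc_gold:
                    neg_pairs.append((a, b))
                    break
            else:
                neg_pairs.append(None)

    return doc_id, categories, (focus, usable, pos_pairs, neg_pairs, doc_gold, cross_type)


def build_corpus(spec: Optional[FixtureSpec] = None) -> CorpusBundle:
    """Generate the full corpus bundle for a fixture spec (deterministic)."""
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    lexicon, rules, meta = gen_lexicon(spec, rng)

    chemicals = [e for e in lexicon.entries if e.entity_type == "chemical"]
    diseases = [e for e in lexicon.entries if e.entity_type == "disease"]
    orgs = {o[0]: o[1] for o in spec.organisms}

    collection = BioCCollection(source="litmine-fixtures", date="2024-01-01",
                                key=f"seed={spec.seed}")
    gold: set = set()
    entities: List[tuple] = []
    labels: Dict[Tuple[str, int], str] = {}
    templates_used: Dict[Tuple[str, int], str] = {}
    conll_lines: List[str] = []

    for d in range(spec.n_docs):
        doc_id, categories, ctx = _plan_document(rng, spec, meta, d)
        focus, usable, pos_pairs, neg_pairs, doc_gold, cross_type = ctx
        for fs in doc_gold:
            a, b = sorted(fs)
            gold.add((doc_id, a, b))

        plans: List[SentencePlan] = []
        sp_surface = orgs[focus]
        plan = _build_sentence("intro", TEMPLATE_OTHER["intro"], {"SP": sp_surface})
        plan.entities[0].update(concept_id=focus, entity_type="species")
        plans.append(plan)

        pos_iter = iter(pos_pairs)
        neg_iter = iter(neg_pairs)
        for cat in categories:
            if cat == "pos":
                try:
                    a, b = next(pos_iter)
                except StopIteration:
                    cat = "plain"
                else:
                    name = rng.choice(sorted(TEMPLATE_POS))
                    plan = _build_sentence(name, TEMPLATE_POS[name],
                                           {"A": a["surface"], "B": b["surface"]})
                    plan.entities[0].update(concept_id=a["ids"][focus], entity_type="protein")
                    plan.entities[1].update(concept_id=b["ids"][focus], entity_type="protein")
                    plan.label = "positive"
                    plans.append(plan)
                    continue
            if cat == "neg":
                pair = next(neg_iter, None)
                if pair is None:
                    cat = "plain"
                else:
                    a, b = pair
                    name = rng.choice(sorted(TEMPLATE_NEG))
                    plan = _build_sentence(name, TEMPLATE_NEG[name],
                                           {"A": a["surface"], "B": b["surface"]})
                    plan.entities[0].update(concept_id=a["ids"][focus], entity_type="protein")
                    plan.entities[1].update(concept_id=b["ids"][focus], entity_type="protein")
                    plans.append(plan)
                    continue
            if cat == "chemdis":
                c = rng.choice(chemicals)
                dis = rng.choice(diseases)
                plan = _build_sentence("chemdis", TEMPLATE_OTHER["chemdis"],
                                       {"C": c.surface, "D": dis.surface})
                plan.entities[0].update(concept_id=c.concept_id, entity_type="chemical")
                plan.entities[1].update(concept_id=dis.concept_id, entity_type="disease")
                plans.append(plan)
                continue
            if cat in ("crosstype_cue", "crosstype_nocue") and cross_type:
                # "biological role" mentions must resolve within the focus
                # organism, else the ground-truth identifier is undefined
                if cat == "crosstype_nocue":
                    pool = sorted(s for s in cross_type
                                  if focus in next(p for p in meta["proteins"]
                                                   if p["surface"] == s)["ids"])
                else:
                    pool = sorted(cross_type)
                if not pool:
                    plans.append(_build_sentence("plain", TEMPLATE_OTHER["plain"], {}))
                    continue
                surface = rng.choice(pool)
                plan = _build_sentence(cat, TEMPLATE_OTHER[cat], {"A": surface})
                if cat == "crosstype_cue":
                    method_id = next(e.concept_id for e in lexicon.entries
                                     if e.surface == surface
                                     and e.entity_type == "experimental_method")
                    plan.entities[0].update(concept_id=method_id,
                                            entity_type="experimental_method")
                else:
                    prot = next(p for p in meta["proteins"] if p["surface"] == surface)
                    plan.entities[0].update(concept_id=prot["ids"][focus],
                                            entity_type="protein")
                plans.append(plan)
                continue
            if cat == "decoy" and meta["common_word"]:
                rec = rng.choice(meta["common_word"])
                plan = _build_sentence("decoy", TEMPLATE_OTHER["decoy"],
                                       {"W": rec["word"]})
                plan.entities = []    # the lowercase word is NOT an entity
                plans.append(plan)
                continue
            if cat == "commonword_true" and meta["common_word"]:
                rec = rng.choice(meta["common_word"])
                plan = _build_sentence("single", TEMPLATE_OTHER["single"],
                                       {"A": rec["surface"]})
                plan.entities[0].update(concept_id=rec["concept_id"], entity_type="gene")
                plans.append(plan)
                continue
            if cat == "single" and usable:
                p = rng.choice(usable)
                plan = _build_sentence("single", TEMPLATE_OTHER["single"],
                                       {"A": p["surface"]})
                plan.entities[0].update(concept_id=p["ids"][focus], entity_type="protein")
                plans.append(plan)
                continue
            plans.append(_build_sentence("plain", TEMPLATE_OTHER["plain"], {}))

        # assemble the document
        doc = BioCDocument(id=doc_id, infons={"focus_organism": focus})
        passage = BioCPassage(offset=0, infons={"type": "abstract"})
        offset = 0
        for idx, plan in enumerate(plans):
            sent = BioCSentence(offset=offset, text=plan.text, index=idx)
            passage.sentences.append(sent)
            labels[(doc_id, idx)] = plan.label
            templates_used[(doc_id, idx)] = plan.template
            for e in plan.entities:
                entities.append((doc_id, idx, offset + e["offset"], e["length"],
                                 e["surface"], e["concept_id"], e["entity_type"]))
            for t_i, t in enumerate(plan.tokens, start=1):
                conll_lines.append("\t".join([str(t_i), t.surface, t.lemma, t.pos,
                                              str(t.head), t.label]))
            conll_lines.append("")
            offset += len(plan.text) + 1   # single space between sentences
        doc.passages.append(passage)
        doc.reindex_sentences()
        collection.documents.append(doc)

    return CorpusBundle(
        spec=spec, collection=collection, lexicon=lexicon, type_rules=rules,
        gold=gold, conll="\n".join(conll_lines) + "\n", entities=entities,
        sentence_labels=labels, sentence_templates=templates_used,
    )


def truth_annotations(bundle: CorpusBundle, doc_id: str) -> List[BioCAnnotation]:
    """Ground-truth annotations for one document, built from the manifest."""
    anns = []
    n = 0
    for rec in bundle.entities:
        if rec[0] != doc_id:
            continue
        n += 1
        _, sent_idx, offset, length, surface, concept_id, etype = rec
        anns.append(BioCAnnotation(
            id=f"{doc_id}.G{n}",
            infons={"type": etype, "concept_id": concept_id,
                    "sentence_index": str(sent_idx), "score": "1.0"},
            locations=[BioCLocation(offset, length)],
            text=surface,
        ))
    return anns


def gen_corpus_files(spec: FixtureSpec, outdir: str) -> dict:
    """Write corpus.xml, lexicon.tsv, gold.tsv, manifest.tsv, parses.conll."""
    import os
    from .bioc import write_bioc
    bundle = build_corpus(spec)
    paths = {}
    for name, content in [
        ("corpus.xml", write_bioc(bundle.collection)),
        ("lexicon.tsv", bundle.lexicon.to_tsv()),
        ("gold.tsv", bundle.gold_tsv()),
        ("manifest.tsv", bundle.manifest_tsv()),
        ("parses.conll", bundle.conll),
    ]:
        path = os.path.join(outdir, name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(content)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# random valid collections (round-trip property fodder)

_RAND_ALPHABET = "abcdefghij klmnop qrstuv wxyz ABCDE 0123456789 αβγδ -/,."


def random_collection(rng: random.Random, max_docs: int = 3) -> BioCCollection:
    """A random structurally valid BioC collection with correct offsets."""
    coll = BioCCollection(
        source=f"src{rng.randrange(100)}", date="2024-01-01",
        key=f"k{rng.randrange(100)}",
        infons={f"ik{i}": f"iv{rng.randrange(100)}" for i in range(rng.randrange(3))},
    )
    for d in range(rng.randrange(1, max_docs + 1)):
        doc = BioCDocument(id=f"doc{d}", infons={"kind": "random"})
        offset = 0
        ann_n = 0
        for _p in range(rng.randrange(1, 3)):
            passage = BioCPassage(offset=offset, infons={"type": "p"})
            segmented = rng.random() < 0.5
            units = []
            if segmented:
                for s in range(rng.randrange(1, 4)):
                    text = "".join(rng.choice(_RAND_ALPHABET)
                                   for _ in range(rng.randrange(10, 40))).strip() or "x"
                    sent = BioCSentence(offset=offset, text=text)
                    passage.sentences.append(sent)
                    units.append(sent)
                    offset += len(text) + 1
            else:
                text = "".join(rng.choice(_RAND_ALPHABET)
                               for _ in range(rng.randrange(15, 60))).strip() or "x"
                passage.text = text
                units.append(passage)
                offset += len(text) + 1
            for unit in units:
                base = unit.offset
                text = unit.text if isinstance(unit, BioCSentence) else unit.text
                for _a in range(rng.randrange(0, 3)):
                    if len(text) < 2:
                        continue
                    start = rng.randrange(0, len(text) - 1)
                    length = rng.randrange(1, min(8, len(text) - start) + 1)
                    ann_n += 1
                    unit.annotations.append(BioCAnnotation(
                        id=f"doc{d}.T{ann_n}",
                        infons={"type": "thing", "concept_id": f"C{ann_n}",
                                "preferred_name": f"N{ann_n}", "score": "0.5"},
                        locations=[BioCLocation(base + start, length)],
                        text=text[start : start + length],
                    ))
            doc.passages.append(passage)
        anns = [a for a in doc.annotations()]
        if len(anns) >= 2 and rng.random() < 0.7:
            a, b = rng.sample(anns, 2)
            doc.passages[0].relations.append(BioCRelation(
                id=f"doc{d}.R1",
                infons={"type": "interaction", "score": "0.5"},
                nodes=[(a.id, "arg1"), (b.id, "arg2")],
            ))
        doc.reindex_sentences()
        coll.documents.append(doc)
    return coll
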