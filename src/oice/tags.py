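"""Canonical Penn-Treebank tag schema for the 27-feature count vector.

The feature space is a fixed, ordered set of 27 Penn Treebank
part-of-speech tags.  All serialization, graph node ordering and
tie-breaking in this package use this canonical order.
"""

from __future__ import annotations

# Canonical order; serialization column order and topological-sort
# tie-breaking both depend on it.
CANONICAL_TAGS: tuple[str, ...] = (
    "NN", "PRP", "VBG", "UH", "NNS", "MD", "JJR", "VB", "IN", "JJ",
    "RP", "PRP$", "CC", "CD", "PDT", "NNP", "TO", "DT", "RB", "VBZ",
    "VBN", "WP", "VBP", "JJS", "VBD", "EX", "WP$",
)

TAG_SET: frozenset[str] = frozenset(CANONICAL_TAGS)

TAG_MEANINGS: dict[str, str] = {
    "NN": "common noun",
    "PRP": "personal pronoun",
    "VBG": "verb, gerund or present participle",
    "UH": "interjection",
    "NNS": "plural noun",
    "MD": "modal verb",
    "JJR": "comparative adjective",
    "VB": "verb, base form",
    "IN": "preposition or subordinating conjunction",
    "JJ": "adjective",
    "RP": "particle",
    "PRP$": "possessive pronoun",
    "CC": "coordinating conjunction",
    "CD": "cardinal number",
    "PDT": "predeterminer",
    "NNP": "singular proper noun",
    "TO": "to",
    "DT": "determiner",
    "RB": "adverb",
    "VBZ": "verb, third-person singular present",
    "VBN": "verb, past participle",
    "WP": "wh-pronoun",
    "VBP": "verb, non-third-person singular present",
    "JJS": "superlative adjective",
    "VBD": "verb, past tense",
    "EX": "existential there",
    "WP$": "possessive wh-pronoun",
}


def canonical_sort_key(name: str):
    """Sort key placing canonical tags in schema order, others after, alphabetically."""
    try:
        return (0, CANONICAL_TAGS.index(name))
    except ValueError:
        return (1, name)
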