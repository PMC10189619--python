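"""Part-of-speech count features for labeled transcripts.

Each speech record is reduced to a fixed 27-dimensional vector of
Penn-Treebank tag counts (see :mod:`oice.tags`).  This module turns raw
text into such vectors via an *injected* tagger function, computes the
per-feature dataset statistics (observed min/max, range, median
absolute deviation) that the counterfactual search and the importance
metrics consume, and reads/writes the CSV feature-table format.

The tagger is a plain ``token -> tag`` callable so the pipeline is
tagger-agnostic; a small rule/lexicon Penn tagger is provided as a
default for users without an external tagger.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tags import CANONICAL_TAGS, TAG_SET

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:\.\d+)?")


@dataclass(frozen=True)
class Transcript:
    """One labeled speech record."""

    record_id: str
    label: str
    text: str


def tokenize(text: str) -> list[str]:
    """Whitespace/punctuation tokenization, case preserved.

    Case is kept because proper-noun (NNP) tagging is case-sensitive.
    """
    return _TOKEN_RE.findall(text)


# Small closed-class lexicon + suffix rules; a deliberately simple
# default so the package works out of the box.  Any token -> Penn tag
# callable may be injected instead.
_LEXICON: dict[str, str] = {
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP", "him": "PRP", "her": "PRP", "them": "PRP",
    "me": "PRP", "us": "PRP",
    "my": "PRP$", "your": "PRP$", "his": "PRP$", "its": "PRP$",
    "our": "PRP$", "their": "PRP$",
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT",
    "all": "PDT", "both": "PDT", "half": "PDT",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "in": "IN", "on": "IN", "of": "IN", "at": "IN", "with": "IN",
    "from": "IN", "because": "IN", "if": "IN", "for": "IN", "by": "IN",
    "into": "IN", "about": "IN",
    "to": "TO",
    "can": "MD", "could": "MD", "will": "MD", "would": "MD", "may": "MD",
    "might": "MD", "shall": "MD", "should": "MD", "must": "MD",
    "there": "EX",
    "who": "WP", "whom": "WP", "what": "WP",
    "whose": "WP$",
    "not": "RB", "very": "RB", "here": "RB", "now": "RB", "then": "RB",
    "um": "UH", "uh": "UH", "oh": "UH", "okay": "UH", "well": "UH",
    "up": "RP", "out": "RP", "off": "RP", "down": "RP", "over": "RP",
    "is": "VBZ", "was": "VBD", "were": "VBD", "are": "VBP", "am": "VBP",
    "be": "VB", "been": "VBN", "being": "VBG",
    "one": "CD", "two": "CD", "three": "CD", "four": "CD", "five": "CD",
}


def default_tagger(token: str) -> str:
    """Rule/lexicon Penn-Treebank tagger used when none is injected."""
    low = token.lower()
    if low in _LEXICON:
        return _LEXICON[low]
    if re.fullmatch(r"\d+(\.\d+)?", token):
        return "CD"
    if token[:1].isupper():
        return "NNP"
    if low.endswith("ing"):
        return "VBG"
    if low.endswith("ed"):
        return "VBD"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("est") and len(low) > 4:
        return "JJS"
    if low.endswith("er") and len(low) > 3:
        return "JJR"
    if low.endswith("s") and not low.endswith("ss"):
        return "NNS"
    return "NN"


def extract_tag_counts(
    transcript: Transcript,
    tagger: Callable[[str], str] | None = None,
) -> dict[str, int]:
    """Count the 27 canonical Penn tags over a transcript's tokens.

    Tags the tagger emits outside the canonical 27-tag set (punctuation
    tags, WDT, WRB, ...) are dropped with a logged warning, keeping the
    feature vector fixed-width.
    """
    tagger = tagger or default_tagger
    counts = {t: 0 for t in CANONICAL_TAGS}
    dropped: set[str] = set()
    for token in tokenize(transcript.text):
        tag = tagger(token)
        if tag in TAG_SET:
            counts[tag] += 1
        else:
            dropped.add(tag)
    if dropped:
        logger.warning(
            "record %s: ignored tags outside the 27-tag schema: %s",
            transcript.record_id, sorted(dropped),
        )
    return counts


@dataclass
class FeatureStats:
    """Per-feature dataset statistics used downstream.

    ``range_`` (max − min, count units) normalizes the cost-of-impact
    metric; ``mad`` (median absolute deviation from the median) weights
    the counterfactual distance.  Reported statistics are never floored;
    the MAD floor is applied only inside the distance function.
    """

    features: list[str]
    min_: pd.Series
    max_: pd.Series
    mad: pd.Series
    range_: pd.Series = field(init=False)

    def __post_init__(self):
        self.range_ = self.max_ - self.min_
        if (self.range_ < 0).any():
            raise ValueError("min > max in feature statistics")


def compute_feature_stats(dataset: pd.DataFrame | Sequence[Mapping[str, float]]) -> FeatureStats:
    """Observed min/max/range and MAD for every feature column."""
    if not isinstance(dataset, pd.DataFrame):
        dataset = pd.DataFrame(list(dataset))
    if len(dataset) == 0:
        raise ValueError("cannot compute feature statistics from an empty dataset")
    med = dataset.median(axis=0)
    mad = (dataset - med).abs().median(axis=0)
    return FeatureStats(
        features=list(dataset.columns),
        min_=dataset.min(axis=0).astype(float),
        max_=dataset.max(axis=0).astype(float),
        mad=mad.astype(float),
    )


# ---------------------------------------------------------------------------
# Feature-table CSV I/O: header = record_id,label,<27 tags in canonical order>
# ---------------------------------------------------------------------------

def write_feature_table(path: str | Path, counts: pd.DataFrame, labels: Sequence[str]) -> None:
    """Write a feature table; ``counts`` indexed by record id, tag columns."""
    missing = [t for t in CANONICAL_TAGS if t not in counts.columns]
    if missing:
        raise ValueError(f"feature table missing tag columns: {missing}")
    out = counts[list(CANONICAL_TAGS)].copy()
    out.insert(0, "label", list(labels))
    out.index.name = "record_id"
    out.to_csv(path)


def load_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Load and validate a feature-table CSV.

    Returns (counts DataFrame indexed by record_id with the 27 tag
    columns in canonical order, label Series).
    """
    df = pd.read_csv(path, index_col="record_id")
    missing = [t for t in CANONICAL_TAGS if t not in df.columns]
    if missing:
        raise ValueError(f"feature table missing tag columns: {missing}")
    extra = [c for c in df.columns if c not in TAG_SET and c != "label"]
    if extra:
        raise ValueError(f"feature table has unexpected columns: {extra}")
    if "label" not in df.columns:
        raise ValueError("feature table missing 'label' column")
    counts = df[list(CANONICAL_TAGS)]
    for row_pos, (rid, row) in enumerate(counts.iterrows()):
        for tag, v in row.items():
            if v < 0 or float(v) != int(v):
                raise ValueError(
                    f"invalid count at row {row_pos} (record {rid}), column {tag}: {v}"
                )
    return counts.astype(int), df["label"]


def read_transcript_manifest(path: str | Path) -> list[Transcript]:
    """Read a TSV manifest (record_id, label, path) of UTF-8 text files."""
    base = Path(path).parent
    manifest = pd.read_csv(path, sep="\t", names=["record_id", "label", "path"], header=0)
    out = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        out.append(Transcript(str(row["record_id"]), str(row["label"]), p.read_text("utf-8")))
    return out


def extract_dataset(
    transcripts: Iterable[Transcript],
    tagger: Callable[[str], str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Tag every transcript and assemble the cohort feature table."""
    rows, labels, ids = [], [], []
    for tr in transcripts:
        rows.append(extract_tag_counts(tr, tagger))
        labels.append(tr.label)
        ids.append(tr.record_id)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in dataset")
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="record_id"), columns=list(CANONICAL_TAGS))
    return counts, pd.Series(labels, index=counts.index, name="label")
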