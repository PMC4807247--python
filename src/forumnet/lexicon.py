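"""Dictionary-based word-category counting (LIWC-style).

A lexicon maps words to one or more category labels drawn from a fixed
hierarchy of 7 main categories -- function words, social, affective,
cognitive, perceptual, biological and relativity -- each with
subcategories, including affective -> {positive, negative -> {anxious,
angry, sad}} and the pronoun chain function -> pronoun -> {first_person,
second_person, third_person}. A word in a subcategory counts toward every
ancestor (hierarchical roll-up), a multi-category word increments each of
its categories, and a token counts once toward the tagged total no matter
how many categories it hits. Occurrence rates are percentages of a unit's
total token count, the standard LIWC convention.

The proprietary dictionaries this mirrors (LIWC / SC-LIWC) are not
redistributable; the package ships a small synthetic English toy lexicon
covering the full main-category hierarchy, plus a loader for any
dictionary in the documented tab-delimited format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import ForumCorpus, occurrence_percentage

__all__ = [
    "CATEGORY_PARENT",
    "MAIN_CATEGORIES",
    "Lexicon",
    "LinguisticProfile",
    "load_lexicon",
    "builtin_toy_lexicon",
    "tag_tokens",
    "profile_unit",
    "member_profiles",
    "corpus_tag_rate",
    "affect_subgroups",
    "word_frequencies",
]

MAIN_CATEGORIES = (
    "function",
    "social",
    "affective",
    "cognitive",
    "perceptual",
    "biological",
    "relativity",
)

#: child category -> parent category; main categories map to None.
CATEGORY_PARENT: dict[str, str | None] = {
    **{c: None for c in MAIN_CATEGORIES},
    # function words
    "pronoun": "function",
    "first_person": "pronoun",
    "second_person": "pronoun",
    "third_person": "pronoun",
    "article": "function",
    "negation": "function",
    "quantifier": "function",
    "preposition": "function",
    "conjunction": "function",
    # social
    "family": "social",
    "friend": "social",
    "communication": "social",
    # affective
    "positive": "affective",
    "negative": "affective",
    "anxious": "negative",
    "angry": "negative",
    "sad": "negative",
    # cognitive
    "insight": "cognitive",
    "causation": "cognitive",
    "certainty": "cognitive",
    "tentative": "cognitive",
    # perceptual
    "see": "perceptual",
    "hear": "perceptual",
    "feel": "perceptual",
    # biological
    "body": "biological",
    "health": "biological",
    # relativity
    "motion": "relativity",
    "space": "relativity",
    "time": "relativity",
}

#: The 13 linguistic properties reported per unit: total word count, the 7
#: main-category rates, the two affect subcategories and the three pronoun
#: persons.
PROFILE_CATEGORIES = MAIN_CATEGORIES + (
    "positive",
    "negative",
    "first_person",
    "second_person",
    "third_person",
)


class LexiconError(ValueError):
    pass


@dataclass
class Lexicon:
    """Word -> category-label-set dictionary over the fixed hierarchy."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    hierarchy: dict[str, str | None] = field(default_factory=lambda: dict(CATEGORY_PARENT))

    def __post_init__(self) -> None:
        for word, labels in self.entries.items():
            for lab in labels:
                if lab not in self.hierarchy:
                    raise LexiconError(f"word {word!r}: unknown category {lab!r}")

    def ancestors(self, label: str) -> list[str]:
        out = []
        parent = self.hierarchy.get(label)
        while parent is not None:
            out.append(parent)
            parent = self.hierarchy.get(parent)
        return out

    def categories_with_rollup(self, word: str) -> frozenset[str]:
        """All categories a word counts toward, ancestors included."""
        labels = self.entries.get(word)
        if not labels:
            return frozenset()
        full = set()
        for lab in labels:
            full.add(lab)
            full.update(self.ancestors(lab))
        return frozenset(full)

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a tab-delimited dictionary: ``word<TAB>label[,label...]``.

    Blank lines and ``#`` comments are skipped; a word listed on several
    lines gets the union of its labels. Unknown labels raise
    :class:`LexiconError`; an entry-free file is rejected.
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(f"{path}:{lineno}: expected 'word<TAB>labels'")
            word, labs = parts[0].strip(), parts[1]
            labels = {lab.strip() for lab in labs.split(",") if lab.strip()}
            if not labels:
                raise LexiconError(f"{path}:{lineno}: no labels for {word!r}")
            entries.setdefault(word, set()).update(labels)
    if not entries:
        raise LexiconError(f"{path}: empty lexicon")
    return Lexicon(entries={w: frozenset(s) for w, s in entries.items()})


def builtin_toy_lexicon() -> Lexicon:
    """The shipped ~100-word synthetic toy dictionary."""
    with resources.as_file(
        resources.files("forumnet.data").joinpath("toy_lexicon.tsv")
    ) as p:
        return load_lexicon(p)


# ---------------------------------------------------------------------------
# counting


def tag_tokens(tokens, lexicon: Lexicon) -> dict:
    """Count category hits in a token sequence.

    Returns ``{"word_count", "tagged_count", "counts": {category: n}}``.
    Each token increments every category it belongs to (with hierarchical
    roll-up) but counts once toward ``tagged_count``; unknown tokens only
    increase ``word_count``.
    """
    counts: dict[str, int] = {}
    tagged = 0
    n = 0
    for tok in tokens:
        n += 1
        cats = lexicon.categories_with_rollup(tok)
        if cats:
            tagged += 1
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
    return {"word_count": n, "tagged_count": tagged, "counts": counts}


@dataclass
class LinguisticProfile:
    """Per-unit (member or thread) occurrence rates in percent of tokens."""

    unit_id: str
    word_count: int
    tagged_count: int
    counts: dict[str, int]
    empty: bool = False

    @property
    def tag_rate(self) -> float:
        return 0.0 if self.empty else occurrence_percentage(self.tagged_count, self.word_count)

    def rate(self, category: str) -> float:
        if self.empty:
            return 0.0
        return occurrence_percentage(self.counts.get(category, 0), self.word_count)

    @property
    def rates(self) -> dict[str, float]:
        return {c: self.rate(c) for c in PROFILE_CATEGORIES}


def _pool_messages(messages, lexicon: Lexicon, unit_id: str) -> LinguisticProfile:
    word_count = 0
    tagged = 0
    counts: dict[str, int] = {}
    for msg in messages:
        if not msg.text_available:
            continue  # deleted-account text: skipped, never zero-counted
        rec = tag_tokens(msg.tokens, lexicon)
        word_count += rec["word_count"]
        tagged += rec["tagged_count"]
        for c, v in rec["counts"].items():
            counts[c] = counts.get(c, 0) + v
    return LinguisticProfile(
        unit_id=unit_id,
        word_count=word_count,
        tagged_count=tagged,
        counts=counts,
        empty=word_count == 0,
    )


def profile_unit(corpus: ForumCorpus, lexicon: Lexicon, unit: str) -> LinguisticProfile:
    """Linguistic profile of one member id or thread id.

    Counts are pooled over all of the unit's messages with available text,
    then standardized to occurrence rates (% of pooled tokens). A unit
    whose pooled text is empty gets all-zero rates with ``empty=True``.
    """
    by_thread = {t.thread_id: t for t in corpus.threads}
    if unit in by_thread:
        return _pool_messages(by_thread[unit].messages, lexicon, unit)
    if unit in corpus.members:
        msgs = [m for m in corpus.iter_messages() if m.author == unit]
        return _pool_messages(msgs, lexicon, unit)
    raise KeyError(f"unknown member or thread id {unit!r}")


def member_profiles(corpus: ForumCorpus, lexicon: Lexicon) -> dict[str, LinguisticProfile]:
    """Profiles for every member who posted, in one corpus pass.

    Members whose text is entirely unavailable (deleted accounts) are
    excluded -- they have network structure but no linguistic denominator.
    """
    buckets: dict[str, list] = {}
    available: dict[str, bool] = {}
    for msg in corpus.iter_messages():
        buckets.setdefault(msg.author, []).append(msg)
        if msg.text_available:
            available[msg.author] = True
    return {
        m: _pool_messages(msgs, lexicon, m)
        for m, msgs in buckets.items()
        if available.get(m, False)
    }


def corpus_tag_rate(corpus: ForumCorpus, lexicon: Lexicon) -> float:
    """% of tokens (over messages with available text) matching the lexicon."""
    total = 0
    tagged = 0
    for msg in corpus.iter_messages():
        if not msg.text_available:
            continue
        rec = tag_tokens(msg.tokens, lexicon)
        total += rec["word_count"]
        tagged += rec["tagged_count"]
    return occurrence_percentage(tagged, total)


def affect_subgroups(profiles) -> dict[str, float]:
    """Split members by affect-word usage into four percentage groups.

    ``negative_only`` / ``positive_only`` / ``both`` / ``neither``, summing
    to 100. ``profiles`` is an iterable of :class:`LinguisticProfile`.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("affect_subgroups needs at least one profile")
    n = len(profiles)
    groups = {"negative_only": 0, "positive_only": 0, "both": 0, "neither": 0}
    for p in profiles:
        pos = p.counts.get("positive", 0) > 0
        neg = p.counts.get("negative", 0) > 0
        key = (
            "both"
            if pos and neg
            else "positive_only"
            if pos
            else "negative_only"
            if neg
            else "neither"
        )
        groups[key] += 1
    return {k: occurrence_percentage(v, n) for k, v in groups.items()}


def word_frequencies(corpus: ForumCorpus):
    """Ranked token-frequency table (for external word-cloud rendering).

    Returns a pandas DataFrame with columns ``token`` and ``count``,
    descending by count, ties broken lexically.
    """
    import pandas as pd

    counts: dict[str, int] = {}
    for msg in corpus.iter_messages():
        if not msg.text_available:
            continue
        for tok in msg.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(items, columns=["token", "count"])
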