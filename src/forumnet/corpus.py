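"""Threaded-forum corpus: data model, line-record I/O, summaries, and a
seeded synthetic generator.

A corpus is a set of discussion threads. Each thread is opened by an
initiator and collects timestamped messages; a message may reply to the
thread at large (conventionally addressed to the initiator) or to one
specific earlier message. Text is stored pre-tokenized so the pipeline is
segmentation-agnostic; a tokenizer (e.g. jieba for Chinese) is a plug-in at
the ingestion boundary, not a dependency.

Serialization is one self-describing JSON record per line (``.jsonl``):
``{"type": "thread", ...}`` followed by its ``{"type": "message", ...}``
records. Timestamps are ordinal integers; ``tokens: null`` marks a message
whose text is unavailable (e.g. a deleted account) while its reply-to
structure is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "Message",
    "Thread",
    "ForumCorpus",
    "GeneratorParams",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "generate_corpus",
    "corpus_summary",
    "occurrence_percentage",
]


class CorpusFormatError(ValueError):
    """A record violates the corpus format or a structural invariant."""


def occurrence_percentage(count: float, total: float) -> float:
    """Percentage ``100 * count / total``; raises on a zero denominator.

    Single definition used for every rate in the package (tag rates,
    category occurrence rates, component shares) so all percentages share
    one convention.
    """
    if total == 0:
        raise ZeroDivisionError("percentage undefined for a zero total")
    return 100.0 * count / total


@dataclass(frozen=True)
class Message:
    """One forum message.

    ``reply_to`` names an earlier message in the same thread; ``None``
    means the message addresses the thread at large (by convention, its
    initiator). ``tokens is None`` marks unavailable text (deleted
    account); an empty tuple is a real, empty message.
    """

    message_id: str
    thread_id: str
    author: str
    timestamp: int
    reply_to: str | None = None
    tokens: tuple[str, ...] | None = ()

    @property
    def text_available(self) -> bool:
        return self.tokens is not None


@dataclass(frozen=True)
class Thread:
    thread_id: str
    initiator: str
    created_time: int
    title: str
    messages: tuple[Message, ...]

    def validate(self) -> None:
        if not self.messages:
            raise CorpusFormatError(f"thread {self.thread_id}: no opening message")
        first = self.messages[0]
        if first.author != self.initiator:
            raise CorpusFormatError(
                f"thread {self.thread_id}: opening message author {first.author!r}"
                f" is not the initiator {self.initiator!r}"
            )
        seen: dict[str, int] = {}
        prev = None
        for msg in self.messages:
            if msg.thread_id != self.thread_id:
                raise CorpusFormatError(
                    f"message {msg.message_id}: thread_id {msg.thread_id!r}"
                    f" does not match containing thread {self.thread_id!r}"
                )
            if prev is not None and msg.timestamp < prev:
                raise CorpusFormatError(
                    f"thread {self.thread_id}: message {msg.message_id}"
                    " breaks timestamp ordering"
                )
            if msg.reply_to is not None:
                if msg.reply_to not in seen:
                    raise CorpusFormatError(
                        f"message {msg.message_id}: reply_to {msg.reply_to!r}"
                        f" is not an earlier message of thread {self.thread_id}"
                    )
                if seen[msg.reply_to] >= msg.timestamp:
                    raise CorpusFormatError(
                        f"message {msg.message_id}: reply_to target is not"
                        " strictly earlier"
                    )
            seen[msg.message_id] = msg.timestamp
            prev = msg.timestamp

    @property
    def participants(self) -> set[str]:
        return {m.author for m in self.messages}


@dataclass
class ForumCorpus:
    threads: list[Thread] = field(default_factory=list)
    members: set[str] = field(default_factory=set)

    def validate(self) -> None:
        thread_ids: set[str] = set()
        message_ids: set[str] = set()
        for t in self.threads:
            if t.thread_id in thread_ids:
                raise CorpusFormatError(f"duplicate thread_id {t.thread_id!r}")
            thread_ids.add(t.thread_id)
            t.validate()
            for m in t.messages:
                if m.message_id in message_ids:
                    raise CorpusFormatError(f"duplicate message_id {m.message_id!r}")
                message_ids.add(m.message_id)
                if m.author not in self.members:
                    raise CorpusFormatError(
                        f"message {m.message_id}: author {m.author!r} not in"
                        " member roster"
                    )

    def iter_messages(self) -> Iterator[Message]:
        for t in self.threads:
            yield from t.messages

    @property
    def n_messages(self) -> int:
        return sum(len(t.messages) for t in self.threads)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ForumCorpus):
            return NotImplemented
        return self.threads == other.threads and self.members == other.members


# ---------------------------------------------------------------------------
# line-record I/O


def _message_to_record(m: Message) -> dict:
    return {
        "type": "message",
        "message_id": m.message_id,
        "thread_id": m.thread_id,
        "author": m.author,
        "timestamp": m.timestamp,
        "reply_to": m.reply_to,
        "tokens": None if m.tokens is None else list(m.tokens),
    }


def write_corpus(corpus: ForumCorpus, path: str | Path) -> None:
    """Write a corpus as one JSON record per line.

    The member roster is written first so that members who never posted
    (a legal, if unusual, state) survive a round trip.
    """
    corpus.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"type": "roster", "members": sorted(corpus.members)}) + "\n")
        for t in corpus.threads:
            fh.write(
                json.dumps(
                    {
                        "type": "thread",
                        "thread_id": t.thread_id,
                        "initiator": t.initiator,
                        "created_time": t.created_time,
                        "title": t.title,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            for m in t.messages:
                fh.write(json.dumps(_message_to_record(m), ensure_ascii=False) + "\n")


def read_corpus(
    path: str | Path,
    tokenizer: Callable[[str], list[str]] | None = None,
) -> ForumCorpus:
    """Read a line-record corpus file.

    Records may carry ``"text"`` instead of ``"tokens"``; in that case
    ``tokenizer`` (e.g. ``jieba.lcut``) must be supplied to segment it.
    Malformed records raise :class:`CorpusFormatError` naming the offending
    thread/message; nothing is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    members: set[str] = set()
    threads: list[Thread] = []
    pending: dict | None = None
    pending_msgs: list[Message] = []

    def flush() -> None:
        nonlocal pending, pending_msgs
        if pending is not None:
            threads.append(Thread(messages=tuple(pending_msgs), **pending))
            pending, pending_msgs = None, []

    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON") from exc
            kind = rec.get("type")
            if kind == "roster":
                members.update(rec["members"])
            elif kind == "thread":
                flush()
                try:
                    pending = {
                        "thread_id": rec["thread_id"],
                        "initiator": rec["initiator"],
                        "created_time": int(rec["created_time"]),
                        "title": rec.get("title", ""),
                    }
                except KeyError as exc:
                    raise CorpusFormatError(f"line {lineno}: thread record missing {exc}")
            elif kind == "message":
                if pending is None:
                    raise CorpusFormatError(
                        f"line {lineno}: message record outside a thread block"
                    )
                if "tokens" in rec:
                    toks = rec["tokens"]
                    tokens = None if toks is None else tuple(toks)
                elif "text" in rec:
                    if tokenizer is None:
                        raise CorpusFormatError(
                            f"line {lineno}: raw text present but no tokenizer given"
                        )
                    tokens = tuple(tokenizer(rec["text"]))
                else:
                    raise CorpusFormatError(
                        f"line {lineno}: message needs 'tokens' or 'text'"
                    )
                try:
                    msg = Message(
                        message_id=rec["message_id"],
                        thread_id=rec["thread_id"],
                        author=rec["author"],
                        timestamp=int(rec["timestamp"]),
                        reply_to=rec.get("reply_to"),
                        tokens=tokens,
                    )
                except KeyError as exc:
                    raise CorpusFormatError(f"line {lineno}: message record missing {exc}")
                pending_msgs.append(msg)
                members.add(msg.author)
            else:
                raise CorpusFormatError(f"line {lineno}: unknown record type {kind!r}")
    flush()
    for t in threads:
        members.add(t.initiator)
    corpus = ForumCorpus(threads=threads, members=members)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# summaries


def corpus_summary(corpus: ForumCorpus) -> dict:
    """Descriptive statistics: counts, thread-participant histogram.

    Returns a plain dict so it serializes directly to JSON. The histogram
    maps participants-per-thread -> number of threads.
    """
    hist: dict[int, int] = {}
    n_messages = 0
    for t in corpus.threads:
        p = len(t.participants)
        hist[p] = hist.get(p, 0) + 1
        n_messages += len(t.messages)
    return {
        "n_threads": len(corpus.threads),
        "n_messages": n_messages,
        "n_members": len(corpus.members),
        "participants_histogram": dict(sorted(hist.items())),
        "max_participants": max(hist) if hist else 0,
        "modal_participants": max(hist, key=lambda k: (hist[k], -k)) if hist else 0,
    }


# ---------------------------------------------------------------------------
# synthetic generator


@dataclass
class GeneratorParams:
    """Parameters of the synthetic forum generator.

    Defaults emulate a large single-disease online health group: ~5050
    members, 3700 threads, ~40k messages, thread-participant counts with
    mode 2 and a heavy tail capped at 276, heavy-tailed member activity,
    and per-member category-mixture text in which function words run near
    50% of tokens, negative affect outweighs positive, and first-person
    pronouns dominate.

    participant distribution: a thread has 1 participant with probability
    ``p_single_participant``; otherwise ``1 + Z`` participants where ``Z``
    follows a discrete power law (Zipf) with exponent
    ``participant_power`` truncated at ``max_participants - 1``, so the
    mode sits at 2.
    """

    n_members: int = 5050
    n_threads: int = 3700
    seed: int = 0

    # thread participation
    p_single_participant: float = 0.15
    participant_power: float = 2.0
    max_participants: int = 276
    # messages
    replier_extra_mean: float = 2.2  # extra messages per replier, Poisson
    initiator_followup_mean: float = 0.04  # untargeted initiator follow-ups
    reply_to_specific: float = 0.35  # else addressed to the thread/initiator
    # member activity: weight ~ 1 + Pareto(activity_pareto_alpha)
    activity_pareto_alpha: float = 1.3
    # text
    mean_tokens_lognorm_mu: float = np.log(40.0)
    mean_tokens_lognorm_sigma: float = 0.8
    mixture_concentration: float = 48.0
    category_means: dict | None = None  # token-class -> mean probability
    deleted_member_fraction: float = 37 / 5050
    vocabulary: dict | None = None  # token-class -> word pool

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.n_threads < 0:
            raise ValueError("n_threads must be >= 0")
        for name in (
            "p_single_participant",
            "reply_to_specific",
            "deleted_member_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_participants < 1:
            raise ValueError("max_participants must be >= 1")
        if self.category_means is not None and any(
            w < 0 for w in self.category_means.values()
        ):
            raise ValueError("category mixture weights must be non-negative")


#: Token-class mixture means of the default member profile. Classes map to
#: pools of dictionary words of the shipped toy lexicon plus an untagged
#: filler pool; the tagged classes sum to ~0.76, giving a corpus tag rate in
#: the mid-70% range typical of LIWC analyses of informal text.
DEFAULT_CATEGORY_MEANS: dict[str, float] = {
    "filler": 0.243,
    "function_other": 0.395,
    "first_person": 0.055,
    "second_person": 0.012,
    "third_person": 0.018,
    "social": 0.025,
    "positive": 0.040,
    "negative": 0.045,
    "cognitive": 0.080,
    "perceptual": 0.015,
    "biological": 0.012,
    "relativity": 0.060,
}


def _default_vocabulary() -> dict[str, list[str]]:
    # Pools come from the shipped toy lexicon so generated text is tagged by
    # the same dictionary the linguistic module ships.
    from .lexicon import builtin_toy_lexicon

    lex = builtin_toy_lexicon()
    pools: dict[str, list[str]] = {k: [] for k in DEFAULT_CATEGORY_MEANS}
    for word, labels in lex.entries.items():
        ancestors = set()
        for lab in labels:
            ancestors.add(lab)
            ancestors.update(lex.ancestors(lab))
        if "first_person" in ancestors:
            pools["first_person"].append(word)
        elif "second_person" in ancestors:
            pools["second_person"].append(word)
        elif "third_person" in ancestors:
            pools["third_person"].append(word)
        elif "positive" in ancestors:
            pools["positive"].append(word)
        elif "negative" in ancestors:
            pools["negative"].append(word)
        elif "function" in ancestors:
            pools["function_other"].append(word)
        elif "social" in ancestors:
            pools["social"].append(word)
        elif "cognitive" in ancestors:
            pools["cognitive"].append(word)
        elif "perceptual" in ancestors:
            pools["perceptual"].append(word)
        elif "biological" in ancestors:
            pools["biological"].append(word)
        elif "relativity" in ancestors:
            pools["relativity"].append(word)
    pools["filler"] = [f"w{i:03d}" for i in range(150)]
    for k, pool in pools.items():
        if not pool:
            raise RuntimeError(f"empty word pool for class {k!r}")
        pool.sort()
    return pools


def _truncated_zipf_cdf(a: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1, dtype=float)
    w = k**-a
    return np.cumsum(w) / w.sum()


def generate_corpus(params: GeneratorParams) -> ForumCorpus:
    """Draw a synthetic forum corpus; deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_mem, n_thr = params.n_members, params.n_threads
    member_ids = np.array([f"m{i:05d}" for i in range(n_mem)])

    # heavy-tailed activity propensities
    activity = 1.0 + rng.pareto(params.activity_pareto_alpha, size=n_mem)
    p_member = activity / activity.sum()

    # deleted accounts: structure kept, text unavailable
    n_deleted = int(round(params.deleted_member_fraction * n_mem))
    deleted = set(rng.choice(n_mem, size=n_deleted, replace=False).tolist())

    # per-member token-class mixtures
    means = dict(params.category_means or DEFAULT_CATEGORY_MEANS)
    classes = list(means)
    base = np.array([means[c] for c in classes], dtype=float)
    base = base / base.sum()
    mixtures = rng.dirichlet(params.mixture_concentration * base, size=n_mem)

    vocab = params.vocabulary or _default_vocabulary()
    pools = [np.array(vocab[c]) for c in classes]
    pool_sizes = np.array([len(p) for p in pools])

    zipf_cdf = _truncated_zipf_cdf(
        params.participant_power, max(1, params.max_participants - 1)
    )

    # skeleton pass: decide authors/replies, then fill tokens member-by-member
    threads: list[Thread] = []
    member_token_needs: dict[int, list[tuple[int, int, int]]] = {}
    skeleton: list[tuple[dict, list[dict]]] = []
    clock = 0
    msg_counter = 0
    for ti in range(n_thr):
        initiator_idx = int(rng.choice(n_mem, p=p_member))
        n_part = 1
        if n_mem > 1 and rng.random() >= params.p_single_participant:
            z = int(np.searchsorted(zipf_cdf, rng.random()) + 1)
            n_part = min(1 + z, n_mem)
        # repliers: distinct members other than the initiator, weighted
        n_repliers = n_part - 1
        repliers: list[int] = []
        if n_repliers > 0:
            w = p_member.copy()
            w[initiator_idx] = 0.0
            w /= w.sum()
            repliers = rng.choice(n_mem, size=n_repliers, replace=False, p=w).tolist()
        events: list[int] = []  # author index per non-opening message
        for ridx in repliers:
            events.extend([ridx] * (1 + int(rng.poisson(params.replier_extra_mean))))
        events.extend([initiator_idx] * int(rng.poisson(params.initiator_followup_mean)))
        rng.shuffle(events)

        thread_id = f"t{ti:05d}"
        clock += 1
        created = clock
        msgs_meta: list[dict] = []
        opening_id = f"p{msg_counter:06d}"
        msg_counter += 1
        msgs_meta.append(
            {
                "message_id": opening_id,
                "author": initiator_idx,
                "timestamp": created,
                "reply_to": None,
            }
        )
        for author_idx in events:
            clock += 1
            mid = f"p{msg_counter:06d}"
            msg_counter += 1
            reply_to = None
            if rng.random() < params.reply_to_specific:
                reply_to = msgs_meta[int(rng.integers(len(msgs_meta)))]["message_id"]
            msgs_meta.append(
                {
                    "message_id": mid,
                    "author": author_idx,
                    "timestamp": clock,
                    "reply_to": reply_to,
                }
            )
        skeleton.append(
            (
                {
                    "thread_id": thread_id,
                    "initiator": str(member_ids[initiator_idx]),
                    "created_time": created,
                    "title": f"thread {ti}",
                },
                msgs_meta,
            )
        )
        for pos, meta in enumerate(msgs_meta):
            a = meta["author"]
            member_token_needs.setdefault(a, []).append((len(skeleton) - 1, pos, 0))

    # token pass: one vectorized draw per member
    tokens_store: dict[tuple[int, int], tuple[str, ...] | None] = {}
    for a, slots in member_token_needs.items():
        lengths = np.maximum(
            1,
            np.round(
                rng.lognormal(
                    params.mean_tokens_lognorm_mu,
                    params.mean_tokens_lognorm_sigma,
                    size=len(slots),
                )
            ).astype(int),
        )
        if a in deleted:
            for (t_i, pos, _), _L in zip(slots, lengths):
                tokens_store[(t_i, pos)] = None
            continue
        total = int(lengths.sum())
        cls = rng.choice(len(classes), size=total, p=mixtures[a])
        widx = rng.integers(0, pool_sizes[cls])
        words = np.empty(total, dtype=object)
        for ci in range(len(classes)):
            sel = cls == ci
            if sel.any():
                words[sel] = pools[ci][widx[sel]]
        off = 0
        for (t_i, pos, _), L in zip(slots, lengths):
            tokens_store[(t_i, pos)] = tuple(words[off : off + L])
            off += L

    for t_i, (tmeta, msgs_meta) in enumerate(skeleton):
        msgs = tuple(
            Message(
                message_id=meta["message_id"],
                thread_id=tmeta["thread_id"],
                author=str(member_ids[meta["author"]]),
                timestamp=meta["timestamp"],
                reply_to=meta["reply_to"],
                tokens=tokens_store[(t_i, pos)],
            )
            for pos, meta in enumerate(msgs_meta)
        )
        threads.append(Thread(messages=msgs, **tmeta))

    corpus = ForumCorpus(threads=threads, members=set(member_ids.tolist()))
    corpus.validate()
    return corpus
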