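import pytest

import forumnet as fn
from forumnet.corpus import ForumCorpus, Message, Thread


def make_thread(thread_id, initiator, entries, t0=0, title=""):
    """Build a thread from (author, reply_to, tokens) tuples; the first
    entry is the opening post."""
    msgs = []
    for i, (author, reply_to, tokens) in enumerate(entries):
        msgs.append(
            Message(
                message_id=f"{thread_id}-m{i}",
                thread_id=thread_id,
                author=author,
                timestamp=t0 + i,
                reply_to=reply_to,
                tokens=tokens,
            )
        )
    return Thread(
        thread_id=thread_id,
        initiator=initiator,
        created_time=t0,
        title=title or thread_id,
        messages=tuple(msgs),
    )


@pytest.fixture
def toy_corpus():
    """Three hand-counted threads over members A, B, C, D.

    t1: A opens, B posts untargeted, C replies to B's message.
    t2: B opens, A replies to the opening post, B posts untargeted
        (initiator self-loop).
    t3: D alone.
    """
    t1 = make_thread(
        "t1",
        "A",
        [
            ("A", None, ("i", "feel", "sad", "today")),
            ("B", None, ("you", "can", "talk", "with", "me")),
            ("C", "t1-m1", ("i", "agree",)),
        ],
        t0=0,
    )
    t2 = make_thread(
        "t2",
        "B",
        [
            ("B", None, ("no", "hope",)),
            ("A", "t2-m0", ("never", "say", "never",)),
            ("B", None, ()),
        ],
        t0=10,
    )
    t3 = make_thread("t3", "D", [("D", None, ("the", "doctor", "helps"))], t0=20)
    corpus = ForumCorpus(threads=[t1, t2, t3], members={"A", "B", "C", "D"})
    corpus.validate()
    return corpus


@pytest.fixture(scope="session")
def toy_lexicon():
    return fn.builtin_toy_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """A mid-size generated corpus shared across tests."""
    return fn.generate_corpus(fn.GeneratorParams(n_members=300, n_threads=220, seed=11))
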