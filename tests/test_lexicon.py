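"""Dictionary loading, category counting and linguistic profiles."""

import numpy as np
import pytest

import forumnet as fn
from forumnet.lexicon import (
    CATEGORY_PARENT,
    MAIN_CATEGORIES,
    Lexicon,
    LexiconError,
    LinguisticProfile,
    load_lexicon,
    tag_tokens,
)


class TestLoader:
    def test_three_word_file(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("alpha\tpositive\nbeta\tsad\ngamma\tarticle\n")
        lex = load_lexicon(p)
        assert len(lex) == 3
        assert lex.entries["beta"] == frozenset({"sad"})

    def test_duplicate_word_merges_labels(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("word\tpositive\nword\tfirst_person\n")
        lex = load_lexicon(p)
        assert lex.entries["word"] == frozenset({"positive", "first_person"})

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("word\tno_such_category\n")
        with pytest.raises(LexiconError):
            load_lexicon(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(LexiconError):
            load_lexicon(p)

    def test_shipped_toy_lexicon_covers_all_main_categories(self, toy_lexicon):
        covered = set()
        for word in toy_lexicon.entries:
            covered.update(toy_lexicon.categories_with_rollup(word))
        assert set(MAIN_CATEGORIES) <= covered
        # pronoun persons and affect polarity present too
        assert {"first_person", "second_person", "third_person",
                "positive", "negative"} <= covered


class TestTagTokens:
    def test_empty_token_list(self, toy_lexicon):
        rec = tag_tokens([], toy_lexicon)
        assert rec == {"word_count": 0, "tagged_count": 0, "counts": {}}

    def test_hand_counted_message(self, toy_lexicon):
        toks = ["i", "feel", "sad", "today", "zzz"]
        rec = tag_tokens(toks, toy_lexicon)
        assert rec["word_count"] == 5
        assert rec["tagged_count"] == 4
        c = rec["counts"]
        assert c["first_person"] == c["pronoun"] == 1
        assert c["function"] == 1
        assert c["sad"] == c["negative"] == c["affective"] == 1
        assert c["feel"] == c["perceptual"] == 1
        assert c["time"] == c["relativity"] == 1

    def test_all_unknown_tokens(self, toy_lexicon):
        rec = tag_tokens(["q%d" % i for i in range(10)], toy_lexicon)
        assert rec["word_count"] == 10 and rec["tagged_count"] == 0

    def test_multicategory_token_tagged_once(self, toy_lexicon):
        # "doctor" is both health (biological) and social
        rec = tag_tokens(["doctor"], toy_lexicon)
        assert rec["tagged_count"] == 1
        assert rec["counts"]["biological"] == 1
        assert rec["counts"]["social"] == 1

    def test_equals_naive_membership_scan(self, toy_lexicon):
        rng = np.random.default_rng(0)
        vocab = list(toy_lexicon.entries) + ["junk1", "junk2", "junk3"]
        for _ in range(20):
            toks = rng.choice(vocab, size=rng.integers(0, 40)).tolist()
            rec = tag_tokens(toks, toy_lexicon)
            # oracle: per-token set membership, counted independently
            naive_tagged = sum(1 for t in toks if t in toy_lexicon.entries)
            naive_counts: dict = {}
            for t in toks:
                for cat in toy_lexicon.categories_with_rollup(t):
                    naive_counts[cat] = naive_counts.get(cat, 0) + 1
            assert rec["tagged_count"] == naive_tagged
            assert rec["counts"] == naive_counts

    def test_rollup_conservation_on_leaf_labeled_lexicon(self, tmp_path):
        p = tmp_path / "leaf.tsv"
        p.write_text("a\tsad\nb\tanxious\nc\tangry\nd\tpositive\ne\tinsight\n")
        lex = load_lexicon(p)
        rec = tag_tokens(["a", "b", "b", "c", "d", "e"], lex)
        c = rec["counts"]
        assert c["negative"] == c["sad"] + c["anxious"] + c["angry"]
        assert c["affective"] == c["negative"] + c["positive"]


class TestProfiles:
    def test_single_message_member_equals_tag_tokens(self, toy_corpus, toy_lexicon):
        prof = fn.profile_unit(toy_corpus, toy_lexicon, "C")
        rec = tag_tokens(["i", "agree"], toy_lexicon)
        assert prof.word_count == rec["word_count"]
        assert prof.counts == rec["counts"]

    def test_rate_arithmetic(self, toy_lexicon):
        prof = LinguisticProfile(unit_id="x", word_count=50, tagged_count=30,
                                 counts={"function": 20})
        assert prof.rate("function") == 40.0
        assert prof.tag_rate == 60.0

    def test_member_rates_hand_counted(self, toy_corpus, toy_lexicon):
        # A pools "i feel sad today" + "never say never": 7 tokens,
        # function hits i + never*2 = 3
        prof = fn.profile_unit(toy_corpus, toy_lexicon, "A")
        assert prof.word_count == 7
        assert prof.rate("function") == pytest.approx(300 / 7)
        assert prof.rate("negative") == pytest.approx(100 / 7)

    def test_thread_profile(self, toy_corpus, toy_lexicon):
        prof = fn.profile_unit(toy_corpus, toy_lexicon, "t3")
        assert prof.word_count == 3 and prof.tagged_count == 2

    def test_unknown_unit_rejected(self, toy_corpus, toy_lexicon):
        with pytest.raises(KeyError):
            fn.profile_unit(toy_corpus, toy_lexicon, "nobody")

    def test_rates_bounded_and_subcategory_leq_ancestor(self, small_corpus, toy_lexicon):
        for prof in fn.member_profiles(small_corpus, toy_lexicon).values():
            rates = prof.rates
            assert all(0.0 <= r <= 100.0 for r in rates.values())
            assert prof.tagged_count <= prof.word_count
            assert rates["positive"] <= rates["affective"]
            assert rates["negative"] <= rates["affective"]
            assert rates["first_person"] <= rates["function"]

    def test_order_invariance_of_pooled_rates(self, toy_corpus, toy_lexicon):
        import forumnet.corpus as fc

        reversed_corpus = fc.ForumCorpus(
            threads=list(reversed(toy_corpus.threads)), members=set(toy_corpus.members)
        )
        a1 = fn.profile_unit(toy_corpus, toy_lexicon, "B").rates
        a2 = fn.profile_unit(reversed_corpus, toy_lexicon, "B").rates
        assert a1 == a2


class TestCorpusLevel:
    def test_toy_corpus_tag_rate_hand_computed(self, toy_corpus, toy_lexicon):
        # 19 tokens total, 15 tagged (can/agree/say/helps unknown)
        assert fn.corpus_tag_rate(toy_corpus, toy_lexicon) == pytest.approx(1500 / 19)

    def test_saturating_lexicon_gives_100(self, toy_corpus):
        words = {t for m in toy_corpus.iter_messages() if m.tokens for t in m.tokens}
        lex = Lexicon(entries={w: frozenset({"function"}) for w in words})
        assert fn.corpus_tag_rate(toy_corpus, lex) == 100.0

    def test_affect_subgroups_toy(self, toy_corpus, toy_lexicon):
        profs = fn.member_profiles(toy_corpus, toy_lexicon).values()
        groups = fn.affect_subgroups(profs)
        assert groups == {"negative_only": 25.0, "positive_only": 25.0,
                          "both": 0.0, "neither": 50.0}

    def test_affect_subgroups_all_neither(self):
        profs = [LinguisticProfile(f"m{i}", 10, 0, {}) for i in range(4)]
        assert fn.affect_subgroups(profs)["neither"] == 100.0

    def test_affect_subgroups_matches_bruteforce(self, small_corpus, toy_lexicon):
        profs = list(fn.member_profiles(small_corpus, toy_lexicon).values())
        got = fn.affect_subgroups(profs)
        brute = {"negative_only": 0, "positive_only": 0, "both": 0, "neither": 0}
        for p in profs:
            pos, neg = p.counts.get("positive", 0) > 0, p.counts.get("negative", 0) > 0
            brute[
                "both" if pos and neg else "positive_only" if pos
                else "negative_only" if neg else "neither"
            ] += 1
        for k in brute:
            assert got[k] == pytest.approx(100 * brute[k] / len(profs))
        assert sum(got.values()) == pytest.approx(100.0)

    def test_empty_profile_set_rejected(self):
        with pytest.raises(ValueError):
            fn.affect_subgroups([])

    def test_word_frequencies(self, toy_corpus):
        freq = fn.word_frequencies(toy_corpus)
        # "i" and "never" both occur twice; ties break lexically
        assert freq.iloc[0]["token"] == "i" and freq.iloc[0]["count"] == 2
        assert freq.iloc[1]["token"] == "never"
        total = sum(len(m.tokens) for m in toy_corpus.iter_messages() if m.tokens)
        assert freq["count"].sum() == total

    def test_word_frequencies_empty_corpus(self):
        from forumnet.corpus import ForumCorpus

        assert fn.word_frequencies(ForumCorpus()).empty
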