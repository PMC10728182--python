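"""Normalization, the fluid switch rule, and cluster segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semforage import coding, fluency_io
from semforage.coding import normalize_item, segment_clusters
from tests.conftest import build_dataset


class TestNormalizeItem:
    @pytest.mark.parametrize(
        "raw,expected",
        [(" Dog ", "dog"), ("polar  bear", "polar bear"), ("", ""),
         ("\tGReat Dane\n", "great dane")],
    )
    def test_examples(self, raw, expected):
        assert normalize_item(raw) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(max_size=30))
    def test_idempotent(self, raw):
        once = normalize_item(raw)
        assert normalize_item(once) == once


class TestCodeList:
    def test_canine_aquatic_switch_pattern(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("fox", 1000), ("wolf", 1100),
                        ("whale", 4000), ("fish", 1200)])],
            small_lexicon,
        )
        flags = [r.is_switch for r in ds.lists[0].responses]
        assert flags == [None, False, False, True, False]

    def test_single_item_list(self, small_lexicon):
        ds = build_dataset([("p1", 1, [("dog", 800)])], small_lexicon)
        (r,) = ds.lists[0].responses
        assert r.is_switch is None and r.is_valid

    def test_shared_category_via_multi_membership_is_not_a_switch(self, small_lexicon):
        # cat (Pets) follows dog (Canine+Pets): intersection nonempty
        ds = build_dataset([("p1", 1, [("dog", 800), ("cat", 900)])], small_lexicon)
        assert ds.lists[0].responses[1].is_switch is False

    def test_intrusions_and_perseverations_skip_the_chain(self, small_lexicon):
        # unicorn is not in the lexicon; dog repeats; fox must be compared to dog
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("unicorn", 500), ("dog", 600), ("fox", 700)])],
            small_lexicon,
        )
        r = ds.lists[0].responses
        assert r[1].is_intrusion and r[1].is_switch is None
        assert r[2].is_perseveration and r[2].is_switch is None
        assert r[3].is_switch is False  # fox vs dog share Canine

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.data())
    def test_random_lists_match_pairwise_intersection_oracle(self, data):
        lex_items = {f"i{k}": frozenset(data.draw(
            st.sets(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=2)))
            for k in range(8)}
        lexicon = fluency_io.Lexicon(dict(lex_items))
        # distinct valid items only, so every response stays in the chain
        seq = data.draw(st.lists(st.sampled_from(sorted(lex_items)), min_size=1,
                                 max_size=8, unique=True))
        ds = build_dataset([("p1", 1, [(i, 1000.0) for i in seq])], lexicon)
        flags = [r.is_switch for r in ds.lists[0].responses]
        oracle = [None] + [
            len(lex_items[a] & lex_items[b]) == 0 for a, b in zip(seq, seq[1:])
        ]
        assert flags == oracle


class TestSegmentClusters:
    def test_hand_computed_offsets_and_switch_time(self, small_lexicon):
        # dog,fox,wolf | whale,fish with rts 800,1000,1500,4000,1200
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("fox", 1000), ("wolf", 1500),
                        ("whale", 4000), ("fish", 1200)])],
            small_lexicon,
        )
        c1, c2 = segment_clusters(ds.lists[0])
        assert c1.item_offsets_ms == [0.0, 1000.0, 2500.0]
        assert c1.leave_time_ms == 2500.0 and c1.switch_time_ms is None
        assert c2.item_offsets_ms == [0.0, 1200.0]
        assert c2.switch_time_ms == 4000.0 and c2.leave_time_ms == 1200.0

    def test_all_switch_list_gives_singleton_clusters(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("whale", 2000), ("giraffe", 2500)])],
            small_lexicon,
        )
        clusters = segment_clusters(ds.lists[0])
        assert [c.n_items for c in clusters] == [1, 1, 1]
        assert all(c.leave_time_ms == 0.0 for c in clusters)
        assert [c.switch_time_ms for c in clusters] == [None, 2000.0, 2500.0]

    def test_cluster_count_is_switches_plus_one(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("fox", 900), ("whale", 2000),
                        ("fish", 1000), ("lion", 2200), ("zebra", 800)])],
            small_lexicon,
        )
        coded = ds.lists[0]
        n_switches = sum(1 for r in coded.responses if r.is_switch)
        assert len(segment_clusters(coded)) == n_switches + 1

    def test_intrusion_rt_folds_into_next_response(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("unicorn", 700), ("fox", 300)])],
            small_lexicon,
        )
        (c,) = segment_clusters(ds.lists[0], timing_policy="fold")
        assert c.item_offsets_ms == [0.0, 1000.0]  # 700 folded into fox's 300
        (c_drop,) = segment_clusters(ds.lists[0], timing_policy="drop")
        assert c_drop.item_offsets_ms == [0.0, 300.0]

    def test_elapsed_time_conservation_on_random_inputs(self, small_lexicon):
        rng = np.random.default_rng(42)
        vocab = list(small_lexicon.entries) + ["unicorn", "dragon"]
        for _ in range(25):
            n = rng.integers(2, 12)
            items = [(vocab[i], float(rng.integers(100, 5000)))
                     for i in rng.integers(0, len(vocab), n)]
            ds = build_dataset([("p1", 1, items)], small_lexicon)
            coded = ds.lists[0]
            clusters = segment_clusters(coded, timing_policy="fold")
            if not clusters:
                continue
            cleaned = coding.cleaned_responses(coded, "fold")
            first_latency = cleaned[0][1]
            total = sum(
                (c.switch_time_ms or 0.0) + c.leave_time_ms for c in clusters
            ) + first_latency
            trailing = 0.0  # rts of invalid responses after the last valid one
            last_valid = max(i for i, r in enumerate(coded.responses) if r.is_valid)
            trailing = sum(r.rt_ms for r in coded.responses[last_valid + 1:])
            assert total == pytest.approx(
                sum(r.rt_ms for r in coded.responses) - trailing
            )

    def test_coding_is_deterministic(self, small_lexicon):
        items = [("dog", 800), ("whale", 2000), ("fish", 900), ("lion", 3000)]
        a = segment_clusters(build_dataset([("p1", 1, items)], small_lexicon).lists[0])
        b = segment_clusters(build_dataset([("p1", 1, items)], small_lexicon).lists[0])
        assert [(c.item_offsets_ms, c.switch_time_ms) for c in a] == [
            (c.item_offsets_ms, c.switch_time_ms) for c in b
        ]


def test_coded_frame_export_carries_flags_and_cluster_ids(small_lexicon):
    ds = build_dataset(
        [("p1", 1, [("dog", 800), ("unicorn", 700), ("whale", 2000)]),
         ("p1", 2, [("cat", 900), ("dog", 1100)])],
        small_lexicon,
    )
    frame = coding.coded_frame(ds)
    assert len(frame) == 5
    assert frame["is_intrusion"].sum() == 1
    # cluster ids are globally unique and None for invalid rows
    valid = frame[frame["cluster_id"].notna()]
    assert valid["cluster_id"].nunique() == 3
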