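"""Window rule, fixation selection, Gaussian rendering, policy sweep."""

import numpy as np
import pytest

from gazemil.gaze_data import Fixation
from gazemil.heatmap_extraction import (
    DEFAULT_POLICY,
    EndRule,
    GazeHeatmap,
    StartRule,
    WindowPolicy,
    binary_iou,
    heatmap_for_label,
    load_heatmap,
    mention_window,
    render_heatmap,
    save_heatmap,
    select_fixations,
    sweep_policies,
)
from gazemil.report_labeler import Mention, find_mentions
from tests.conftest import make_sentence, make_session


def session_with_mention(vocab, prev_start=10.0, mention_start=14.0,
                         recording_start=0.0, fixations=()):
    s0 = make_sentence(0, "the lungs are clear.", prev_start)
    s1 = make_sentence(1, "there is cardiomegaly.", mention_start)
    session = make_session([s0, s1], fixations, recording_start=recording_start)
    (mention,) = [
        m for m in find_mentions(session.sentences, vocab) if m.sentence_index == 1
    ]
    return session, mention


class TestMentionWindow:
    def test_default_rule_delay_caps(self, vocab):
        session, mention = session_with_mention(vocab, 10.0, 14.0)
        t0, t1 = mention_window(session, mention, DEFAULT_POLICY)
        assert t0 == pytest.approx(12.5)  # max(14.0 - 1.5, 10.0)
        assert t1 == pytest.approx(mention.last_mention_end)

    def test_previous_sentence_caps_short_windows(self, vocab):
        s0 = make_sentence(0, "lungs clear.", 13.2, word_duration=0.3)
        s1 = make_sentence(1, "there is cardiomegaly.", 14.0)
        session = make_session([s0, s1])
        (mention,) = [
            m for m in find_mentions(session.sentences, vocab) if m.sentence_index == 1
        ]
        t0, _ = mention_window(session, mention, DEFAULT_POLICY)
        assert t0 == pytest.approx(13.2)  # the shorter of the two windows

    def test_first_sentence_falls_back_to_recording_start(self, vocab):
        s0 = make_sentence(0, "there is cardiomegaly.", 2.0)
        session = make_session([s0], recording_start=0.0)
        (mention,) = find_mentions(session.sentences, vocab)
        t0, _ = mention_window(session, mention, DEFAULT_POLICY)
        assert t0 == pytest.approx(0.5)  # max(2.0 - 1.5, recording_start)

    def test_all_start_and_end_rules_produce_windows(self, vocab):
        session, mention = session_with_mention(vocab)
        for sr in StartRule:
            for er in EndRule:
                t0, t1 = mention_window(
                    session, mention, WindowPolicy(sr, er, delay=1.0)
                )
                assert np.isfinite(t0) and np.isfinite(t1)

    def test_missing_sentence_is_integrity_error(self, vocab):
        session, mention = session_with_mention(vocab)
        bad = Mention(
            label=mention.label, sentence_index=7, span=mention.span,
            first_mention_end=mention.first_mention_end,
            last_mention_end=mention.last_mention_end, negated=False,
        )
        with pytest.raises(KeyError):
            mention_window(session, bad, DEFAULT_POLICY)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            WindowPolicy(delay=-0.1)


class TestSelectFixations:
    def test_partial_overlap_clips_duration(self):
        session = make_session([], [Fixation(5, 5, 12.0, 13.0)])
        (fx,) = select_fixations(session, 12.5, 16.0)
        assert fx.duration == pytest.approx(0.5)
        assert fx.start == pytest.approx(12.5)

    def test_outside_window_excluded(self):
        session = make_session([], [Fixation(5, 5, 16.5, 17.0)])
        assert select_fixations(session, 12.5, 16.0) == []

    def test_zero_overlap_at_boundary_excluded(self):
        session = make_session([], [Fixation(5, 5, 16.0, 17.0)])
        assert select_fixations(session, 12.5, 16.0) == []

    def test_empty_window_returns_empty(self):
        session = make_session([], [Fixation(5, 5, 0.0, 10.0)])
        assert select_fixations(session, 5.0, 4.0) == []


class TestRenderHeatmap:
    def test_single_fixation_peak_normalized(self):
        m = render_heatmap([Fixation(64, 64, 0, 0.7, pixels_per_degree=8.0)], (128, 128))
        assert m[64, 64] == pytest.approx(1.0)
        assert np.unravel_index(m.argmax(), m.shape) == (64, 64)

    def test_duration_weighting_before_normalization(self):
        # two far-apart fixations; cross-talk negligible at sigma 5
        fixes = [
            Fixation(30, 30, 0, 2.0, pixels_per_degree=5.0),
            Fixation(100, 100, 2, 3.0, pixels_per_degree=5.0),
        ]
        m = render_heatmap(fixes, (128, 128))
        # oracle: explicit Gaussian sum at both centers
        assert m[30, 30] == pytest.approx(1.0, abs=1e-6)
        assert m[100, 100] == pytest.approx(0.5, abs=1e-3)

    def test_zero_fixations_all_zero(self):
        m = render_heatmap([], (32, 32))
        assert not m.any()

    def test_scale_invariance_of_normalization(self, rng):
        fixes = [
            Fixation(
                float(rng.uniform(0, 64)), float(rng.uniform(0, 64)),
                i * 1.0, i * 1.0 + float(rng.uniform(0.1, 0.6)),
                pixels_per_degree=6.0,
            )
            for i in range(8)
        ]
        doubled = [
            Fixation(f.x, f.y, 2 * f.start, 2 * f.start + 2 * f.duration, f.pixels_per_degree)
            for f in fixes
        ]
        np.testing.assert_allclose(
            render_heatmap(fixes, (64, 64)), render_heatmap(doubled, (64, 64)),
            atol=1e-12,
        )

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            render_heatmap([], (0, 10))


class TestHeatmapForLabel:
    def _session(self, vocab):
        s0 = make_sentence(0, "there is cardiomegaly.", 5.0)
        s1 = make_sentence(1, "again cardiomegaly noted.", 12.0)
        fixations = [
            Fixation(20, 20, 4.2, 5.0, pixels_per_degree=5.0),
            Fixation(100, 100, 11.0, 12.2, pixels_per_degree=5.0),
        ]
        session = make_session([s0, s1], fixations)
        mentions = [
            m for m in find_mentions(session.sentences, vocab) if not m.negated
        ]
        return session, mentions

    def test_two_mentions_both_peaks_at_one(self, vocab):
        session, mentions = self._session(vocab)
        hm = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions)
        assert hm.map[20, 20] == pytest.approx(1.0, abs=1e-6)
        assert hm.map[100, 100] == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self, vocab):
        session, mentions = self._session(vocab)
        a = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions)
        b = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions[::-1])
        np.testing.assert_array_equal(a.map, b.map)

    def test_single_mention_equals_render(self, vocab):
        session, mentions = self._session(vocab)
        hm = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions[:1])
        assert hm.map.max() == pytest.approx(1.0)
        assert hm.n_fixations == 1

    def test_max_aggregation_idempotent(self, vocab):
        session, mentions = self._session(vocab)
        once = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions)
        twice = heatmap_for_label(
            session, "Enlarged Cardiac Silhouette", mentions + mentions
        )
        np.testing.assert_allclose(once.map, twice.map, atol=1e-12)

    def test_wrong_label_rejected(self, vocab):
        session, mentions = self._session(vocab)
        with pytest.raises(ValueError):
            heatmap_for_label(session, "Pneumothorax", mentions)

    def test_values_in_unit_interval(self, vocab):
        session, mentions = self._session(vocab)
        hm = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions)
        assert hm.map.min() >= 0.0 and hm.map.max() <= 1.0


class TestSweepPolicies:
    def test_toy_iou_matches_hand_count(self, vocab):
        # one 8x8 case: window captures one fixation; manual pixel count
        s0 = make_sentence(0, "there is cardiomegaly.", 2.0)
        fix = Fixation(2, 2, 1.8, 2.4, pixels_per_degree=0.8)
        session = make_session([s0], [fix], size=8)
        mentions = find_mentions(session.sentences, vocab)
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:4, 1:4] = True
        table = sweep_policies(
            [(session, mentions, {"Enlarged Cardiac Silhouette": mask})],
            start_rules=(StartRule.MENTION_SENTENCE_START_MINUS_DELAY_CAPPED_PREV,),
            end_rules=(EndRule.LAST_MENTION_END,),
            delays=(1.5,),
            threshold_grid=(0.5,),
        )
        hm = heatmap_for_label(session, "Enlarged Cardiac Silhouette", mentions)
        expected = binary_iou(hm.map > 0.5, mask)
        assert table.iloc[0]["mean_iou"] == pytest.approx(expected)
        inter = np.logical_and(hm.map > 0.5, mask).sum()
        union = np.logical_or(hm.map > 0.5, mask).sum()
        assert expected == pytest.approx(inter / union)

    def test_impossible_policies_excluded(self, vocab):
        # end before start for every mention: start at sentence start,
        # end at sentence start minus nothing -> use end=MENTION_SENTENCE_START
        # with start=SENTENCE_END_MINUS_DELAY_CAPPED_PREV and delay 0
        s0 = make_sentence(0, "there is cardiomegaly.", 2.0)
        session = make_session([s0], [Fixation(2, 2, 1.0, 2.0)], size=8)
        mentions = find_mentions(session.sentences, vocab)
        mask = np.ones((8, 8), dtype=bool)
        table = sweep_policies(
            [(session, mentions, {"Enlarged Cardiac Silhouette": mask})],
            start_rules=(StartRule.SENTENCE_END_MINUS_DELAY_CAPPED_PREV,),
            end_rules=(EndRule.MENTION_SENTENCE_START,),
            delays=(0.0,),
            threshold_grid=(0.5,),
        )
        assert len(table) == 0

    def test_requires_gold_masks(self, vocab):
        s0 = make_sentence(0, "there is cardiomegaly.", 2.0)
        session = make_session([s0], [], size=8)
        with pytest.raises(ValueError):
            sweep_policies([(session, [], {})])


class TestHeatmapIO:
    def test_png_sidecar_roundtrip(self, tmp_path, rng):
        m = rng.random((16, 16))
        m /= m.max()
        hm = GazeHeatmap(label="Edema", map=m, n_fixations=3)
        save_heatmap(hm, tmp_path / "h.png", meta={"case_id": "c1"})
        back = load_heatmap(tmp_path / "h.png")
        assert back.label == "Edema"
        assert back.n_fixations == 3
        np.testing.assert_allclose(back.map, m, atol=1.0 / 65535)


def test_binary_iou_edge_cases():
    a = np.zeros((4, 4), dtype=bool)
    assert binary_iou(a, a) == 0.0
    a[0, 0] = True
    assert binary_iou(a, a) == 1.0
    b = np.zeros((4, 4), dtype=bool)
    b[1, 1] = True
    assert binary_iou(a, b) == 0.0
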