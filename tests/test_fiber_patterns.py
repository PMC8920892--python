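"""Profile sampling, CART branch segmentation and the pattern grammar."""

import itertools

import numpy as np
import pytest

from replidyn.fiber_patterns import (
    FIRST,
    SECOND,
    UNLABELED,
    BranchSegmentation,
    FiberPattern,
    LabelProfile,
    Segment,
    cart_segment,
    classify_pattern,
    review_queue,
    sample_profiles,
)
from replidyn.fiber_imaging import compute_ridge_map, extract_traces
from replidyn.protocol import PulseProtocol
from replidyn.simulate import FiberSpec, ForkEvent, render_fiber_image
from replidyn.simulate.populations import ongoing_fork_spec


def make_profile(values, labeled=None, step=0.2):
    values = np.asarray(values, dtype=float)
    labeled = (
        np.ones(len(values), bool) if labeled is None else np.asarray(labeled, bool)
    )
    lr = np.where(labeled, values, np.nan)
    return LabelProfile(
        arclength_um=np.arange(len(values)) * step,
        first=values * 0,
        second=values * 0,
        log_ratio=lr,
        labeled_mask=labeled,
    )


def segmentation(labels_and_spans):
    segs = []
    pos = 0.0
    for label, span in labels_and_spans:
        segs.append(Segment(pos, pos + span, label, 1.0 if label == FIRST else -1.0))
        pos += span
    return BranchSegmentation(segs)


class TestSampleProfiles:
    def _rendered(self, seed=0):
        rng = np.random.default_rng(seed)
        spec = ongoing_fork_spec(1.0, PulseProtocol(), rng)
        image, gt = render_fiber_image([spec], seed=seed)
        trace = extract_traces(compute_ridge_map(image), min_length_um=3.0)[0]
        return image, trace, gt

    def test_log_ratio_signs_follow_labels(self):
        """First label on the first half of an ongoing fork, second on the
        rest: the log ratio changes sign accordingly."""
        image, trace, gt = self._rendered()
        prof = sample_profiles(image, trace)
        segs = gt.segments_um[0]
        first_seg = next(s for s in segs if s.label == FIRST)
        second_seg = next(s for s in segs if s.label == SECOND)
        # interior of each true segment, away from the boundary
        for seg, sign in ((first_seg, 1), (second_seg, -1)):
            sel = (
                (prof.arclength_um > seg.start_um + 2)
                & (prof.arclength_um < seg.end_um - 2)
                & prof.labeled_mask
            )
            assert np.nanmedian(prof.log_ratio[sel]) * sign > 0

    def test_equal_channels_give_zero_log_ratio(self):
        image, trace, _ = self._rendered(seed=1)
        image.channels[SECOND] = image.channels[FIRST].copy()
        prof = sample_profiles(image, trace)
        assert np.nanmax(np.abs(prof.log_ratio)) < 0.05

    def test_unlabeled_gap_detected(self):
        """A planted 3-um label gap inside the track is unlabeled."""
        protocol = PulseProtocol()
        rng = np.random.default_rng(5)
        spec = ongoing_fork_spec(1.2, protocol, rng)
        gap = (10.0, 13.0)
        spec.label_gaps_um = [gap]
        image, gt = render_fiber_image([spec], seed=5)
        trace = extract_traces(compute_ridge_map(image), min_length_um=3.0)[0]
        prof = sample_profiles(image, trace)
        # trace arclength may run in either direction; check against both
        sel_fwd = (prof.arclength_um > gap[0] + 1) & (prof.arclength_um < gap[1] - 1)
        rev = prof.arclength_um[-1] - prof.arclength_um
        sel_rev = (rev > gap[0] + 1) & (rev < gap[1] - 1)
        assert (~prof.labeled_mask[sel_fwd]).all() or (~prof.labeled_mask[sel_rev]).all()

    def test_even_width_rejected(self):
        image, trace, _ = self._rendered(seed=2)
        with pytest.raises(ValueError):
            sample_profiles(image, trace, width_px=4)


class TestCartSegment:
    def test_single_step(self):
        vals = np.concatenate([np.full(50, 1.0), np.full(50, -1.0)])
        seg = cart_segment(make_profile(vals), min_segment_um=1.0)
        assert seg.labels() == (FIRST, SECOND)
        assert seg.segments[0].end_um == pytest.approx(50 * 0.2 - 0.1, abs=0.2)

    def test_constant_signal_one_segment(self):
        seg = cart_segment(make_profile(np.full(80, 0.8)))
        assert seg.labels() == (FIRST,)

    def test_three_step_matches_exhaustive_oracle(self):
        """Boundaries of a (-1, +1, -1) profile equal the exhaustive
        two-changepoint SSE minimizer within half a micrometer."""
        rng = np.random.default_rng(7)
        step = 0.2
        b1, b2 = 60, 90  # 12 um and 18 um
        vals = np.concatenate([np.full(b1, -1.0), np.full(b2 - b1, 1.0), np.full(40, -1.0)])
        vals += rng.normal(0, 0.25, len(vals))
        seg = cart_segment(make_profile(vals, step=step), min_segment_um=1.0)
        assert seg.labels() == (SECOND, FIRST, SECOND)
        found = [s.end_um for s in seg.segments[:-1]]
        # exhaustive search over all changepoint pairs
        best, best_cuts = np.inf, None
        pre = np.concatenate([[0], np.cumsum(vals)])
        pre2 = np.concatenate([[0], np.cumsum(vals**2)])

        def sse(i, j):
            s = pre[j] - pre[i]
            return pre2[j] - pre2[i] - s * s / (j - i)

        n = len(vals)
        for i, j in itertools.combinations(range(5, n - 4), 2):
            if j - i < 5:
                continue
            tot = sse(0, i) + sse(i, j) + sse(j, n)
            if tot < best:
                best, best_cuts = tot, (i, j)
        expected = [(c - 0.5) * step for c in best_cuts]
        assert found == pytest.approx(expected, abs=0.5)
        assert np.abs(np.array(found) - [12.0, 18.0]).max() < 0.5

    def test_all_unlabeled_single_segment(self):
        prof = make_profile(np.zeros(40), labeled=np.zeros(40, bool))
        seg = cart_segment(prof)
        assert seg.labels() == (UNLABELED,)
        assert classify_pattern(seg).pattern == "ambiguous"

    def test_scale_invariance(self):
        """Multiplying both channels by a common constant leaves the
        segmentation unchanged (log-ratio invariance)."""
        rng = np.random.default_rng(1)
        spec = ongoing_fork_spec(1.0, PulseProtocol(), rng)
        image, _ = render_fiber_image([spec], seed=11)
        trace = extract_traces(compute_ridge_map(image), min_length_um=3.0)[0]
        seg1 = cart_segment(sample_profiles(image, trace))
        for role in (FIRST, SECOND):
            image.channels[role] = image.channels[role] * 3.7
        seg2 = cart_segment(sample_profiles(image, trace))
        assert seg1.labels() == seg2.labels()
        for a, b in zip(seg1.segments, seg2.segments):
            assert a.start_um == pytest.approx(b.start_um, abs=0.3)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ((FIRST, SECOND), "ongoing_fork"),
            ((SECOND, FIRST), "ongoing_fork"),
            ((FIRST,), "stalled_after_first_label"),
            ((SECOND,), "second_pulse_origin"),
            ((SECOND, FIRST, SECOND), "first_pulse_origin"),
            ((FIRST, SECOND, FIRST), "termination"),
            ((SECOND, FIRST, SECOND, FIRST, SECOND), "multi_origin"),
        ],
    )
    def test_grammar(self, labels, expected):
        seg = segmentation([(lab, 5.0) for lab in labels])
        assert classify_pattern(seg).pattern == expected

    def test_multi_origin_event_count(self):
        seg = segmentation([(lab, 5.0) for lab in
                            (SECOND, FIRST, SECOND, FIRST, SECOND)])
        assert classify_pattern(seg).n_origins == 2

    def test_short_gap_elided(self):
        seg = segmentation(
            [(FIRST, 8.0), (UNLABELED, 1.0), (SECOND, 8.0)]
        )
        assert classify_pattern(seg, gap_tolerance_um=2.0).pattern == "ongoing_fork"

    def test_large_gap_splits_events(self):
        seg = segmentation(
            [(FIRST, 8.0), (UNLABELED, 5.0), (SECOND, 8.0)]
        )
        pat = classify_pattern(seg, gap_tolerance_um=2.0)
        assert pat.pattern == "ambiguous"  # two independent events

    def test_origin_boundaries_recorded(self):
        seg = segmentation([(SECOND, 10.0), (FIRST, 4.0), (SECOND, 10.0)])
        pat = classify_pattern(seg)
        assert pat.origin_boundaries_um == [(10.0, 14.0)]


class TestReviewQueue:
    def _patterns(self):
        pats = [FiberPattern("ongoing_fork", fiber_id=i, trace_length_um=20.0)
                for i in range(9)]
        pats.append(FiberPattern("ambiguous", fiber_id=9, trace_length_um=20.0))
        return pats

    def test_empty_reject_list_is_identity(self):
        pats = self._patterns()
        queue, curated = review_queue(pats)
        assert curated == pats
        assert set(queue["fiber_id"]) == {9}

    def test_reject_all_ambiguous(self):
        pats = self._patterns()
        queue, curated = review_queue(pats, reject_ids=list(queue_ids(pats)))
        assert all(p.pattern != "ambiguous" for p in curated)

    def test_planted_ambiguous_fraction_queued(self):
        rng = np.random.default_rng(0)
        pats = [
            FiberPattern(
                "ambiguous" if rng.random() < 0.1 else "ongoing_fork",
                fiber_id=i,
                trace_length_um=20.0,
            )
            for i in range(200)
        ]
        planted = sum(p.pattern == "ambiguous" for p in pats)
        queue, _ = review_queue(pats)
        assert len(queue) == planted

    def test_unknown_reject_id_rejected(self):
        with pytest.raises(ValueError, match="unknown fiber ids"):
            review_queue(self._patterns(), reject_ids=[999])


def queue_ids(pats):
    queue, _ = review_queue(pats)
    return queue["fiber_id"].tolist()
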