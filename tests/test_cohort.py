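"""Label correction, scan linking, balancing and leakage-free splitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse.cohort import (
    assign_labels,
    assign_scan_label,
    augment_positives,
    correct_labels,
    drop_repeat_positives,
    patient_wise_split,
    stratified_folds,
    undersample_negatives,
)
from neurofuse.synth import DiagnosisEvent, ScanRecord


def events_from(labels, subject="S1", start_day=0, gap=100):
    return [DiagnosisEvent(subject, start_day + i * gap, int(l))
            for i, l in enumerate(labels)]


def brute_force_correction(labels):
    """Independent re-statement of the two-neighbours-each-side rule,
    written as literal condition checks."""
    labels = list(labels)
    out = []
    for i, lab in enumerate(labels):
        before = [labels[j] for j in (i - 2, i - 1) if 0 <= j < len(labels)]
        after = [labels[j] for j in (i + 1, i + 2) if 0 <= j < len(labels)]
        if lab == 0:
            if any(b == 1 for b in before) and any(a == 1 for a in after):
                out.append(1)
                continue
        if lab == 1:
            if any(b == 0 for b in before) and any(a == 0 for a in after):
                out.append(0)
                continue
        out.append(lab)
    return out


class TestCorrectLabels:
    @pytest.mark.parametrize("labels,expected", [
        # position 1 (an isolated positive: 0 before, 0 after) flips down
        # while position 2 (0 with a positive on each side) flips up — both
        # in the same simultaneous pass over the original labels
        ([0, 1, 0, 1, 1], [0, 0, 1, 1, 1]),
        ([0, 0, 0, 0], [0, 0, 0, 0]),
        ([1, 0, 1], [1, 1, 1]),
        ([0, 1, 0], [0, 0, 0]),
        ([], []),
        ([1], [1]),
        ([0, 1], [0, 1]),  # boundary positions have one-sided neighbours only
    ])
    def test_hand_traced_sequences(self, labels, expected):
        got = [e.label for e in correct_labels(events_from(labels))]
        assert got == expected

    def test_matches_brute_force_on_all_short_sequences(self):
        """Exhaustive equivalence over every label sequence of length <= 6."""
        for n in range(7):
            for labels in itertools.product((0, 1), repeat=n):
                got = [e.label for e in correct_labels(events_from(labels))]
                assert got == brute_force_correction(labels), labels

    def test_single_simultaneous_pass_does_not_cascade(self):
        # on the ORIGINAL labels of [1,0,0,0,1], only position 2 qualifies
        # (positions 1 and 3 lack a positive within two on one side); a
        # cascading left-to-right pass would let the new 1 at position 2
        # flip position 3 as well
        got = [e.label for e in correct_labels(events_from([1, 0, 0, 0, 1]))]
        assert got == [1, 0, 1, 0, 1]

    def test_input_not_mutated_and_sorted_required(self):
        evs = events_from([0, 1, 0, 1, 1])
        correct_labels(evs)
        assert [e.label for e in evs] == [0, 1, 0, 1, 1]
        with pytest.raises(ValueError, match="sorted"):
            correct_labels(list(reversed(evs)))


class TestAssignScanLabel:
    def scan(self, day):
        return ScanRecord("S1", "MRI", day)

    def test_closest_event_wins(self):
        evs = [DiagnosisEvent("S1", 90, 0), DiagnosisEvent("S1", 130, 1)]
        assert assign_scan_label(self.scan(100), evs) == 0

    def test_exact_day_match(self):
        evs = [DiagnosisEvent("S1", 90, 0), DiagnosisEvent("S1", 100, 1)]
        assert assign_scan_label(self.scan(100), evs) == 1

    def test_tie_goes_to_earlier_event(self):
        evs = [DiagnosisEvent("S1", 90, 0), DiagnosisEvent("S1", 110, 1)]
        assert assign_scan_label(self.scan(100), evs) == 0

    def test_empty_events_error(self):
        with pytest.raises(ValueError):
            assign_scan_label(self.scan(0), [])


class TestDropRepeatPositives:
    def recs(self, day_labels, subject="S1", modality="MRI"):
        return [ScanRecord(subject, modality, d, label=l) for d, l in day_labels]

    def test_consecutive_positive_run_keeps_earliest(self):
        out = drop_repeat_positives(self.recs([(0, 1), (100, 1), (200, 1)]))
        assert [(r.day, r.label) for r in out] == [(0, 1)]

    def test_single_positive_unchanged(self):
        recs = self.recs([(0, 1)])
        assert drop_repeat_positives(recs) == recs

    def test_interrupted_positives_both_kept(self):
        out = drop_repeat_positives(
            self.recs([(0, 1), (100, 0), (200, 1)]))
        assert [(r.day, r.label) for r in out] == [(0, 1), (100, 0), (200, 1)]

    def test_modalities_are_independent_streams(self):
        recs = (self.recs([(0, 1), (100, 1)], modality="MRI")
                + self.recs([(0, 1), (100, 1)], modality="PET"))
        out = drop_repeat_positives(recs)
        assert len(out) == 2
        assert {r.modality for r in out} == {"MRI", "PET"}


class TestBalancing:
    def make_records(self, n_neg, n_pos, rng):
        recs = []
        for i in range(n_neg):
            recs.append(ScanRecord(f"S{i:04d}", "MRI", 0, label=0))
        for i in range(n_pos):
            vol = rng.standard_normal((8, 8, 4)).astype(np.float32)
            recs.append(ScanRecord(f"P{i:04d}", "MRI", 0, volume_ref=vol,
                                   label=1))
        return recs

    def test_undersample_hits_target_exactly(self, rng):
        # scenario shaped after a 1217-negative / 148-target curation
        recs = self.make_records(1217, 115, rng)
        out = undersample_negatives(recs, 148, seed=3)
        assert sum(r.label == 0 for r in out) == 148
        assert sum(r.label == 1 for r in out) == 115

    def test_undersample_identity_and_determinism(self, rng):
        recs = self.make_records(10, 2, rng)
        assert undersample_negatives(recs, 10, seed=0) == recs
        a = undersample_negatives(recs, 4, seed=5)
        b = undersample_negatives(recs, 4, seed=5)
        assert a == b
        with pytest.raises(ValueError):
            undersample_negatives(recs, 11, seed=0)

    def test_augmentation_is_lossless_and_tagged(self, rng):
        recs = self.make_records(0, 1, rng)
        out = augment_positives(recs, 4, seed=9)
        assert len(out) == 4
        src = np.sort(np.asarray(recs[0].volume_ref), axis=None)
        for new in out[1:]:
            assert new.meta["augmented_from"] == ("P0000", "MRI", 0)
            assert np.array_equal(np.sort(np.asarray(new.volume_ref),
                                          axis=None), src)
            t = new.meta["transform"]
            assert (t["rot90"], t["mirror"]) != (0, False)

    def test_augmentation_never_touches_sources_or_negatives(self, rng):
        recs = self.make_records(3, 2, rng)
        before = [np.asarray(r.volume_ref).copy() for r in recs
                  if r.label == 1]
        out = augment_positives(recs, 6, seed=1)
        after = [np.asarray(r.volume_ref) for r in out[:5] if r.label == 1]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)
        assert sum(r.label == 0 for r in out) == 3

    def test_augmentation_determinism_and_errors(self, rng):
        recs = self.make_records(0, 2, rng)
        a = augment_positives(recs, 5, seed=2)
        b = augment_positives(recs, 5, seed=2)
        for ra, rb in zip(a, b):
            assert np.array_equal(np.asarray(ra.volume_ref),
                                  np.asarray(rb.volume_ref))
        with pytest.raises(ValueError):
            augment_positives(recs, 1, seed=0)
        with pytest.raises(ValueError):
            augment_positives([r for r in recs if r.label == 0], 3, seed=0)


class TestSplits:
    def subjects_records(self, n, scans_per_subject=2, balanced=True):
        recs = []
        for i in range(n):
            label = i % 2 if balanced else 0
            for v in range(scans_per_subject):
                recs.append(ScanRecord(f"S{i:03d}", "MRI", 100 * v,
                                       label=label))
        return recs

    def test_split_counts_and_disjointness(self):
        recs = self.subjects_records(10)
        train, test = patient_wise_split(recs, 0.2, seed=0)
        train_subj = {r.subject_id for r in train}
        test_subj = {r.subject_id for r in test}
        assert len(test_subj) == 2
        assert not (train_subj & test_subj)
        assert len(train) + len(test) == len(recs)

    def test_split_determinism_and_errors(self):
        recs = self.subjects_records(10)
        a = patient_wise_split(recs, 0.3, seed=4)
        b = patient_wise_split(recs, 0.3, seed=4)
        assert a == b
        with pytest.raises(ValueError):
            patient_wise_split(self.subjects_records(1), 0.2, seed=0)

    @given(n=st.integers(4, 40), frac=st.floats(0.05, 0.9),
           seed=st.integers(0, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_no_subject_leakage_property(self, n, frac, seed):
        recs = self.subjects_records(n, scans_per_subject=3)
        train, test = patient_wise_split(recs, frac, seed=seed)
        assert not ({r.subject_id for r in train}
                    & {r.subject_id for r in test})
        assert train and test

    def test_stratified_folds_balanced(self):
        recs = self.subjects_records(20)
        folds = stratified_folds(recs, 10, seed=0)
        subj_class = {r.subject_id: r.label for r in recs}
        assert set(folds.values()) == set(range(10))
        for f in range(10):
            members = [s for s, ff in folds.items() if ff == f]
            assert len(members) == 2
            assert sorted(subj_class[s] for s in members) == [0, 1]

    def test_stratified_folds_partition_and_errors(self):
        recs = self.subjects_records(13)
        folds = stratified_folds(recs, 3, seed=1)
        assert set(folds) == {r.subject_id for r in recs}
        with pytest.raises(ValueError):
            stratified_folds(recs, 7, seed=0)  # smaller class has 6 subjects


class TestAssignLabels:
    def test_pipeline_assigns_every_scan(self, small_cohort):
        records, events = small_cohort
        out = assign_labels(records, events)
        assert all(r.label in (0, 1) for r in out)
        assert len(out) == len(records)
        # original records untouched
        assert all(r.label is None for r in records)
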