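"""Scan-label curation and leakage-free dataset assembly.

Longitudinal binary diagnoses are noisy: a subject on a monotone disease
trajectory occasionally receives an isolated discordant diagnosis. The
correction rule used here flips such outliers by looking at up to two
neighbours on each side:

* a negative label becomes positive iff at least one of the up-to-two
  preceding labels is positive AND at least one of the up-to-two following
  labels is positive;
* symmetrically, a positive label becomes negative iff at least one label on
  each side (within two) is negative.

The pass is *simultaneous* over the original labels (corrections do not
cascade), which makes it order-independent and reproducible. A position with
no neighbour on one side never changes.

Scans are then labelled by the temporally closest corrected diagnosis (ties
go to the earlier event), repeat positives from consecutive positive visits
are dropped, classes are balanced by under-sampling negatives and by
rotation/mirror augmentation of positives, and train/test and CV folds are
formed patient-wise so no subject leaks across sets.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .synth import DiagnosisEvent, ScanRecord

__all__ = [
    "correct_labels",
    "assign_scan_label",
    "assign_labels",
    "drop_repeat_positives",
    "undersample_negatives",
    "augment_positives",
    "patient_wise_split",
    "stratified_folds",
    "AUGMENT_TRANSFORMS",
]


def correct_labels(events: list[DiagnosisEvent]) -> list[DiagnosisEvent]:
    """Single simultaneous correction pass over one subject's timeline."""
    if not events:
        return []
    subjects = {e.subject_id for e in events}
    if len(subjects) != 1:
        raise ValueError(f"events must belong to one subject, got {sorted(subjects)}")
    days = [e.day for e in events]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("events must be sorted by strictly increasing day")
    orig = [e.label for e in events]
    out = []
    for i, e in enumerate(events):
        prev = orig[max(0, i - 2):i]
        nxt = orig[i + 1:i + 3]
        lab = orig[i]
        if lab == 0 and (1 in prev) and (1 in nxt):
            lab = 1
        elif lab == 1 and (0 in prev) and (0 in nxt):
            lab = 0
        out.append(DiagnosisEvent(e.subject_id, e.day, lab))
    return out


def assign_scan_label(scan: ScanRecord, events: list[DiagnosisEvent]) -> int:
    """Label of the temporally closest diagnosis; exact ties go to the
    earlier event."""
    if not events:
        raise ValueError("cannot label a scan with no diagnosis events")
    best = min(events, key=lambda e: (abs(e.day - scan.day), e.day))
    return best.label


def assign_labels(records: list[ScanRecord], events: list[DiagnosisEvent],
                  correct: bool = True) -> list[ScanRecord]:
    """Correct each subject's timeline and label every scan from it.

    Returns new records; inputs are not mutated.
    """
    by_subject: dict[str, list[DiagnosisEvent]] = {}
    for e in events:
        by_subject.setdefault(e.subject_id, []).append(e)
    for sid in by_subject:
        by_subject[sid].sort(key=lambda e: e.day)
        if correct:
            by_subject[sid] = correct_labels(by_subject[sid])
    out = []
    for rec in records:
        evs = by_subject.get(rec.subject_id)
        if not evs:
            raise ValueError(f"no diagnosis events for subject {rec.subject_id}")
        out.append(ScanRecord(rec.subject_id, rec.modality, rec.day,
                              rec.volume_ref, assign_scan_label(rec, evs),
                              dict(rec.meta)))
    return out


def drop_repeat_positives(records: list[ScanRecord]) -> list[ScanRecord]:
    """Keep, per subject and modality, only the earliest positive scan of
    each consecutive run of positive visits; negatives all stay."""
    if any(r.label is None for r in records):
        raise ValueError("all records must have assigned labels")
    order = {id(r): i for i, r in enumerate(records)}
    keys = sorted({(r.subject_id, r.modality) for r in records})
    kept: list[ScanRecord] = []
    for sid, mod in keys:
        stream = sorted((r for r in records
                         if r.subject_id == sid and r.modality == mod),
                        key=lambda r: r.day)
        prev_label = 0
        for r in stream:
            if r.label == 0 or prev_label == 0:
                kept.append(r)
            prev_label = r.label
    kept.sort(key=lambda r: order[id(r)])
    return kept


def undersample_negatives(records: list[ScanRecord], target_count: int,
                          seed: int) -> list[ScanRecord]:
    """Uniform random sample of the negative scans down to ``target_count``;
    positives untouched; original record order preserved."""
    negatives = [i for i, r in enumerate(records) if r.label == 0]
    if target_count > len(negatives):
        raise ValueError(
            f"target_count {target_count} exceeds negative count {len(negatives)}")
    rng = np.random.default_rng(seed)
    keep_neg = set(rng.choice(negatives, size=target_count, replace=False).tolist())
    return [r for i, r in enumerate(records)
            if r.label == 1 or i in keep_neg]


# the seven non-identity rigid in-plane transforms: (quarter-turns, mirror)
AUGMENT_TRANSFORMS: list[tuple[int, bool]] = [
    (k, m) for k in range(4) for m in (False, True)][1:]


def apply_transform(vol: np.ndarray, k_rot: int, mirror: bool) -> np.ndarray:
    """Axis-aligned 90-degree in-plane rotation(s) then optional left-right
    mirror; lossless (a pure voxel permutation)."""
    out = np.rot90(vol, k=k_rot, axes=(0, 1))
    if mirror:
        out = np.flip(out, axis=1)
    return np.ascontiguousarray(out)


def augment_positives(records: list[ScanRecord], target_count: int,
                      seed: int) -> list[ScanRecord]:
    """Grow the positive class to ``target_count`` by rotating/mirroring
    randomly selected positive volumes. New records keep the source subject
    (so they follow it through any split) and are tagged with their source
    and transform."""
    positives = [r for r in records if r.label == 1]
    if not positives:
        raise ValueError("need at least one positive record to augment")
    if target_count < len(positives):
        raise ValueError(
            f"target_count {target_count} below current positive count "
            f"{len(positives)}")
    rng = np.random.default_rng(seed)
    out = list(records)
    for _ in range(target_count - len(positives)):
        src = positives[int(rng.integers(len(positives)))]
        k_rot, mirror = AUGMENT_TRANSFORMS[int(rng.integers(len(AUGMENT_TRANSFORMS)))]
        vol = apply_transform(np.asarray(src.volume_ref), k_rot, mirror)
        meta = dict(src.meta)
        meta.update({"augmented_from": (src.subject_id, src.modality, src.day),
                     "transform": {"rot90": k_rot, "mirror": mirror}})
        out.append(ScanRecord(src.subject_id, src.modality, src.day,
                              vol, 1, meta))
    return out


def patient_wise_split(records: list[ScanRecord], test_fraction: float,
                       seed: int) -> tuple[list[ScanRecord], list[ScanRecord]]:
    """Partition *subjects* (never scans) into train and test.

    Number of test subjects = round(test_fraction * n_subjects), at least 1
    and at most n_subjects - 1.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a patient-wise split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_test = int(round(test_fraction * len(subjects)))
    n_test = min(max(n_test, 1), len(subjects) - 1)
    test_subjects = {subjects[i] for i in perm[:n_test]}
    train = [r for r in records if r.subject_id not in test_subjects]
    test = [r for r in records if r.subject_id in test_subjects]
    return train, test


def _subject_classes(records: list[ScanRecord]) -> tuple[list[str], list[int]]:
    cls: dict[str, int] = {}
    for r in records:
        if r.label is None:
            raise ValueError("all records must have assigned labels")
        cls[r.subject_id] = max(cls.get(r.subject_id, 0), r.label)
    subjects = sorted(cls)
    return subjects, [cls[s] for s in subjects]


def stratified_folds(records: list[ScanRecord], k: int,
                     seed: int) -> dict[str, int]:
    """Subject-level stratified k-fold assignment (subject_id -> fold).

    Stratification is by subject class (positive if the subject has any
    positive scan), so each fold keeps class proportions within one subject
    of the overall mix, and no subject appears in two folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    subjects, classes = _subject_classes(records)
    counts = [classes.count(0), classes.count(1)]
    if min(counts) < k:
        raise ValueError(
            f"k={k} exceeds the smaller class's subject count {min(counts)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(subjects)),
                                                   np.asarray(classes))):
        for i in test_idx:
            assignment[subjects[i]] = fold
    return assignment
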