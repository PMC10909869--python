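"""Synthetic cohorts with known planted signal.

Real studies of this kind draw on access-controlled longitudinal cohorts of
T1-weighted MRI and amyloid PET with dated clinical diagnoses. This module
emulates the *structure* of such data at desk scale so that every downstream
stage — label correction, brain extraction, model training, attribution — can
be tested against a known ground truth:

* a toy anatomical atlas: an ellipsoidal "brain" partitioned into regions by
  seeded Voronoi growth (standing in for a cortical parcellation);
* per-subject visit timelines whose binary diagnosis follows a monotone
  disease path, corrupted by occasional isolated label flips (the artifacts
  the label-correction step is meant to undo);
* per-visit MRI-like and PET-like volumes, each a per-region baseline plus an
  additive class effect planted in designated regions plus Gaussian voxel
  noise; PET volumes carry a time axis of noisy frames around the target mean.

MRI and PET effect regions are configurable and disjoint by default, so the
complementarity of the two modalities is a property of the generator.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ToyAtlas",
    "EffectSpec",
    "TimelineParams",
    "DiagnosisEvent",
    "ScanRecord",
    "make_toy_atlas",
    "simulate_timeline",
    "simulate_volume",
    "simulate_cohort",
    "default_mri_spec",
    "default_pet_spec",
    "save_cohort",
    "save_atlas",
]


# ---------------------------------------------------------------------------
# domain types shared with the cohort module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosisEvent:
    """One dated binary diagnosis for one subject (day = days since entry)."""

    subject_id: str
    day: int
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")


@dataclass
class ScanRecord:
    """One imaging session: subject, modality, day, volume, assigned label."""

    subject_id: str
    modality: str  # "MRI" | "PET"
    day: int
    volume_ref: object = None  # ndarray or path
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in ("MRI", "PET"):
            raise ValueError(f"modality must be 'MRI' or 'PET', got {self.modality!r}")


@dataclass(frozen=True)
class ToyAtlas:
    """Integer region-label volume (0 = outside brain, 1..R = regions).

    ``shell`` marks a thin bright skull-like rim just outside the brain; it
    is not an atlas region but is part of the simulated head, giving every
    scan a class-independent intensity maximum (as scalp/fat does in real
    T1 images).
    """

    labels: np.ndarray
    names: dict[int, str]
    shell: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.names)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class EffectSpec:
    """Where and how strongly a class effect is planted for one modality."""

    modality: str
    affected_regions: frozenset[int]
    effect_size: float = 1.0
    noise_sd: float = 0.2
    n_frames: int = 1
    brain_offset_sd: float = 0.2

    def __post_init__(self):
        if self.modality not in ("MRI", "PET"):
            raise ValueError(f"modality must be 'MRI' or 'PET', got {self.modality!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "affected_regions",
                           frozenset(self.affected_regions))


@dataclass(frozen=True)
class TimelineParams:
    """Visit schedule and diagnosis-noise settings for simulated subjects."""

    n_visits: int = 3
    day_gap_range: tuple[int, int] = (180, 420)
    flip_prob: float = 0.1


def default_mri_spec(effect_size: float = 1.0, noise_sd: float = 0.2) -> EffectSpec:
    """MRI-like effect: atrophy surrogate planted in region 3."""
    return EffectSpec("MRI", frozenset({3}), effect_size, noise_sd)


def default_pet_spec(effect_size: float = 1.0, noise_sd: float = 0.2,
                     n_frames: int = 4) -> EffectSpec:
    """PET-like effect: tracer-uptake surrogate planted in region 8,
    disjoint from the MRI region so the modalities are complementary."""
    return EffectSpec("PET", frozenset({8}), effect_size, noise_sd, n_frames)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def make_toy_atlas(grid_shape: tuple[int, int, int], n_regions: int,
                   seed: int) -> ToyAtlas:
    """Ellipsoidal brain mask partitioned into ``n_regions`` Voronoi cells.

    Voronoi cells are convex, and a convex set intersected with the
    ellipsoid is connected, so every region is a connected patch. Each seed
    voxel belongs to its own cell, so regions are non-empty by construction.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if any(s < 16 for s in grid_shape):
        raise ValueError(
            f"every grid dimension must be >= 16 to host an atlas, got {grid_shape}")
    grid_shape = tuple(int(s) for s in grid_shape)
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [0.40 * s for s in grid_shape]
    coords = np.indices(grid_shape).astype(np.float64)
    d2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    mask = d2 <= 1.0
    shell = (d2 > 1.0) & (d2 <= 1.25)
    brain_idx = np.argwhere(mask)
    if n_regions > len(brain_idx):
        raise ValueError(
            f"grid too small: brain mask has {len(brain_idx)} voxels, "
            f"cannot host {n_regions} non-empty regions")
    rng = np.random.default_rng(seed)
    seeds = brain_idx[rng.choice(len(brain_idx), size=n_regions, replace=False)]
    # multi-source breadth-first growth from the seed voxels (6-connected):
    # every region is connected by construction, and growth is geodesic
    # within the mask
    from collections import deque

    labels = np.zeros(grid_shape, dtype=np.int32)
    queue = deque()
    for r, (x, y, z) in enumerate(seeds, start=1):
        labels[x, y, z] = r
        queue.append((int(x), int(y), int(z)))
    nbrs = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while queue:
        x, y, z = queue.popleft()
        r = labels[x, y, z]
        for dx, dy, dz in nbrs:
            nx, ny, nz = x + dx, y + dy, z + dz
            if (0 <= nx < grid_shape[0] and 0 <= ny < grid_shape[1]
                    and 0 <= nz < grid_shape[2] and mask[nx, ny, nz]
                    and labels[nx, ny, nz] == 0):
                labels[nx, ny, nz] = r
                queue.append((nx, ny, nz))
    names = {r: f"region_{r:02d}" for r in range(1, n_regions + 1)}
    return ToyAtlas(labels=labels, names=names, shell=shell)


# ---------------------------------------------------------------------------
# timelines
# ---------------------------------------------------------------------------

def progression_path(n_visits: int, onset_visit: int | None) -> list[int]:
    """Monotone disease path: negative before ``onset_visit``, positive from
    it on; ``None`` means the subject never converts."""
    if onset_visit is None:
        return [0] * n_visits
    return [0 if v < onset_visit else 1 for v in range(n_visits)]


def simulate_timeline(n_visits: int, day_gap_range: tuple[int, int],
                      base_label_path, flip_prob: float, seed: int,
                      subject_id: str = "S000") -> list[DiagnosisEvent]:
    """Visit days (strictly increasing) and diagnosis labels along
    ``base_label_path``, with each label independently flipped at rate
    ``flip_prob`` — the isolated artifacts label correction should undo."""
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    base = list(base_label_path)[:n_visits]
    if len(base) < n_visits:
        raise ValueError("base_label_path shorter than n_visits")
    lo, hi = day_gap_range
    if not 1 <= lo <= hi:
        raise ValueError("day_gap_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    gaps = rng.integers(lo, hi + 1, size=n_visits)
    days = np.cumsum(gaps)  # first visit one gap after study entry
    flips = rng.random(n_visits) < flip_prob
    return [
        DiagnosisEvent(subject_id, int(day), int(lab ^ flip))
        for day, lab, flip in zip(days, base, flips)
    ]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

SHELL_INTENSITY = 2.5


def _baseline_map(atlas: ToyAtlas) -> np.ndarray:
    """Per-region baseline intensity: 1.0 plus a small deterministic
    region-dependent offset (same for both classes), plus the bright skull
    shell. The shell pins each scan's intensity maximum independently of
    class, so per-volume normalization cannot leak the planted effect."""
    base = np.zeros(atlas.grid_shape, dtype=np.float32)
    for r in atlas.region_ids:
        base[atlas.labels == r] = 1.0 + 0.04 * (r % 5)
    if atlas.shell is not None:
        base[atlas.shell] = SHELL_INTENSITY
    return base


def clean_volume(atlas: ToyAtlas, class_label: int,
                 effect_spec: EffectSpec) -> np.ndarray:
    """Noise-free 3D target: baseline plus the planted class effect."""
    unknown = set(effect_spec.affected_regions) - set(atlas.region_ids)
    if unknown:
        raise ValueError(f"effect regions not in atlas: {sorted(unknown)}")
    vol = _baseline_map(atlas)
    if class_label == 1 and effect_spec.affected_regions:
        sel = np.isin(atlas.labels, list(effect_spec.affected_regions))
        vol[sel] += effect_spec.effect_size
    return vol


def simulate_volume(atlas: ToyAtlas, class_label: int,
                    effect_spec: EffectSpec, seed: int) -> np.ndarray:
    """One synthetic scan.

    MRI: 3D target plus Gaussian voxel noise.
    PET (``n_frames > 1`` or modality == "PET"): 4D stack of frames, each the
    3D target plus independent Gaussian frame noise, so the per-voxel mean
    over frames equals the target in expectation (bit-exactly at zero noise).

    A per-scan brain-wide intensity offset (``brain_offset_sd``, drawn once
    per scan, identical for both classes at a given seed) emulates
    inter-subject and inter-session tissue-intensity variability. Without
    it, a planted regional effect would make the *global* brain mean a
    perfectly separable class feature — a degenerate shortcut absent from
    real cohorts, where anatomy and calibration vary far more between
    subjects than any focal disease effect moves the global mean.
    """
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label}")
    target = clean_volume(atlas, class_label, effect_spec)
    rng = np.random.default_rng(seed)
    if effect_spec.brain_offset_sd > 0:
        offset = rng.normal(0.0, effect_spec.brain_offset_sd)
        target = target.copy()
        target[atlas.brain_mask] += np.float32(offset)
    if effect_spec.modality == "PET":
        frames = np.repeat(target[..., None], effect_spec.n_frames, axis=3)
        if effect_spec.noise_sd > 0:
            # noise_sd is the effective noise of the frame-averaged image,
            # so individual frames carry sqrt(T) times more
            frame_sd = effect_spec.noise_sd * np.sqrt(effect_spec.n_frames)
            frames = frames + rng.normal(
                0.0, frame_sd, frames.shape).astype(np.float32)
        return frames.astype(np.float32)
    vol = target
    if effect_spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, effect_spec.noise_sd,
                               vol.shape).astype(np.float32)
    return vol.astype(np.float32)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(n_subjects: int, prevalence: float, atlas: ToyAtlas,
                    mri_spec: EffectSpec, pet_spec: EffectSpec,
                    timeline_params: TimelineParams, seed: int,
                    ) -> tuple[list[ScanRecord], list[DiagnosisEvent]]:
    """Paired MRI+PET scan records plus diagnosis timelines.

    Subjects convert with probability ``prevalence``; converters get a random
    onset visit. Volumes are generated from the subject's *true* disease
    state at each visit, while diagnosis events carry the flip-corrupted
    labels — so scan-label curation has genuine errors to fix, and the true
    state is kept in ``ScanRecord.meta['true_label']`` for evaluation.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    records: list[ScanRecord] = []
    events: list[DiagnosisEvent] = []
    tp = timeline_params
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        positive = rng.random() < prevalence
        onset = int(rng.integers(0, tp.n_visits)) if positive else None
        path = progression_path(tp.n_visits, onset)
        tl_seed = int(rng.integers(0, 2**31 - 1))
        timeline = simulate_timeline(tp.n_visits, tp.day_gap_range, path,
                                     tp.flip_prob, tl_seed, subject_id=sid)
        events.extend(timeline)
        for v, ev in enumerate(timeline):
            true_lab = path[v]
            for spec in (mri_spec, pet_spec):
                vol_seed = int(rng.integers(0, 2**31 - 1))
                vol = simulate_volume(atlas, true_lab, spec, vol_seed)
                records.append(ScanRecord(
                    subject_id=sid, modality=spec.modality, day=ev.day,
                    volume_ref=vol, label=None,
                    meta={"true_label": true_lab, "visit": v}))
    return records, events


# ---------------------------------------------------------------------------
# on-disk interchange
# ---------------------------------------------------------------------------

def save_atlas(atlas: ToyAtlas, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the atlas as NIfTI plus an id,name CSV; returns both paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nii = out_dir / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4)), nii)
    csv = out_dir / "atlas_regions.csv"
    pd.DataFrame({"id": atlas.region_ids,
                  "name": [atlas.names[r] for r in atlas.region_ids]}
                 ).to_csv(csv, index=False)
    return nii, csv


def save_cohort(records: list[ScanRecord], events: list[DiagnosisEvent],
                out_dir: str | Path) -> tuple[Path, Path]:
    """Write volumes as NIfTI and the cohort/timeline tables as CSV."""
    import nibabel as nib

    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        path = out_dir / "volumes" / f"{rec.subject_id}_{rec.modality}_{rec.day:05d}_{i}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(rec.volume_ref, dtype=np.float32),
                                 np.eye(4)), path)
        rows.append({"subject_id": rec.subject_id, "modality": rec.modality,
                     "day": rec.day, "path": str(path),
                     "label": "" if rec.label is None else rec.label})
    scans_csv = out_dir / "scans.csv"
    pd.DataFrame(rows).to_csv(scans_csv, index=False)
    events_csv = out_dir / "events.csv"
    pd.DataFrame([{"subject_id": e.subject_id, "day": e.day, "label": e.label}
                  for e in events]).to_csv(events_csv, index=False)
    return scans_csv, events_csv
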