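"""End-to-end desk-scale experiments on synthetic cohorts.

These pipelines wire the whole package together: simulate a cohort with a
planted class effect, curate scan labels through the correction/linking
rules, preprocess volumes, train a classifier, evaluate on held-out
subjects, and (for the recovery experiment) ask Grad-CAM which atlas
regions drove the decision.

Problem sizes are desk-scale study conditions: a 32x32x32 grid with a
10-region atlas, 60 subjects at 50% prevalence with 2 visits each, an
effect-to-noise ratio of 5 (effect 1.0, voxel noise 0.2), and the small
architecture/training configuration. Held-out metrics are computed against
the generator's true disease state, so residual diagnosis noise affects
training realism but not the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cohort as ch
from .evaluate import auc as rank_auc
from .evaluate import confusion, metrics
from .explain import (
    cam_to_scan_grid,
    coverage_mask,
    gradcam,
    region_attribution,
)
from .models import (
    ArchitectureConfig,
    ModelVariant,
    TrainConfig,
    build_model,
    predict,
    train,
)
from .preprocess import PreprocessConfig, preprocess_volume
from .synth import (
    EffectSpec,
    TimelineParams,
    make_toy_atlas,
    simulate_cohort,
)

__all__ = [
    "DeskStudy",
    "build_desk_cohort",
    "prepare_modality",
    "run_unimodal",
    "run_planted_recovery",
    "run_fusion_comparison_once",
]


@dataclass(frozen=True)
class DeskStudy:
    """Study conditions for the desk-scale experiments."""

    grid: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 10
    n_subjects: int = 60
    prevalence: float = 0.5
    mri_regions: frozenset[int] = frozenset({3})
    pet_regions: frozenset[int] = frozenset({8})
    effect_mri: float = 1.0
    effect_pet: float = 1.0
    noise_sd: float = 0.2
    n_frames: int = 4
    timeline: TimelineParams = field(default_factory=lambda: TimelineParams(
        n_visits=2, day_gap_range=(180, 420), flip_prob=0.1))
    test_fraction: float = 0.2
    val_fraction: float = 0.25


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def build_desk_cohort(seed: int, study: DeskStudy = DeskStudy()):
    """Atlas + label-curated scan records for one simulated study."""
    s_atlas, s_cohort = _seeds(seed, 2)
    atlas = make_toy_atlas(study.grid, study.n_regions, s_atlas)
    mri_spec = EffectSpec("MRI", study.mri_regions, study.effect_mri,
                          study.noise_sd)
    pet_spec = EffectSpec("PET", study.pet_regions, study.effect_pet,
                          study.noise_sd, study.n_frames)
    records, events = simulate_cohort(
        study.n_subjects, study.prevalence, atlas, mri_spec, pet_spec,
        study.timeline, s_cohort)
    records = ch.assign_labels(records, events)
    return atlas, records, events


def prepare_modality(records, modality: str, pconfig: PreprocessConfig):
    """Preprocess all records of one modality into a model-ready stack.

    Returns ``(X, y_train, y_true, provenance, infos)`` where ``y_train``
    are the curated pipeline labels and ``y_true`` the generator's disease
    states.
    """
    sel = [r for r in records if r.modality == modality]
    vols, infos = [], []
    for r in sel:
        v, info = preprocess_volume(np.asarray(r.volume_ref), pconfig)
        vols.append(v)
        infos.append(info)
    X = np.stack(vols).astype(np.float32)
    y_train = np.array([r.label for r in sel], dtype=np.int64)
    y_true = np.array([r.meta.get("true_label", r.label) for r in sel],
                      dtype=np.int64)
    prov = [(r.subject_id, f"{r.modality}:{r.day}") for r in sel]
    return X, y_train, y_true, prov, infos


def _three_way_split(records, study: DeskStudy, seed: int):
    s_test, s_val = _seeds(seed + 1, 2)
    train_recs, test_recs = ch.patient_wise_split(records, study.test_fraction,
                                                  s_test)
    fit_recs, val_recs = ch.patient_wise_split(train_recs, study.val_fraction,
                                               s_val)
    return fit_recs, val_recs, test_recs


def run_unimodal(seed: int, modality: str = "MRI",
                 study: DeskStudy = DeskStudy(),
                 max_epochs: int = 60,
                 keep_test_artifacts: bool = False) -> dict:
    """Train one 3D uni-modal classifier and evaluate on held-out subjects."""
    atlas, records, _ = build_desk_cohort(seed, study)
    fit_recs, val_recs, test_recs = _three_way_split(records, study, seed)
    pconfig = PreprocessConfig.desk_scale()
    Xf, yf, _, _, _ = prepare_modality(fit_recs, modality, pconfig)
    Xv, yv, _, _, _ = prepare_modality(val_recs, modality, pconfig)
    Xt, _, yt_true, prov, infos = prepare_modality(test_recs, modality, pconfig)
    s_model, s_train = _seeds(seed + 2, 2)
    variant = ModelVariant.MRI_3D if modality == "MRI" else ModelVariant.PET_3D
    model = build_model(variant, ArchitectureConfig.desk_scale(3),
                        Xf.shape[1:], seed=s_model)
    cfg = TrainConfig.desk_scale(seed=s_train, max_epochs=max_epochs)
    model, history = train(model, (Xf, yf), (Xv, yv), cfg)
    preds = predict(model, Xt, yt_true, prov)
    row = metrics(confusion(preds), percentage=False)
    both_classes = len(set(yt_true.tolist())) == 2
    result = {
        "model": model,
        "atlas": atlas,
        "history": history,
        "test_accuracy": row.accuracy,
        "test_sensitivity": row.sensitivity,
        "test_specificity": row.specificity,
        "test_auc": rank_auc(preds) if both_classes else None,
        "n_test": len(preds),
    }
    if keep_test_artifacts:
        result.update({"X_test": Xt, "y_test_true": yt_true,
                       "test_infos": infos, "test_records": test_recs})
    return result


def run_planted_recovery(seed: int, study: DeskStudy = DeskStudy(),
                         modality: str = "MRI",
                         gradcam_layer: int | None = None,
                         max_epochs: int = 60) -> dict:
    """Train a uni-modal model, then test whether Grad-CAM's top-percentile
    region selection for the positive group recovers the planted regions."""
    res = run_unimodal(seed, modality, study, max_epochs=max_epochs,
                       keep_test_artifacts=True)
    atlas = res["atlas"]
    model = res["model"]
    planted = (study.mri_regions if modality == "MRI" else study.pet_regions)
    planted_names = {atlas.names[r] for r in planted}
    pos = np.flatnonzero(res["y_test_true"] == 1)
    acc_map = np.zeros(atlas.grid_shape, dtype=np.float64)
    seen = np.zeros(atlas.grid_shape, dtype=bool)
    for i in pos:
        cam = gradcam(model, res["X_test"][i], class_index=1,
                      layer=gradcam_layer)
        info = res["test_infos"][i]
        acc_map += cam_to_scan_grid(cam, info, atlas.grid_shape)
        seen |= coverage_mask(info, atlas.grid_shape)
    acc_map /= max(len(pos), 1)
    attrib = region_attribution(acc_map, atlas, mask=seen)
    res.update({
        "planted_regions": planted_names,
        "selected_regions": set(attrib.selected),
        "recovered": planted_names <= set(attrib.selected),
        "region_means": attrib.means,
        "n_positive_test": int(len(pos)),
    })
    return res


def _pair_records(records):
    """Pair each subject-day's MRI and PET scans (fusion input)."""
    mri = {(r.subject_id, r.day): r for r in records if r.modality == "MRI"}
    pet = {(r.subject_id, r.day): r for r in records if r.modality == "PET"}
    keys = sorted(set(mri) & set(pet))
    return [(mri[k], pet[k]) for k in keys]


def _prepare_pairs(records, pconfig):
    pairs = _pair_records(records)
    Xm, Xp, y_fit, y_true, prov = [], [], [], [], []
    for rm, rp in pairs:
        vm, _ = preprocess_volume(np.asarray(rm.volume_ref), pconfig)
        vp, _ = preprocess_volume(np.asarray(rp.volume_ref), pconfig)
        Xm.append(vm)
        Xp.append(vp)
        y_fit.append(rm.label)
        y_true.append(rm.meta.get("true_label", rm.label))
        prov.append((rm.subject_id, f"pair:{rm.day}"))
    return (np.stack(Xm).astype(np.float32), np.stack(Xp).astype(np.float32),
            np.array(y_fit), np.array(y_true), prov)


def run_fusion_comparison_once(seed: int, study: DeskStudy | None = None,
                               max_epochs: int = 60) -> dict:
    """One seed of the complementarity experiment: disjoint MRI/PET effect
    regions with per-modality effect halved; fusion vs both uni-modal 3D
    models on the same cohort and split."""
    if study is None:
        study = DeskStudy(n_subjects=48, effect_mri=0.5, effect_pet=0.5)
    atlas, records, _ = build_desk_cohort(seed, study)
    fit_recs, val_recs, test_recs = _three_way_split(records, study, seed)
    pconfig = PreprocessConfig.desk_scale()
    out = {}
    s_model, s_train = _seeds(seed + 2, 2)
    # uni-modal arms
    for modality, variant in (("MRI", ModelVariant.MRI_3D),
                              ("PET", ModelVariant.PET_3D)):
        Xf, yf, _, _, _ = prepare_modality(fit_recs, modality, pconfig)
        Xv, yv, _, _, _ = prepare_modality(val_recs, modality, pconfig)
        Xt, _, yt, prov, _ = prepare_modality(test_recs, modality, pconfig)
        model = build_model(variant, ArchitectureConfig.desk_scale(3),
                            Xf.shape[1:], seed=s_model)
        cfg = TrainConfig.desk_scale(seed=s_train, max_epochs=max_epochs)
        model, _ = train(model, (Xf, yf), (Xv, yv), cfg)
        preds = predict(model, Xt, yt, prov)
        out[modality.lower()] = metrics(confusion(preds),
                                        percentage=False).accuracy
    # fusion arm
    Xmf, Xpf, yf, _, _ = _prepare_pairs(fit_recs, pconfig)
    Xmv, Xpv, yv, _, _ = _prepare_pairs(val_recs, pconfig)
    Xmt, Xpt, _, yt, prov = _prepare_pairs(test_recs, pconfig)
    fusion = build_model(ModelVariant.FUSION_3D,
                         ArchitectureConfig.desk_scale(3),
                         Xmf.shape[1:], seed=s_model)
    cfg = TrainConfig.desk_scale(seed=s_train, max_epochs=max_epochs)
    fusion, _ = train(fusion, ((Xmf, Xpf), yf), ((Xmv, Xpv), yv), cfg)
    preds = predict(fusion, (Xmt, Xpt), yt, prov)
    out["fusion"] = metrics(confusion(preds), percentage=False).accuracy
    out["n_test_pairs"] = len(preds)
    return out
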