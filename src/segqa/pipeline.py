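"""End-to-end study orchestration.

One call runs the whole experiment on synthetic phantoms: generate an
in-distribution training cohort, an in-distribution test cohort and an
out-of-distribution cohort; train the dropout U-Net on the training cohort
only; run T stochastic forward passes per test slice; derive uncertainty
maps; stratify pixel outcomes and sweep certainty thresholds; score
segmentation geometry; summarize scan-level mutual information and test
ID/OOD separation; render example review panels.  Every stage draws its
randomness from a named substream of the master seed and all tabular outputs
are written as CSV/JSON next to a manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .error_analysis import (
    DEFAULT_THRESHOLDS,
    OutcomeMap,
    ThresholdSweepResult,
    classify_outcomes,
    pe_distribution_by_outcome,
    threshold_sweep,
)
from .inference import mean_and_binarize, sample_ensemble_volume
from .io import RunConfig, config_hash, config_to_yaml, write_volume
from .metrics import segmentation_report
from .model import TrainResult, build_model, save_checkpoint, train
from .ood import ScanUncertaintySummary, SeparationReport, separation_analysis, summarize_scan
from .phantom import Cohort, default_spec, generate_cohort
from .uncertainty import uncertainty_maps
from .viz import flag_pixels, render_panels

log = logging.getLogger("segqa")

_STREAMS = ("gen_train", "gen_test", "gen_ood", "model_init", "train",
            "infer_test", "infer_ood")


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Named per-stage substream seeds from the master seed (all < 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STREAMS))
    return {name: int(s % 2**31) for name, s in zip(_STREAMS, state)}


def ood_spec(seed: int, shift: float = 1.0, image_size: int = 64):
    """The OOD phantom conditions, with the contrast/shape shift scaled by
    ``shift`` (1 = the default study gap, 0 = identical to ID)."""
    id_spec = default_spec(Cohort.ID, seed=seed, image_size=image_size)
    full = default_spec(Cohort.OOD, seed=seed, image_size=image_size)
    if shift == 1.0:
        return full
    means = tuple(
        (1 - shift) * a + shift * b
        for a, b in zip(id_spec.intensity_means, full.intensity_means)
    )
    shapes = {}
    for cls, sp_id in id_spec.shape_params.items():
        sp_ood = full.shape_params[cls]
        shapes[cls] = dataclasses.replace(
            sp_id,
            axes=tuple((1 - shift) * a + shift * b
                       for a, b in zip(sp_id.axes, sp_ood.axes)),
            axes_jitter=(1 - shift) * sp_id.axes_jitter + shift * sp_ood.axes_jitter,
        )
    return dataclasses.replace(full, intensity_means=means, shape_params=shapes)


@dataclass
class SliceCase:
    """Everything derived from one test slice."""

    scan: int
    slice_index: int
    image: np.ndarray
    truth: np.ndarray
    pred: np.ndarray
    pcpe: np.ndarray          # (C, H, W) per-class PE
    pe: np.ndarray            # (H, W)
    mi: np.ndarray            # (H, W)
    outcomes: OutcomeMap


@dataclass
class StudyResult:
    config: RunConfig
    seeds: dict[str, int]
    train_result: TrainResult
    id_cases: list[SliceCase]
    sweep: ThresholdSweepResult
    distributions: pd.DataFrame
    outcome_fractions: pd.DataFrame   # per structure: correct low-PE / wrong high-PE
    geometry: pd.DataFrame            # per scan+slice+structure DSC/HD95/MSD
    id_summaries: list[ScanUncertaintySummary]
    ood_summaries: list[ScanUncertaintySummary]
    separation: SeparationReport
    runtime_s: float = 0.0

    # -- headline quantities -------------------------------------------------
    def separation_accuracy_percent(self) -> float:
        return 100.0 * self.separation.best_accuracy

    def min_correct_lowpe_percent(self) -> float:
        """Min over structures of % correct (TP+TN) pixels with PE <= 0.05."""
        return float(self.outcome_fractions["correct_pe_le_0.05_pct"].min())

    def min_wrong_highpe_percent(self) -> float:
        """Min over structures of % wrong (FP+FN) pixels with PE > 0.10."""
        return float(self.outcome_fractions["wrong_pe_gt_0.10_pct"].min())


def _analyze_scan(model, volume, mask_volume, T, seed):
    """Per-slice ensembles -> (cases-without-scan-ids, mi_volume, pe_volume)."""
    ensembles = sample_ensemble_volume(model, volume, T=T, seed=seed)
    cases, mi_slices, pe_slices = [], [], []
    for s, (ens, truth) in enumerate(zip(ensembles, mask_volume)):
        maps = uncertainty_maps(ens)
        pred = mean_and_binarize(ens).label_mask
        cases.append(SliceCase(
            scan=-1, slice_index=s, image=volume[s], truth=truth, pred=pred,
            pcpe=maps.per_class_pe, pe=maps.pe, mi=maps.mi,
            outcomes=classify_outcomes(pred, truth),
        ))
        mi_slices.append(maps.mi)
        pe_slices.append(maps.pe)
    return cases, np.stack(mi_slices), np.stack(pe_slices)


def _outcome_fraction_table(cases: list[SliceCase]) -> pd.DataFrame:
    """Pooled per-structure fractions: correct pixels with PE <= 0.05 and
    wrong pixels with PE > 0.10 (in percent)."""
    from .error_analysis import FN, FP, TN, TP
    from .phantom import CLASS_NAMES

    rows = []
    for c in (1, 2, 3):
        pe_vals = np.concatenate([case.pcpe[c].ravel() for case in cases])
        codes = np.concatenate([case.outcomes.codes[c].ravel() for case in cases])
        correct = (codes == TP) | (codes == TN)
        wrong = (codes == FP) | (codes == FN)
        rows.append({
            "class": CLASS_NAMES[c],
            "n_correct": int(correct.sum()),
            "n_wrong": int(wrong.sum()),
            "correct_pe_le_0.05_pct":
                100.0 * float((pe_vals[correct] <= 0.05).mean()) if correct.any() else np.nan,
            "wrong_pe_gt_0.10_pct":
                100.0 * float((pe_vals[wrong] > 0.10).mean()) if wrong.any() else np.nan,
        })
    return pd.DataFrame(rows)


def run_study(cfg: RunConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Run the full uncertainty-QA study under one configuration."""
    cfg.validate()
    t0 = time.time()
    seeds = derive_seeds(cfg.seed)
    logging.basicConfig(level=cfg.log_level)
    log.info("stage=seeds %s", seeds)

    # -- cohorts -------------------------------------------------------------
    id_train = generate_cohort(
        default_spec(Cohort.ID, seed=seeds["gen_train"], image_size=cfg.image_size),
        cfg.n_train_scans, cfg.slices_per_scan)
    id_test = generate_cohort(
        default_spec(Cohort.ID, seed=seeds["gen_test"], image_size=cfg.image_size),
        cfg.n_test_scans, cfg.slices_per_scan)
    ood = generate_cohort(
        ood_spec(seeds["gen_ood"], shift=cfg.ood_shift, image_size=cfg.image_size),
        cfg.n_ood_scans, cfg.slices_per_scan)
    log.info("stage=generate id_train=%d id_test=%d ood=%d scans",
             len(id_train), len(id_test), len(ood))

    # -- training (in-distribution scans only) -------------------------------
    model = build_model(cfg.model, seed=seeds["model_init"])
    tr_cfg = dataclasses.replace(cfg.train, seed=seeds["train"])
    tres = train(model, id_train, tr_cfg)
    log.info("stage=train loss %0.4f -> %0.4f, mean dropout p=%0.3f",
             tres.loss_trace[0], tres.loss_trace[-1], tres.mean_dropout_probability)

    # -- inference + uncertainty on the ID test cohort -----------------------
    id_cases: list[SliceCase] = []
    id_summaries, geometry_rows = [], []
    test_children = np.random.SeedSequence(seeds["infer_test"]).spawn(len(id_test))
    for i, ((vol, msk), child) in enumerate(zip(id_test, test_children)):
        scan_seed = int(child.generate_state(1)[0] % 2**31)
        cases, mi_vol, pe_vol = _analyze_scan(model, vol, msk, cfg.T, scan_seed)
        for case in cases:
            case.scan = i
            rep = segmentation_report(case.pred, case.truth, spacing=cfg.spacing[1:])
            for sname, m in rep.items():
                geometry_rows.append({"scan": i, "slice": case.slice_index,
                                      "structure": sname, **m})
        id_cases.extend(cases)
        id_summaries.append(summarize_scan(mi_vol, pe_vol, f"ID-{i:02d}", "ID"))

    # -- inference on the OOD cohort (scan-level summaries only) -------------
    ood_summaries = []
    ood_children = np.random.SeedSequence(seeds["infer_ood"]).spawn(len(ood))
    for i, ((vol, msk), child) in enumerate(zip(ood, ood_children)):
        scan_seed = int(child.generate_state(1)[0] % 2**31)
        _, mi_vol, pe_vol = _analyze_scan(model, vol, msk, cfg.T, scan_seed)
        ood_summaries.append(summarize_scan(mi_vol, pe_vol, f"OOD-{i:02d}", "OOD"))
    log.info("stage=infer done (%d ID cases)", len(id_cases))

    # -- error analysis ------------------------------------------------------
    sweep = threshold_sweep(
        [(c.outcomes, c.pcpe) for c in id_cases], cfg.thresholds or DEFAULT_THRESHOLDS)
    pooled_codes = np.concatenate([c.outcomes.codes for c in id_cases], axis=1)
    pooled_pcpe = np.concatenate([c.pcpe for c in id_cases], axis=1)
    dist = pe_distribution_by_outcome(OutcomeMap(codes=pooled_codes), pooled_pcpe)
    fractions = _outcome_fraction_table(id_cases)
    separation = separation_analysis(id_summaries, ood_summaries)
    log.info("stage=analyze separation=%.2f%% margin=%.4g",
             100 * separation.best_accuracy, separation.margin)

    result = StudyResult(
        config=cfg, seeds=seeds, train_result=tres, id_cases=id_cases,
        sweep=sweep, distributions=dist, outcome_fractions=fractions,
        geometry=pd.DataFrame(geometry_rows),
        id_summaries=id_summaries, ood_summaries=ood_summaries,
        separation=separation, runtime_s=time.time() - t0,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir), model)
    return result


def write_outputs(res: StudyResult, out_dir: Path, model=None) -> None:
    """Persist every stage's tabular output, the checkpoint, a rendered
    example panel and a manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    config_to_yaml(cfg, out_dir / "config.yaml")
    if model is not None:
        save_checkpoint(model, out_dir / "model.npz")
    res.sweep.per_image.to_csv(out_dir / "sweep_per_image.csv", index=False)
    res.sweep.summary.to_csv(out_dir / "sweep_summary.csv", index=False)
    res.distributions.to_csv(out_dir / "pe_distributions.csv", index=False)
    res.outcome_fractions.to_csv(out_dir / "outcome_fractions.csv", index=False)
    res.geometry.to_csv(out_dir / "geometry_metrics.csv", index=False)
    with open(out_dir / "scan_summaries.jsonl", "w") as fh:
        for s in res.id_summaries + res.ood_summaries:
            fh.write(json.dumps(dataclasses.asdict(s)) + "\n")
    with open(out_dir / "separation.json", "w") as fh:
        json.dump(dataclasses.asdict(res.separation), fh, indent=2)

    case = res.id_cases[0]
    write_volume(case.truth, cfg.spacing[1:], out_dir / "example_truth.nii.gz")
    write_volume(case.pred, cfg.spacing[1:], out_dir / "example_pred.nii.gz")
    write_volume(case.pe, cfg.spacing[1:], out_dir / "example_pe.nii.gz")
    fmap = flag_pixels(case.pred, case.pcpe, cfg.flag_threshold, class_id=None)
    render_panels(case.image, case.truth, case.pred, case.pe, fmap,
                  out_dir / "example_panels.png")

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seeds": res.seeds,
        "runtime_s": round(res.runtime_s, 2),
        "mean_dropout_probability": res.train_result.mean_dropout_probability,
        "final_training_loss": res.train_result.loss_trace[-1],
        "separation_accuracy_percent": res.separation_accuracy_percent(),
        "min_correct_lowpe_percent": res.min_correct_lowpe_percent(),
        "min_wrong_highpe_percent": res.min_wrong_highpe_percent(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
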