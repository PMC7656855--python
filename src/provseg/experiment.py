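"""Orchestrate the contour-provenance study on a synthetic cohort.

The study asks: does training a CT segmentation network on degraded contours
drawn in the low-contrast frame (the CT/CT analogue) lose performance and
gain predictive uncertainty compared to training on clean contours propagated
from the high-contrast frame (the CT/MRregCT analogue)?  A third arm trains
and predicts directly on the high-contrast pseudo-MR (the MR/MR analogue,
an upper performance bound).

All arms are evaluated against the same propagated-clean ground truth in the
CT frame; test predictions come only from each fold's held-out cases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CaseRecord,
    DegradationSpec,
    PhantomSpec,
    calibrated_degradation,
    desk_calibrated_degradation,
    generate_cohort,
)
from .inference import mc_entropy_map, postprocess, predict_volume
from .metrics import MetricRecord, evaluate_case, rtog_pass_rate, wilcoxon_signed_rank
from .network import ArchitectureConfig
from .preprocess import AugmentationSpec, normalize_ct, normalize_mr, propagate_contour, resample
from .training import HyperbandSchedule, TrainingCase, run_hyperband
from .types import LabelMask, Volume

logger = logging.getLogger("provseg")

ARM_CLEAN = "clean_contours"      # CT images, propagated clean contours (CT/MRregCT analogue)
ARM_DEGRADED = "degraded_contours"  # CT images, degraded contours (CT/CT analogue)
ARM_MR = "mr_upper_bound"         # MR images, clean contours (MR/MR analogue)
ARM_MANUAL = "manual_degraded"    # the degraded contours themselves, scored as-is

CT_FRAME_ARMS = (ARM_CLEAN, ARM_DEGRADED)


@dataclass(frozen=True)
class ExperimentConfig:
    n_cases: int = 20
    n_folds: int = 5
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationSpec = field(default_factory=calibrated_degradation)
    arms: tuple[str, ...] = (ARM_CLEAN, ARM_DEGRADED)
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    schedule: HyperbandSchedule = field(default_factory=HyperbandSchedule.desk_scale)
    lr_range: tuple[float, float] = (3e-4, 3e-2)
    rigid_augmentation: bool = False
    train_spacing_mm: float | None = None  # None: stay on the native grid
    propagation_smooth_sd_mm: float = 1.0
    propagation_threshold: float = 0.5
    mc_samples: int = 25
    batch_size: int = 4
    seed: int = 0


def desk_config(seed: int = 0, arms: tuple[str, ...] = (ARM_CLEAN, ARM_DEGRADED),
                rigid_augmentation: bool = False) -> ExperimentConfig:
    """Desk-scale study conditions: 20 cases, 5 folds of 12/4/4, small grids,
    a tiny 3-level network (5-slice slab) and a (4, 2, 1)-trial halving ladder."""
    phantom = PhantomSpec(
        grid_shape=(18, 24, 24),
        spacing_mm=(1.5, 1.5, 1.5),
        structure_length_mm=19.0,
        structure_radius_mm=3.0,
        curvature_mm=2.0,
        lateral_offset_mm=7.0,
        affine_jitter=(1.2, 1.2),
    )
    arch = ArchitectureConfig(
        n_levels=3, layers_per_dense_block=1, growth_rate=4,
        dropout_rate=0.1, in_plane_size=24, slab_in=5, sep_channels=8,
    )
    return ExperimentConfig(
        n_cases=20,
        n_folds=5,
        phantom=phantom,
        degradation=desk_calibrated_degradation(),
        arms=arms,
        architecture=arch,
        schedule=HyperbandSchedule(((4, 60), (2, 120), (1, 240))),
        lr_range=(1e-3, 3e-2),
        rigid_augmentation=rigid_augmentation,
        mc_samples=5,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-case preprocessed bundle
# ---------------------------------------------------------------------------


@dataclass
class PreparedCase:
    case_id: str
    ct_image: Volume            # normalized, training grid
    mr_image: Volume
    gt_ct: LabelMask            # propagated clean ground truth, CT frame
    degraded_ct: LabelMask
    gt_mr: LabelMask
    record: CaseRecord


def prepare_case(record: CaseRecord, config: ExperimentConfig) -> PreparedCase:
    ct = normalize_ct(record.ct_volume)
    mr = normalize_mr(record.mr_volume)
    gt_ct = propagate_contour(
        record.gt_mask_mr,
        record.tilt_angle_deg,
        record.true_affine,
        smooth_sd_mm=config.propagation_smooth_sd_mm,
        threshold=config.propagation_threshold,
        target=record.ct_volume.grid,
    )
    degraded = record.degraded_mask_ct
    gt_mr = record.gt_mask_mr
    if config.train_spacing_mm is not None:
        ct = resample(ct, config.train_spacing_mm)
        mr = resample(mr, config.train_spacing_mm)
        gt_ct = resample(gt_ct, config.train_spacing_mm)
        degraded = resample(degraded, config.train_spacing_mm)
        gt_mr = resample(gt_mr, config.train_spacing_mm)
    return PreparedCase(record.case_id, ct, mr, gt_ct, degraded, gt_mr, record)


def _arm_training_case(prep: PreparedCase, arm: str) -> TrainingCase:
    if arm == ARM_CLEAN:
        return TrainingCase(prep.case_id, prep.ct_image, prep.gt_ct)
    if arm == ARM_DEGRADED:
        return TrainingCase(prep.case_id, prep.ct_image, prep.degraded_ct)
    if arm == ARM_MR:
        return TrainingCase(prep.case_id, prep.mr_image, prep.gt_mr)
    raise ValueError(f"unknown arm {arm!r}")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate(records: list[MetricRecord]) -> dict:
    """Median, IQR (Q3-Q1, linear-interpolation quantiles), mean, sd per metric.

    Dice includes empty-prediction cases; surface-distance aggregates exclude
    them and report the excluded count.  The RTOG passing rate counts records
    without a Hausdorff distance as failures.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")

    def stats_of(values):
        v = np.asarray(values, dtype=float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        return {
            "median": float(med),
            "iqr": float(q3 - q1),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }

    out: dict = {"n_records": len(records)}
    out["dice"] = stats_of([r.dice for r in records])
    with_dist = [r for r in records if r.hausdorff_mm is not None]
    out["n_excluded_from_distances"] = len(records) - len(with_dist)
    if with_dist:
        out["mean_surface_distance_mm"] = stats_of([r.mean_surface_distance_mm for r in with_dist])
        out["hausdorff_mm"] = stats_of([r.hausdorff_mm for r in with_dist])
        hds = [r.hausdorff_mm if r.hausdorff_mm is not None else np.inf for r in records]
        out["rtog_pass_rate_pct"] = rtog_pass_rate(hds)
    tols = sorted({t for r in records for t in r.contour_dice})
    out["contour_dice"] = {
        t: stats_of([r.contour_dice[t] for r in records if t in r.contour_dice]) for t in tols
    }
    ud_tols = sorted({t for r in records for t in r.uncertainty_density})
    if ud_tols:
        out["uncertainty_density"] = {
            t: stats_of([r.uncertainty_density[t] for r in records if t in r.uncertainty_density])
            for t in ud_tols
        }
    return out


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "side": r.side,
            "dice": r.dice,
            "mean_surface_distance_mm": r.mean_surface_distance_mm,
            "hausdorff_mm": r.hausdorff_mm,
            "flags": ";".join(r.flags),
        }
        for t, v in r.contour_dice.items():
            row[f"contour_dice_{t:g}mm"] = v
        for t, v in r.uncertainty_density.items():
            row[f"uncertainty_density_{t:g}mm"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------


@dataclass
class ArmSummary:
    arm: str
    records: list[MetricRecord]
    aggregates: dict
    best_per_fold: dict[int, dict] = field(default_factory=dict)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    arm_summaries: dict[str, ArmSummary]
    pairwise_tests: dict[str, float]
    manifest: dict
    failures: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "arms": {a: s.aggregates for a, s in self.arm_summaries.items()},
            "pairwise_wilcoxon_p": self.pairwise_tests,
            "failures": self.failures,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for arm, s in self.arm_summaries.items():
            records_to_frame(s.records).to_csv(out / f"metrics_{arm}.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary_dict(), indent=2, default=float))
        (out / "pairwise_tests.json").write_text(json.dumps(self.pairwise_tests, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        (out / "report.txt").write_text(self.render_text())

    def render_text(self) -> str:
        lines = ["Contour-provenance study report", "=" * 32]
        for arm, s in self.arm_summaries.items():
            agg = s.aggregates
            lines.append(f"\n[{arm}]  n={agg['n_records']} case-sides")
            d = agg["dice"]
            lines.append(f"  Dice: median {d['median']:.3f} (IQR {d['iqr']:.3f}), mean {d['mean']:.3f} +/- {d['sd']:.3f}")
            if "hausdorff_mm" in agg:
                h = agg["hausdorff_mm"]
                m = agg["mean_surface_distance_mm"]
                lines.append(f"  MSD: median {m['median']:.2f} mm; HD: median {h['median']:.2f} mm; "
                             f"RTOG pass rate {agg['rtog_pass_rate_pct']:.1f}%")
            if agg.get("n_excluded_from_distances"):
                lines.append(f"  ({agg['n_excluded_from_distances']} record(s) without distance metrics)")
            if "uncertainty_density" in agg:
                parts = [f"tau={t:g}: {v['mean']:.3f}" for t, v in agg["uncertainty_density"].items()]
                lines.append("  Uncertainty density (mean nats): " + ", ".join(parts))
        lines.append("\nPairwise Wilcoxon signed-rank (Dice):")
        for k, p in self.pairwise_tests.items():
            lines.append(f"  {k}: p = {p:.3g}")
        if self.failures:
            lines.append("\nFailures: " + "; ".join(self.failures))
        return "\n".join(lines)


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentReport:
    """Run the full study: cohort, per-fold hyperparameter searches per arm,
    held-out predictions, metrics, uncertainty and pairwise tests."""
    records, splits = generate_cohort(
        config.n_cases, config.phantom, config.degradation, config.n_folds, config.seed
    )
    prepared = {r.case_id: prepare_case(r, config) for r in records}

    # the degraded contours scored against the clean ground truth
    manual_records: list[MetricRecord] = []
    for cid, prep in prepared.items():
        manual_records.extend(evaluate_case(cid, prep.degraded_ct, prep.gt_ct))

    aug = AugmentationSpec(flip_prob=0.5) if config.rigid_augmentation else AugmentationSpec.flip_only()

    arm_records: dict[str, list[MetricRecord]] = {arm: [] for arm in config.arms}
    best_per_fold: dict[str, dict[int, dict]] = {arm: {} for arm in config.arms}
    manifest = {"folds": [], "predictions": []}
    failures: list[str] = []
    for split in splits:
        manifest["folds"].append(
            {"fold_id": split.fold_id, "train_ids": list(split.train_ids),
             "validation_ids": list(split.validation_ids), "test_ids": list(split.test_ids)}
        )
    rng = np.random.default_rng(config.seed + 7919)
    for split in splits:
        for arm in config.arms:
            try:
                train_cases = [_arm_training_case(prepared[c], arm) for c in split.train_ids]
                val_cases = [_arm_training_case(prepared[c], arm) for c in split.validation_ids]
                arm_seed = int(rng.integers(0, 2**31 - 1))
                best, _ = run_hyperband(
                    config.schedule, config.architecture, train_cases, val_cases,
                    config.lr_range, seed=arm_seed, augmentation=aug,
                    batch_size=config.batch_size,
                )
                best_per_fold[arm][split.fold_id] = {
                    "trial_id": best.trial_id,
                    "learning_rate": best.learning_rate,
                    "validation_jaccard": best.validation_jaccard,
                    "iterations": best.iterations_completed,
                }
                mc_seed = int(rng.integers(0, 2**31 - 1))
                for cid in split.test_ids:
                    prep = prepared[cid]
                    test_case = _arm_training_case(prep, arm)
                    probs = predict_volume(best.network, test_case.image)
                    pred = postprocess(probs, test_case.image.grid, eval_spacing_mm=None)
                    entropy_values = None
                    if arm in CT_FRAME_ARMS and config.architecture.dropout_rate > 0:
                        emap, _ = mc_entropy_map(best.network, test_case.image,
                                                 n_samples=config.mc_samples, seed=mc_seed)
                        entropy_values = emap.values
                    if arm == ARM_MR:
                        pred = propagate_contour(
                            pred, prep.record.tilt_angle_deg, prep.record.true_affine,
                            smooth_sd_mm=config.propagation_smooth_sd_mm,
                            threshold=config.propagation_threshold,
                            target=prep.gt_ct.grid,
                        )
                    arm_records[arm].extend(evaluate_case(cid, pred, prep.gt_ct, entropy_values))
                    manifest["predictions"].append({"case_id": cid, "fold_id": split.fold_id, "arm": arm})
            except Exception as exc:  # failed fold: keep a partial report
                msg = f"fold {split.fold_id}, arm {arm}: {exc!r}"
                logger.error(msg)
                failures.append(msg)

    case_fold = {p["case_id"]: p["fold_id"] for p in manifest["predictions"]}
    summaries = {ARM_MANUAL: ArmSummary(ARM_MANUAL, manual_records, aggregate(manual_records))}
    for arm in config.arms:
        if arm_records[arm]:
            agg = aggregate(arm_records[arm])
            # pooled vs per-fold view of the headline metric, labeled explicitly
            by_fold: dict[int, list[float]] = {}
            for r in arm_records[arm]:
                by_fold.setdefault(case_fold[r.case_id], []).append(r.dice)
            agg["dice_per_fold_median"] = {
                f: float(np.median(v)) for f, v in sorted(by_fold.items())
            }
            agg["dice_pooled_median"] = agg["dice"]["median"]
            summaries[arm] = ArmSummary(arm, arm_records[arm], agg, best_per_fold[arm])

    pairwise = {}
    arms_with_records = [a for a in summaries if summaries[a].records]
    for i, a in enumerate(arms_with_records):
        for b in arms_with_records[i + 1 :]:
            da = {(r.case_id, r.side): r.dice for r in summaries[a].records}
            db = {(r.case_id, r.side): r.dice for r in summaries[b].records}
            common = sorted(set(da) & set(db))
            if len(common) >= 5:
                pairwise[f"{a}_vs_{b}"] = wilcoxon_signed_rank(
                    [da[k] for k in common], [db[k] for k in common]
                )

    report = ExperimentReport(config, summaries, pairwise, manifest, failures)
    if out_dir is not None:
        report.write(out_dir)
    return report


def verify_no_leakage(report: ExperimentReport) -> None:
    """Assert every prediction's case is in its fold's test ids and each case
    is tested in exactly one fold."""
    fold_tests = {f["fold_id"]: set(f["test_ids"]) for f in report.manifest["folds"]}
    seen: dict[str, int] = {}
    for p in report.manifest["predictions"]:
        if p["case_id"] not in fold_tests[p["fold_id"]]:
            raise AssertionError(f"prediction for {p['case_id']} outside its fold's test set")
        prev = seen.setdefault(p["case_id"], p["fold_id"])
        if prev != p["fold_id"]:
            raise AssertionError(f"case {p['case_id']} tested in multiple folds")
    all_tests = [cid for s in fold_tests.values() for cid in s]
    if len(all_tests) != len(set(all_tests)):
        raise AssertionError("fold test sets overlap")
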