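"""End-to-end experiment orchestration.

The full hybrid pipeline on a cohort of volumes:

1. window the intensities and crop the slice range of interest;
2. run the marker-seeded variational segmentation once, on a single
   reference volume (the only interactive step);
3. propagate that saved segmentation onto every other volume by
   registration, giving each an *estimated* segmentation;
4. refine the estimates of unlabelled volumes variationally to obtain
   pseudo-labels;
5. train the refinement network — ``hybrid`` (scan + estimate channels,
   semi-supervised) or ``standard`` (scan only, supervised) — and run
   inference on the held-out test volumes;
6. evaluate everything against ground truth (Dice/Jaccard/VS/HD/TPR/TNR,
   per class and for the class union).

``run_benchmark`` executes this on a synthetic phantom cohort whose split
sizes follow the study design (50 labelled at 60:20:20 → 30/10/10, plus 20
unlabelled volumes giving a 50-volume training pool) and emits a
three-column comparison — variational-only / standard / hybrid — plus the
raw propagated-estimate scores.  ``reduced_data_experiment`` retrains the
hybrid model at decreasing labelled fractions against the full-data
standard baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .grids import LabelMask, Volume
from .metrics import evaluate_cohort
from .phantom import PhantomSpec, generate_cohort
from .registration import make_estimates
from .training import TrainConfig, TrainingExample, infer, make_split, train
from .variational import MarkerSet, VariationalParams, segment_multiclass

__all__ = [
    "window_and_crop",
    "markers_from_mask",
    "refine_estimate",
    "BenchmarkConfig",
    "run_benchmark",
    "reduced_data_experiment",
    "config_hash",
]

LABEL_NAMES = {1: "thrombus", 2: "stent_lumen"}


def window_and_crop(
    volume: Volume,
    window: tuple[float, float] = (0.0, 1.0),
    slice_range: tuple[int, int] | None = None,
) -> Volume:
    """Clip intensities to [low, high], rescale to [0, 1], crop z-slices.

    ``slice_range`` is inclusive on both ends, 0-based, along the first (z)
    axis — the uppermost and lowermost slice retained.  Windowing is
    idempotent: a second application with the same window maps [0,1] onto
    itself.
    """
    low, high = window
    if not low < high:
        raise ValueError(f"window low must be < high, got {window}")
    data = (np.clip(volume.data, low, high) - low) / (high - low)
    if slice_range is not None:
        top, bottom = slice_range
        if not (0 <= top <= bottom < volume.shape[0]):
            raise ValueError(f"slice_range {slice_range} invalid for {volume.shape[0]} slices")
        data = data[top : bottom + 1]
    return Volume(data, volume.spacing, "normalized")


def markers_from_mask(
    mask: LabelMask, label: int, n: int = 3, rng: np.random.Generator | None = None
) -> MarkerSet:
    """Deterministically sample interior seed points of one labelled region.

    Stands in for interactive marker placement: points are drawn
    from the deepest interior of the region (top decile of the distance
    transform), spread by a seeded shuffle.
    """
    rng = rng or np.random.default_rng(0)
    binary = mask.binary(label)
    if not binary.any():
        raise ValueError(f"label {label} absent from mask")
    depth = ndimage.distance_transform_edt(binary, sampling=mask.spacing)
    cutoff = np.percentile(depth[binary], 90)
    candidates = np.argwhere(depth >= max(cutoff, depth.max() * 0.5))
    order = rng.permutation(len(candidates))
    picks = candidates[order[: max(n, 1)]]
    return MarkerSet(inside=[tuple(int(c) for c in p) for p in picks])


def refine_estimate(
    volume: Volume,
    estimate: LabelMask,
    params: VariationalParams | None = None,
    rng: np.random.Generator | None = None,
) -> LabelMask:
    """Variational segmentation seeded by an estimated mask (no user markers).

    Markers are sampled from the interior of each estimated class, so the
    variational stage can be applied to volumes that were never manually
    seeded — this is how unlabelled volumes receive their pseudo-labels.
    """
    rng = rng or np.random.default_rng(0)
    markers = markers_from_estimate(volume, estimate, rng)
    if not markers:
        raise ValueError("estimate contains no foreground to seed from")
    refined, _ = segment_multiclass(volume, markers, params)
    return refined


def markers_from_estimate(
    volume: Volume, estimate: LabelMask, rng: np.random.Generator
) -> dict[int, MarkerSet]:
    """Per-class seed points derived from an estimated mask.

    Candidates come from the deep interior of each estimated class; since an
    estimate is allowed to be wrong in places, candidates whose intensity
    disagrees with the group's median are dropped before they are trusted.
    """
    markers: dict[int, MarkerSet] = {}
    for lab in estimate.labels:
        try:
            candidates = markers_from_mask(estimate, lab, n=7, rng=rng)
        except ValueError:
            continue
        vals = np.array([volume.data[m] for m in candidates.inside])
        order = np.argsort(np.abs(vals - np.median(vals)), kind="stable")
        keep = [candidates.inside[i] for i in order[: max(3, len(order) // 2)]]
        markers[lab] = MarkerSet(inside=keep)
    return markers


@dataclass
class BenchmarkConfig:
    """Synthetic-cohort study conditions and desk-scale solver settings.

    The cohort design mirrors the study: 50 labelled volumes split 60:20:20
    into 30 train / 10 validation / 10 test, plus 20 unlabelled volumes that
    enter training with pseudo-labels (a 50-volume training pool).
    """

    n_labelled: int = 50
    n_unlabelled: int = 20
    ratio: tuple[int, int, int] = (60, 20, 20)
    seed: int = 7
    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(
            grid_shape=(24, 24, 24),
            spacing=(1.0, 1.0, 1.0),
            task="aneurysm",
            lumen_radius_mm=2.8,
            thrombus_outer_radius_mm=6.0,
            centerline_amplitude_mm=1.0,
            boundary_contrast=0.15,
            noise_sigma=0.05,
            dropout_fraction=0.4,
            texture_amplitude=0.03,
            n_distractors=0,
            spine=False,
        )
    )
    jitter: dict = field(
        default_factory=lambda: {
            "lumen_radius_mm": (2.4, 3.2),
            "thrombus_outer_radius_mm": (4.5, 6.0),
            "centerline_amplitude_mm": (0.5, 1.5),
            "center_offset_y_mm": (-3.0, 3.0),
            "center_offset_x_mm": (-3.0, 3.0),
            "ellipse_ratio": (0.75, 1.35),
            "ellipse_angle_rad": (0.0, 3.14159),
            "wobble_cycles": (0.5, 2.0),
            "wobble_phase_rad": (0.0, 6.28318),
            "boundary_contrast": (0.10, 0.20),
            "dropout_fraction": (0.2, 0.6),
        }
    )
    window: tuple[float, float] = (0.0, 1.0)
    registration_mode: str = "affine"
    variational: VariationalParams = field(
        default_factory=lambda: VariationalParams(
            max_iters=150, lambda_intensity=0.5, mu_distance=0.3
        )
    )
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            mode="hybrid",
            n_classes=3,
            epochs=14,
            batch_size=2,
            patch_size=24,
            learning_rate=2e-3,
            base_width=8,
            pseudo_label_weight=0.5,
            patience=12,
        )
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        return d


def config_hash(config: BenchmarkConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class BenchmarkContext:
    """Everything upstream of network training, reusable across trainings."""

    volumes: list[Volume]
    truths: list[LabelMask]
    split: object
    estimates: list[LabelMask]  # one per cohort volume, propagated from the reference
    pseudo: dict[int, LabelMask]  # unlabelled id -> variationally refined pseudo-label
    reference_id: int
    reference_mask: LabelMask


def prepare_benchmark(config: BenchmarkConfig) -> BenchmarkContext:
    """Stages 1-4: simulate, window, segment the reference, propagate, pseudo-label."""
    n_total = config.n_labelled + config.n_unlabelled
    cohort = generate_cohort(n_total, config.phantom, config.jitter, seed=config.seed)
    volumes = [window_and_crop(p.volume, config.window) for p in cohort]
    truths = [p.truth for p in cohort]

    labelled_ids = list(range(config.n_labelled))
    unlabelled_ids = list(range(config.n_labelled, n_total))
    split = make_split(labelled_ids, unlabelled_ids, config.ratio, seed=config.seed)

    # the single interactive step: marker-seeded variational run on one
    # reference volume (markers stand in for the manual seeds)
    ref_id = split.train[0]
    rng = np.random.default_rng(config.seed + 101)
    markers = {
        lab: markers_from_mask(truths[ref_id], lab, n=3, rng=rng)
        for lab in truths[ref_id].labels
    }
    ref_mask, _ = segment_multiclass(volumes[ref_id], markers, config.variational)

    estimates = make_estimates(
        volumes, (volumes[ref_id], ref_mask), mode=config.registration_mode
    )

    pseudo = {}
    for uid in unlabelled_ids:
        rng_u = np.random.default_rng(config.seed + 1000 + uid)
        pseudo[uid] = refine_estimate(
            volumes[uid], estimates[uid], config.variational, rng_u
        )
    return BenchmarkContext(
        volumes=volumes,
        truths=truths,
        split=split,
        estimates=estimates,
        pseudo=pseudo,
        reference_id=ref_id,
        reference_mask=ref_mask,
    )


def _examples(ctx: BenchmarkContext, ids, targets: str, config: TrainConfig):
    out = []
    for i in ids:
        if targets == "manual":
            tgt, sup = ctx.truths[i], "manual"
        else:
            tgt, sup = ctx.pseudo[i], "pseudo"
        est = ctx.estimates[i] if config.mode == "hybrid" else None
        out.append(TrainingExample(ctx.volumes[i], tgt, est, sup))
    return out


def train_and_eval(
    ctx: BenchmarkContext,
    mode: str,
    config: BenchmarkConfig,
    labelled_fraction: float = 1.0,
    seed: int | None = None,
):
    """Train one network variant and score it on the held-out test volumes.

    ``standard`` trains supervised on the labelled volumes only (scan as sole
    input); ``hybrid`` additionally consumes the estimate channels and the
    pseudo-labelled pool.  ``labelled_fraction`` < 1 drops labelled training
    volumes (floor), keeping the pseudo pool intact.
    """
    if not (0.0 < labelled_fraction <= 1.0):
        raise ValueError("labelled_fraction must lie in (0, 1]")
    n_keep = int(np.floor(labelled_fraction * len(ctx.split.train)))
    if n_keep == 0:
        raise ValueError("labelled_fraction leaves no labelled training volumes")
    train_ids = list(ctx.split.train)[:n_keep]

    tcfg = dataclasses.replace(config.train, mode=mode)
    if seed is not None:
        tcfg = dataclasses.replace(tcfg, rng_seed=seed)

    examples = _examples(ctx, train_ids, "manual", tcfg)
    if mode == "hybrid":
        examples += _examples(ctx, sorted(ctx.pseudo), "pseudo", tcfg)
    val_examples = _examples(ctx, ctx.split.val, "manual", tcfg)

    model, log = train(examples, val_examples, tcfg)

    preds = []
    for i in ctx.split.test:
        est = ctx.estimates[i] if mode == "hybrid" else None
        preds.append(infer(model, ctx.volumes[i], est, tcfg)[1])
    refs = [ctx.truths[i] for i in ctx.split.test]
    per_case, summary = evaluate_cohort(preds, refs, [1, 2], LABEL_NAMES, "whole_aneurysm")
    return model, log, per_case, summary


def _vm_only_and_estimate_rows(ctx: BenchmarkContext, config: BenchmarkConfig):
    refs = [ctx.truths[i] for i in ctx.split.test]
    est_preds = [ctx.estimates[i] for i in ctx.split.test]
    vm_preds = []
    for i in ctx.split.test:
        rng = np.random.default_rng(config.seed + 2000 + i)
        vm_preds.append(
            refine_estimate(ctx.volumes[i], ctx.estimates[i], config.variational, rng)
        )
    vm = evaluate_cohort(vm_preds, refs, [1, 2], LABEL_NAMES, "whole_aneurysm")
    est = evaluate_cohort(est_preds, refs, [1, 2], LABEL_NAMES, "whole_aneurysm")
    return vm, est


def run_benchmark(config: BenchmarkConfig | None = None) -> dict:
    """Full synthetic benchmark; returns a JSON-serializable report.

    The report carries, for each method column (variational-only, propagated
    estimate, standard, hybrid), per-case metrics and mean ± sd / median
    (range) summaries per region, plus provenance (config hash, seed,
    package version) so a re-run with the same config reproduces it
    bit-identically.
    """
    config = config or BenchmarkConfig()
    ctx = prepare_benchmark(config)
    report: dict = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "version": __version__,
        },
        "split": {
            "train": list(ctx.split.train),
            "val": list(ctx.split.val),
            "test": list(ctx.split.test),
            "unlabelled": list(ctx.split.unlabelled),
            "training_pool_size": ctx.split.training_pool_size,
        },
        "methods": {},
    }

    (vm_pc, vm_sum), (est_pc, est_sum) = _vm_only_and_estimate_rows(ctx, config)
    report["methods"]["vm_only"] = _method_entry(vm_pc, vm_sum)
    report["methods"]["estimate"] = _method_entry(est_pc, est_sum)

    for mode in ("standard", "hybrid"):
        _, log, per_case, summary = train_and_eval(ctx, mode, config)
        report["methods"][mode] = _method_entry(per_case, summary)
        report["methods"][mode]["training_log"] = log.to_dict("records")
    return report


def _method_entry(per_case: pd.DataFrame, summary: pd.DataFrame) -> dict:
    return {
        "per_case": json.loads(per_case.to_json(orient="records")),
        "summary": json.loads(summary.to_json(orient="records")),
    }


def mean_dice(report_entry: dict, region: str = "whole_aneurysm") -> float:
    for row in report_entry["summary"]:
        if row["region"] == region:
            return row["dice_mean"]
    raise KeyError(region)


def reduced_data_experiment(
    config: BenchmarkConfig | None = None,
    labelled_fractions=(1.0, 2.0 / 3.0, 1.0 / 3.0),
    seeds=(0,),
) -> pd.DataFrame:
    """Hybrid performance vs labelled-data fraction, against full-data standard.

    Retrains the hybrid model at each fraction (and seed), reusing the
    simulated cohort, estimates and pseudo-labels; emits mean test Dice per
    region alongside the full-data standard baseline.  The monotone trend is
    reported, not enforced.
    """
    config = config or BenchmarkConfig()
    for f in labelled_fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must lie in (0,1], got {f}")
    ctx = prepare_benchmark(config)
    rows = []
    for seed in seeds:
        _, _, _, std_sum = train_and_eval(ctx, "standard", config, 1.0, seed=seed)
        for region_row in std_sum.to_dict("records"):
            rows.append(
                {
                    "method": "standard",
                    "labelled_fraction": 1.0,
                    "seed": seed,
                    "region": region_row["region"],
                    "dice_mean": region_row["dice_mean"],
                }
            )
        for f in sorted(labelled_fractions, reverse=True):
            _, _, _, sumdf = train_and_eval(ctx, "hybrid", config, f, seed=seed)
            for region_row in sumdf.to_dict("records"):
                rows.append(
                    {
                        "method": "hybrid",
                        "labelled_fraction": f,
                        "seed": seed,
                        "region": region_row["region"],
                        "dice_mean": region_row["dice_mean"],
                    }
                )
    return pd.DataFrame(rows)
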