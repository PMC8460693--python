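"""End-to-end experiment orchestration and the modelling facade.

The workflow mirrors the clinical study on synthetic phantoms: simulate a
cohort, split it 48%/12%/40% into training/validation/test (stratified by
case label, respecting case order as the temporal-split analogue), train the
3-D U-net on patches, predict the test cases, run the HU-threshold baseline,
and evaluate voxel-, region- and case-level performance with case-resampled
bootstrap confidence intervals.

The public surface follows the model/results idiom: build a
:class:`HypoperfusionSegmenter` from the training and validation cases, call
``fit()`` to obtain a :class:`SegmentationResults`, then ``predict`` volumes
or ``evaluate`` a test set to get an :class:`EvaluationReport` with a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import regions as _regions
from .model import TrainConfig, TrainingHistory, build_unet, predict_volume, train
from .nn.network import UNetConfig
from .phantom import PhantomCase, PhantomConfig, generate_cohort
from .preprocess import normalize_hu, resample_isotropic
from .volio import BinaryMask, CTVolume, ProbabilityMap

__all__ = [
    "PreparedCase",
    "ExperimentConfig",
    "EvaluationReport",
    "HypoperfusionSegmenter",
    "SegmentationResults",
    "split_cohort",
    "prepare_case",
    "evaluate_methods",
    "run_experiment",
    "default_small_config",
]


# --------------------------------------------------------------------------
# case preparation and cohort splitting


@dataclass
class PreparedCase:
    """A case resampled to the working grid, in both HU and normalized form."""

    case_id: str
    is_positive: bool
    hu: CTVolume
    volume: CTVolume  # normalized intensities (network input)
    lung_mask: BinaryMask
    lesion_mask: BinaryMask


def prepare_case(case: PhantomCase, target_mm: float = 1.0) -> PreparedCase:
    hu = resample_isotropic(case.volume, target_mm)
    lung = resample_isotropic(case.lung_mask, target_mm)
    lesion = resample_isotropic(case.lesion_mask, target_mm)
    return PreparedCase(
        case_id=case.case_id,
        is_positive=case.is_positive,
        hu=hu,
        volume=normalize_hu(hu),
        lung_mask=lung,
        lesion_mask=lesion,
    )


def split_cohort(cases, fractions=(0.48, 0.12, 0.40)):
    """Stratified train/validation/test split respecting case order.

    Per class, partition sizes are ``round(fraction * class_size)`` (half up)
    with any remainder assigned to the earliest partition; the first cases of
    each class go to training (the temporal-split analogue -- phantoms have
    no acquisition dates, so case index order stands in).  A 25+25 cohort at
    the default fractions yields 12/3/10 cases per class.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("need exactly three fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    splits = ([], [], [])
    for label in (True, False):
        group = [c for c in cases if bool(c.is_positive) == label]
        if not group:
            continue
        n = len(group)
        counts = [int(np.floor(f * n + 0.5)) for f in fractions]
        counts[0] += n - sum(counts)
        if any(c < 1 for c in counts):
            raise ValueError(
                f"class with {n} cases yields an empty partition: {counts}"
            )
        lo = 0
        for part, c in zip(splits, counts):
            part.extend(group[lo : lo + c])
            lo += c
    if not any(len(s) for s in splits):
        raise ValueError("no cases to split")
    return splits


# --------------------------------------------------------------------------
# configuration


def _default_experiment_unet() -> UNetConfig:
    # one-level net with margin 6: sized for CPU training on 64-cube phantoms
    return UNetConfig(
        levels=1,
        filters_per_level=(8,),
        bottleneck_filters=16,
        encoder_convs=(2,),
        bottleneck_convs=1,
        decoder_convs=(1,),
        margin=6,
        output_bias=-1.4,  # logit of the ~20% lesion prevalence
    )


def _default_experiment_train() -> TrainConfig:
    return TrainConfig(
        learning_rate=7e-3,
        batch_size=8,
        max_epochs=10,
        patience=10,
        patch=16,
        margin=6,
        patches_per_case=48,
        lesion_oversample=0.5,
        input_clip=2.0,
        lr_final_fraction=0.1,
        val_patches_per_case=64,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_positive: int = 9
    n_negative: int = 9
    fractions: tuple[float, float, float] = (5 / 9, 1 / 9, 3 / 9)
    resample_mm: float = 2.0
    unet: UNetConfig = field(default_factory=_default_experiment_unet)
    train: TrainConfig = field(default_factory=_default_experiment_train)
    n_resamples: int = 2000
    ci_level: float = 0.95
    case_cutoff: float = 0.55
    baseline_threshold_hu: float = -850.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_small_config() -> ExperimentConfig:
    """The scaled-down study conditions used throughout the test battery:
    a 9+9 cohort of 64-cube phantoms at 2 mm spacing split 5/1/3 per class
    (10 train / 2 validation / 6 test cases)."""
    return ExperimentConfig()


# --------------------------------------------------------------------------
# modelling facade


class HypoperfusionSegmenter:
    """Patch-based 3-D U-net model of parenchymal hypoperfusion.

    Built from training and validation cases (anything exposing ``volume``
    normalized, ``lung_mask`` and ``lesion_mask``); ``fit()`` trains the
    network and returns a :class:`SegmentationResults`.
    """

    def __init__(
        self,
        train_cases,
        val_cases,
        unet_config: UNetConfig | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ):
        self.train_cases = list(train_cases)
        self.val_cases = list(val_cases)
        self.unet_config = unet_config if unet_config is not None else UNetConfig()
        self.train_config = (
            train_config if train_config is not None else TrainConfig()
        )
        self.seed = int(seed)

    @classmethod
    def from_cohort(
        cls,
        cases,
        fractions=(0.48, 0.12, 0.40),
        unet_config=None,
        train_config=None,
        seed: int = 0,
    ):
        """Split a prepared cohort and return (model, test_cases)."""
        tr, va, te = split_cohort(cases, fractions)
        return cls(tr, va, unet_config, train_config, seed=seed), te

    def fit(self) -> "SegmentationResults":
        ss = np.random.SeedSequence(self.seed).generate_state(2) % (2**31)
        net = build_unet(self.unet_config, seed=int(ss[0]))
        tcfg = dataclasses.replace(self.train_config, seed=int(ss[1]))
        history = train(net, self.train_cases, self.val_cases, tcfg)
        return SegmentationResults(self, net, history)


class SegmentationResults:
    """Trained network plus training history; prediction and evaluation
    hang off this object."""

    def __init__(self, model: HypoperfusionSegmenter, net, history: TrainingHistory):
        self.model = model
        self.net = net
        self.history = history

    def predict(self, case: PreparedCase) -> ProbabilityMap:
        return predict_volume(
            self.net,
            case.volume,
            case.lung_mask,
            patch=self.model.train_config.patch,
            margin=self.net.margin,
            input_clip=self.model.train_config.input_clip,
        )

    def evaluate(self, test_cases, config: ExperimentConfig | None = None, seed: int = 0):
        cfg = config if config is not None else ExperimentConfig()
        prob_maps = [self.predict(c) for c in test_cases]
        return evaluate_methods(test_cases, prob_maps, cfg, seed=seed)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Hypoperfusion segmentation model",
            "=" * 40,
            f"epochs run           {h.stopped_epoch + 1}",
            f"best epoch           {h.best_epoch + 1}",
            f"final train loss     {h.train_loss[-1]:.4f}",
            f"best val metric      {max(h.val_metric):.4f}",
            f"train cases          {len(self.model.train_cases)}",
            f"validation cases     {len(self.model.val_cases)}",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# evaluation


def _auc_from_hists(pos: np.ndarray, neg: np.ndarray) -> float:
    """Trapezoidal AUC from class histograms on a shared ascending score grid."""
    n_pos, n_neg = pos.sum(), neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise _metrics.UndefinedStatisticError("single-class resample")
    # descending-score cumulative rates
    tpr = np.concatenate([[0.0], np.cumsum(pos[::-1]) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(neg[::-1]) / n_neg])
    return float(np.trapezoid(tpr, fpr))


@dataclass
class _CaseEval:
    """Per-case quantities carried into the bootstrap."""

    case_id: str
    is_positive: bool
    counts_cnn: _metrics.ConfusionCounts
    counts_base: _metrics.ConfusionCounts
    hist_pos_cnn: np.ndarray
    hist_neg_cnn: np.ndarray
    hist_pos_base: np.ndarray
    hist_neg_base: np.ndarray


def _pooled_counts(cases, attr) -> _metrics.ConfusionCounts:
    total = _metrics.ConfusionCounts(0, 0, 0, 0)
    for c in cases:
        total = total + getattr(c, attr)
    return total


def _mcc_statistic(attr):
    def stat(cases):
        c = _pooled_counts(cases, attr)
        if (c.tp + c.fn) == 0 or (c.tn + c.fp) == 0:
            raise _metrics.UndefinedStatisticError("single-class resample")
        return _metrics.mcc(c)

    return stat


def _auc_statistic(pos_attr, neg_attr):
    def stat(cases):
        pos = sum(getattr(c, pos_attr) for c in cases)
        neg = sum(getattr(c, neg_attr) for c in cases)
        return _auc_from_hists(pos, neg)

    return stat


@dataclass
class EvaluationReport:
    """Voxel, region and case-level evaluation of both methods."""

    methods: dict
    mcc_difference: dict
    regions: dict
    cases: list
    training: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    #: ROC curves keyed by method name; attached by evaluate_methods, kept
    #: out of the dataclass fields so JSON serialization stays plain
    roc_curves = None

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    def plot_roc(self, ax=None):
        """Plot both methods' pooled ROC curves (requires matplotlib)."""
        if self.roc_curves is None:
            raise ValueError("this report carries no ROC curves")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        labels = {"cnn": "CNN", "hu_threshold": "HU threshold"}
        for key, roc in self.roc_curves.items():
            ax.plot(roc.fpr, roc.tpr, label=f"{labels.get(key, key)} (AUC {roc.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax

    def case_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.cases)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(self.to_json())
        self.case_table().to_csv(out_dir / "cases.csv", index=False)

    def summary(self) -> str:
        m = self.methods
        rows = [
            ("AUC", "auc"),
            ("optimal threshold", "optimal_threshold"),
            ("balanced accuracy", "balanced_accuracy"),
            ("MCC", "mcc"),
        ]
        lines = [
            "Voxel-level test performance (pooled over cases)",
            "=" * 56,
            f"{'':24s}{'CNN':>14s}{'HU threshold':>16s}",
        ]
        for label, key in rows:
            lines.append(
                f"{label:24s}{m['cnn'][key]:>14.4g}{m['hu_threshold'][key]:>16.4g}"
            )
        d = self.mcc_difference
        lines += [
            "-" * 56,
            (
                f"MCC difference (CNN - HU): {d['point']:.4f} "
                f"[{d['ci_low']:.4f}, {d['ci_high']:.4f}] "
                f"({'significant' if d['significant'] else 'not significant'})"
            ),
            (
                f"regions: TP {self.regions['n_true_positive']} / "
                f"FP {self.regions['n_false_positive']} / "
                f"FN {self.regions['n_false_negative']}"
            ),
            f"test cases: {len(self.cases)} "
            f"({sum(1 for c in self.cases if c['call_correct'])} case calls correct)",
        ]
        return "\n".join(lines)


def evaluate_methods(
    test_cases,
    prob_maps,
    cfg: ExperimentConfig | None = None,
    seed: int = 0,
    n_bins: int = 512,
) -> EvaluationReport:
    """Full evaluation of CNN probability maps against the HU baseline.

    Voxels are pooled across test cases for the ROC curves; the optimal
    threshold of each method maximises pooled balanced accuracy; MCC and AUC
    confidence intervals come from the case-resampled percentile bootstrap
    (AUC via per-case score histograms on a fixed grid).
    """
    cfg = cfg if cfg is not None else ExperimentConfig()
    if len(test_cases) != len(prob_maps):
        raise ValueError("one probability map per test case required")

    cnn_scores, base_scores, truths = [], [], []
    for case, pmap in zip(test_cases, prob_maps):
        lung = case.lung_mask.data
        cnn_scores.append(pmap.data[lung])
        base_scores.append(-np.asarray(case.hu.data, dtype=np.float64)[lung])
        truths.append(case.lesion_mask.data[lung])
    pooled_cnn = np.concatenate(cnn_scores)
    pooled_base = np.concatenate(base_scores)
    pooled_truth = np.concatenate(truths)

    roc_cnn = _metrics.roc_curve(pooled_cnn, pooled_truth)
    roc_base = _metrics.roc_curve(pooled_base, pooled_truth)
    thr_cnn, bal_cnn = _metrics.optimal_threshold(pooled_cnn, pooled_truth)
    thr_base, bal_base = _metrics.optimal_threshold(pooled_base, pooled_truth)

    # histogram grids for the bootstrap AUC (binned, shared per method)
    edges_cnn = np.linspace(0.0, 1.0, n_bins + 1)
    lo, hi = float(pooled_base.min()), float(pooled_base.max())
    edges_base = np.linspace(lo, hi + 1e-9, n_bins + 1)

    case_evals: list[_CaseEval] = []
    region_tp = region_fp = region_fn = 0
    case_rows = []
    for case, pmap, sc_cnn, sc_base, tr in zip(
        test_cases, prob_maps, cnn_scores, base_scores, truths
    ):
        counts_cnn = _confusion_from_scores(sc_cnn, tr, thr_cnn)
        counts_base = _confusion_from_scores(sc_base, tr, thr_base)
        case_evals.append(
            _CaseEval(
                case_id=case.case_id,
                is_positive=case.is_positive,
                counts_cnn=counts_cnn,
                counts_base=counts_base,
                hist_pos_cnn=np.histogram(sc_cnn[tr], bins=edges_cnn)[0],
                hist_neg_cnn=np.histogram(sc_cnn[~tr], bins=edges_cnn)[0],
                hist_pos_base=np.histogram(sc_base[tr], bins=edges_base)[0],
                hist_neg_base=np.histogram(sc_base[~tr], bins=edges_base)[0],
            )
        )
        pred_mask = BinaryMask(
            _mask_from_scores(pmap.data, case.lung_mask.data, thr_cnn),
            case.lung_mask.spacing,
        )
        match = _regions.match_regions(pred_mask, case.lesion_mask, case.lung_mask)
        region_tp += match.n_true_positive_regions
        region_fp += match.n_false_positive_regions
        region_fn += match.n_false_negative_regions
        call, mean_prob = _regions.classify_case(pmap, case.lung_mask, cfg.case_cutoff)
        hu_sum = _regions.case_hu_summary(case.hu, case.lung_mask, cfg.baseline_threshold_hu)
        case_rows.append(
            {
                "case_id": case.case_id,
                "is_positive": case.is_positive,
                "mean_cnn_probability": mean_prob,
                "cnn_case_call": call,
                "call_correct": call == case.is_positive,
                "lung_fraction_below_threshold": hu_sum.fraction_below,
                "mean_hu_below_threshold": hu_sum.mean_hu_below,
                "mean_lung_hu": hu_sum.mean_lung_hu,
                "region_tp": match.n_true_positive_regions,
                "region_fp": match.n_false_positive_regions,
                "region_fn": match.n_false_negative_regions,
            }
        )

    seeds = np.random.SeedSequence(seed).generate_state(5) % (2**31)
    mcc_cnn_ci = _metrics.bootstrap_ci(
        case_evals, _mcc_statistic("counts_cnn"), cfg.n_resamples, cfg.ci_level, int(seeds[0])
    )
    mcc_base_ci = _metrics.bootstrap_ci(
        case_evals, _mcc_statistic("counts_base"), cfg.n_resamples, cfg.ci_level, int(seeds[1])
    )
    mcc_diff = _metrics.paired_difference_ci(
        case_evals,
        _mcc_statistic("counts_cnn"),
        _mcc_statistic("counts_base"),
        cfg.n_resamples,
        cfg.ci_level,
        int(seeds[2]),
    )
    auc_cnn_ci = _metrics.bootstrap_ci(
        case_evals,
        _auc_statistic("hist_pos_cnn", "hist_neg_cnn"),
        cfg.n_resamples,
        cfg.ci_level,
        int(seeds[3]),
    )
    auc_base_ci = _metrics.bootstrap_ci(
        case_evals,
        _auc_statistic("hist_pos_base", "hist_neg_base"),
        cfg.n_resamples,
        cfg.ci_level,
        int(seeds[4]),
    )

    pooled_cnn_counts = _pooled_counts(case_evals, "counts_cnn")
    pooled_base_counts = _pooled_counts(case_evals, "counts_base")

    methods = {
        "cnn": {
            "auc": roc_cnn.auc,
            "auc_ci": auc_cnn_ci.as_dict(),
            "optimal_threshold": thr_cnn,
            "balanced_accuracy": bal_cnn,
            "mcc": _metrics.mcc(pooled_cnn_counts),
            "mcc_ci": mcc_cnn_ci.as_dict(),
        },
        "hu_threshold": {
            "auc": roc_base.auc,
            "auc_ci": auc_base_ci.as_dict(),
            # baseline scores are negated HU: threshold t on score = -t HU
            "optimal_threshold": thr_base,
            "optimal_threshold_hu": -thr_base,
            "balanced_accuracy": bal_base,
            "mcc": _metrics.mcc(pooled_base_counts),
            "mcc_ci": mcc_base_ci.as_dict(),
        },
    }
    report = EvaluationReport(
        methods=methods,
        mcc_difference=mcc_diff.as_dict(),
        regions={
            "n_true_positive": region_tp,
            "n_false_positive": region_fp,
            "n_false_negative": region_fn,
        },
        cases=case_rows,
    )
    report.roc_curves = {"cnn": roc_cnn, "hu_threshold": roc_base}
    return report


def _confusion_from_scores(scores, truth, threshold) -> _metrics.ConfusionCounts:
    pred = scores >= threshold
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return _metrics.ConfusionCounts(tp, fp, fn, tn)


def _mask_from_scores(prob_data, lung_data, threshold) -> np.ndarray:
    return lung_data & (prob_data >= threshold)


# --------------------------------------------------------------------------
# full pipeline


def run_experiment(
    cfg: ExperimentConfig | None = None, seed: int = 0, out_dir=None
) -> EvaluationReport:
    """simulate -> split -> train -> predict + baseline -> evaluate.

    A single master seed fans out (via ``numpy.random.SeedSequence``) to the
    phantom cohort, network initialization, patch sampling/shuffling and the
    bootstrap, so the whole run is reproducible from one integer.
    """
    cfg = cfg if cfg is not None else default_small_config()
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)

    cohort = generate_cohort(cfg.phantom, cfg.n_positive, cfg.n_negative, int(seeds[0]))
    prepared = [prepare_case(c, cfg.resample_mm) for c in cohort]
    train_cases, val_cases, test_cases = split_cohort(prepared, cfg.fractions)
    if not test_cases:
        raise ValueError("split produced no test cases")

    segmenter = HypoperfusionSegmenter(
        train_cases, val_cases, cfg.unet, cfg.train, seed=int(seeds[1])
    )
    results = segmenter.fit()
    report = results.evaluate(test_cases, cfg, seed=int(seeds[2]))
    report.training = {
        "epochs_run": results.history.stopped_epoch + 1,
        "best_epoch": results.history.best_epoch,
        "train_loss": results.history.train_loss,
        "val_metric": results.history.val_metric,
    }
    report.config = {"seed": int(seed), **cfg.to_dict()}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.save(out_dir)
        (out_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
        results.net.save(out_dir / "model.npz")
    return report
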