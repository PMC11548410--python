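"""Five-fold cross-validated synthetic-augmentation ratio sweep.

For each fold of a stratified 5-fold split over the real trials, a
conditional GAN is trained on the fold's real training portion only (so no
information from the held-out trials can leak through synthetic samples),
the training set is augmented at each real:synthetic ratio (Real Only, 2:1,
1:1, 2:3, 1:2), a fresh FCN classifier is trained per condition, and the
held-out real trials are scored. Metrics (support-weighted precision,
recall, F1, and accuracy) are aggregated as across-fold mean +/- SD.
Support-weighted recall equals accuracy identically, which doubles as an
internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import FcnTaskClassifier, predict_confusion
from .gan import SpectralCGAN
from .trials import Dataset


@dataclass(frozen=True)
class AugmentationRatio:
    """Real:synthetic mixing ratio for the training set."""

    real_part: int
    synth_part: int

    def __post_init__(self) -> None:
        if self.real_part <= 0 or self.synth_part < 0:
            raise ValueError("real_part must be positive and synth_part nonnegative")

    @property
    def name(self) -> str:
        if self.synth_part == 0:
            return "Real Only"
        return f"{self.real_part}:{self.synth_part}"

    @classmethod
    def parse(cls, text: str) -> "AugmentationRatio":
        text = text.strip()
        if text.lower() in ("real", "real only", "real_only"):
            return cls(1, 0)
        r, s = text.split(":")
        return cls(int(r), int(s))


#: The five training-set compositions of the ratio sweep.
DEFAULT_RATIOS: tuple[AugmentationRatio, ...] = (
    AugmentationRatio(1, 0),
    AugmentationRatio(2, 1),
    AugmentationRatio(1, 1),
    AugmentationRatio(2, 3),
    AugmentationRatio(1, 2),
)


def synth_count(n_real_train: int, ratio: AugmentationRatio) -> int:
    """Number of synthetic trials matching a real:synthetic ratio."""
    if n_real_train < 0:
        raise ValueError("n_real_train must be nonnegative")
    if ratio.synth_part == 0:
        return 0
    return int(round(n_real_train * ratio.synth_part / ratio.real_part))


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total``, proportional to ``quotas``."""
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Class-stratified k-fold partition of indices.

    Within each class, shuffled indices are dealt round-robin starting at a
    random fold offset, so per-fold class counts differ by at most 1.
    Classes with fewer than k members are still dealt (some folds simply
    miss them). Deterministic given the seed.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        offset = int(rng.integers(k))
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def augment_training_set(
    real_train: Dataset,
    gan: SpectralCGAN,
    ratio: AugmentationRatio,
    rng: np.random.Generator | int | None = None,
    lowpass: bool = True,
) -> Dataset:
    """Real training trials plus GAN samples at the requested ratio.

    Synthetic counts are allocated per class proportionally to the real
    class counts (largest-remainder rounding) and pass the 2 Hz lowpass
    before joining the training set. Real Only returns the input unchanged.
    """
    n_synth = synth_count(len(real_train), ratio)
    if n_synth == 0:
        return real_train
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = real_train.labels
    present, counts = np.unique(labels, return_counts=True)
    missing = sorted(set(present) - set(gan.classes_))
    if missing:
        raise ValueError(f"GAN was not trained on classes {missing}")
    alloc = _largest_remainder(counts * n_synth / len(real_train), n_synth)
    out = real_train
    for cls, n_cls in zip(present, alloc):
        if n_cls > 0:
            out = out.extend(gan.sample_trials(int(cls), int(n_cls), rng=rng, lowpass=lowpass))
    return out


def compute_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Support-weighted precision/recall/F1 and accuracy from a confusion
    count matrix (rows = true, columns = predicted).

    Classes never predicted contribute precision 0 (their labels are listed
    under ``zero_predicted``). Support-weighted recall equals accuracy by
    the identity sum_i n_i (c_ii / n_i) / N = trace / N.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1] or (conf < 0).any():
        raise ValueError("confusion must be a square nonnegative matrix")
    total = conf.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    support = conf.sum(axis=1)
    predicted = conf.sum(axis=0)
    diag = np.diag(conf).astype(float)
    precision_c = np.divide(diag, predicted, out=np.zeros_like(diag), where=predicted > 0)
    recall_c = np.divide(diag, support, out=np.zeros_like(diag), where=support > 0)
    pr_sum = precision_c + recall_c
    f1_c = np.divide(
        2 * precision_c * recall_c, pr_sum, out=np.zeros_like(diag), where=pr_sum > 0
    )
    weights = support / total
    return {
        "precision": float((weights * precision_c).sum()),
        "recall": float((weights * recall_c).sum()),
        "f1": float((weights * f1_c).sum()),
        "accuracy": float(diag.sum() / total),
        "zero_predicted": [int(i) for i in np.flatnonzero((predicted == 0) & (support > 0))],
    }


METRIC_NAMES = ("precision", "recall", "f1", "accuracy")


@dataclass
class MetricsReport:
    """Per-condition classification metrics with across-fold spread.

    ``fold_metrics`` maps condition name -> (k, 4) array in METRIC_NAMES
    order; ``confusions`` maps condition name -> summed confusion counts
    over test folds. The +/- values in the summary are across-fold standard
    deviations.
    """

    conditions: list[str]
    fold_metrics: dict[str, np.ndarray]
    confusions: dict[str, np.ndarray] = field(default_factory=dict)
    provenance_log: list[dict] = field(default_factory=list)

    def mean(self, condition: str) -> np.ndarray:
        return self.fold_metrics[condition].mean(axis=0)

    def sd(self, condition: str) -> np.ndarray:
        return self.fold_metrics[condition].std(axis=0, ddof=1)

    def accuracy(self, condition: str) -> float:
        return float(self.mean(condition)[METRIC_NAMES.index("accuracy")])

    def summary(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            mean, sd = self.mean(cond), self.sd(cond)
            row = {"condition": cond}
            for i, name in enumerate(METRIC_NAMES):
                row[name] = mean[i]
                row[f"{name}_sd"] = sd[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = ["condition      " + "  ".join(f"{m:>18s}" for m in METRIC_NAMES)]
        for cond in self.conditions:
            mean, sd = self.mean(cond), self.sd(cond)
            cells = "  ".join(
                f"{mean[i]:.3f} +/- {sd[i]:.3f}".rjust(18) for i in range(len(METRIC_NAMES))
            )
            lines.append(f"{cond:<15s}{cells}")
        return "\n".join(lines)


def run_experiment(
    real_dataset: Dataset,
    ratios: tuple[AugmentationRatio, ...] = DEFAULT_RATIOS,
    k: int = 5,
    seed: int = 0,
    gan_params: dict | None = None,
    fcn_params: dict | None = None,
    target: str = "task",
    gan_global: bool = False,
) -> MetricsReport:
    """The full cross-validated ratio sweep.

    Per fold: train the GAN on the real training portion (unless
    ``gan_global``, which mimics training it once on all real data and
    accepts the resulting leakage), build each ratio's training set from
    the same GAN bundle, train a classifier per condition, and evaluate on
    the held-out real trials only. ``target`` chooses the label space:
    "task" (10 classes, default) or "class" (all 30 codes). Bit-reproducible
    given the seed.
    """
    if any(t.provenance != "real" for t in real_dataset):
        raise ValueError("run_experiment expects a real-provenance dataset")
    gan_params = dict(gan_params or {})
    fcn_params = dict(fcn_params or {})
    if target not in ("task", "class"):
        raise ValueError("target must be 'task' or 'class'")

    ss = np.random.SeedSequence(seed)
    fold_seed, *stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(1 + 3 * k + 1)]
    folds = stratified_folds(real_dataset.labels, k=k, seed=fold_seed)

    global_gan = None
    if gan_global:
        global_gan = SpectralCGAN(random_state=stage_seeds[-1], **gan_params)
        global_gan.fit(real_dataset.signals(), real_dataset.labels)

    conditions = [r.name for r in ratios]
    fold_metrics = {c: np.zeros((k, len(METRIC_NAMES))) for c in conditions}
    confusions: dict[str, np.ndarray] = {}
    log: list[dict] = []

    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(len(real_dataset), dtype=bool)
        train_mask[test_idx] = False
        train_set = real_dataset.subset(train_mask)
        test_set = real_dataset.subset(test_idx)
        assert all(t.provenance == "real" for t in test_set)

        gan_seed, sample_seed, clf_seed = stage_seeds[3 * fi : 3 * fi + 3]
        if global_gan is not None:
            gan = global_gan
        else:
            gan = SpectralCGAN(random_state=gan_seed, **gan_params)
            gan.fit(train_set.signals(), train_set.labels)

        test_x = test_set.signals()
        test_y = test_set.task_labels if target == "task" else test_set.labels
        for ratio in ratios:
            sample_rng = np.random.default_rng([sample_seed, ratio.real_part, ratio.synth_part])
            augmented = augment_training_set(train_set, gan, ratio, rng=sample_rng)
            assert not any(t.provenance == "synthetic" for t in test_set)
            train_y = augmented.task_labels if target == "task" else augmented.labels
            clf = FcnTaskClassifier(random_state=clf_seed, **fcn_params)
            clf.fit(augmented.signals(), train_y)
            conf = predict_confusion(clf, test_x, test_y)
            metrics = compute_metrics(conf)
            fold_metrics[ratio.name][fi] = [metrics[m] for m in METRIC_NAMES]
            confusions[ratio.name] = confusions.get(ratio.name, 0) + conf
            log.append(
                {
                    "fold": fi,
                    "condition": ratio.name,
                    "n_real_train": len(train_set),
                    "n_synth": len(augmented) - len(train_set),
                    "n_test": len(test_set),
                    "gan_seed": gan_seed,
                    "clf_seed": clf_seed,
                    "accuracy": metrics["accuracy"],
                }
            )

    return MetricsReport(
        conditions=conditions,
        fold_metrics=fold_metrics,
        confusions=confusions,
        provenance_log=log,
    )
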