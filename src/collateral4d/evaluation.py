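"""Monte Carlo cross-validation, binary classification metrics, and
ROC/AUC aggregation with mean +/- SD reporting."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic import GOOD, POOR

__all__ = [
    "SplitPlan",
    "ConfusionCounts",
    "MetricsReport",
    "mc_splits",
    "confusion",
    "metrics",
    "roc_auc",
    "aggregate",
    "plot_roc",
]

#: common false-positive-rate grid for vertical ROC averaging
FPR_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class SplitPlan:
    iteration: int
    seed: int
    train_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets must be disjoint")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Per-iteration and aggregated classification performance."""

    per_iteration: list[dict]          # accuracy/precision/recall/f1/auc per split
    rocs: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per split
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    mean_roc: tuple[np.ndarray, np.ndarray] | None = None
    roc_band: tuple[np.ndarray, np.ndarray] | None = None  # (lower, upper) TPR


def mc_splits(ids, ratio: float = 0.7, n_iter: int = 5, seed: int = 0,
              labels=None, stratify: bool = True, max_attempts: int = 100):
    """``n_iter`` independent random 70/30-style splits.

    Train size is ceil(ratio * n).  With ``labels`` given and
    ``stratify`` true, splits are drawn per class so each side contains
    both classes; a degenerate draw is re-drawn, erroring after
    ``max_attempts``.
    """
    ids = list(ids)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 ids")
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    n_train = math.ceil(ratio * n)
    rng = np.random.default_rng(seed)
    plans = []
    for it in range(n_iter):
        for attempt in range(max_attempts):
            if labels is not None and stratify:
                train_idx: list[int] = []
                by_class: dict = {}
                for i, lab in enumerate(labels):
                    by_class.setdefault(lab, []).append(i)
                # proportional allocation, largest classes absorb rounding
                alloc = {
                    c: math.floor(ratio * len(members))
                    for c, members in by_class.items()
                }
                short = n_train - sum(alloc.values())
                # absorb rounding in the largest classes, preferring ones
                # that can spare a member for the test side
                order_c = sorted(by_class, key=lambda c: -len(by_class[c]))
                sparable = [c for c in order_c if alloc[c] + 1 <= len(by_class[c]) - 1]
                rest = [c for c in order_c if c not in sparable]
                for c in (sparable + rest)[:short]:
                    alloc[c] += 1
                for c, members in by_class.items():
                    pick = rng.permutation(len(members))[: alloc[c]]
                    train_idx.extend(members[i] for i in pick)
            else:
                train_idx = list(rng.permutation(n)[:n_train])
            train = set(train_idx)
            test_idx = [i for i in range(n) if i not in train]
            if labels is None:
                break
            tr_labs = {labels[i] for i in train_idx}
            te_labs = {labels[i] for i in test_idx}
            if len(tr_labs) > 1 and len(te_labs) > 1:
                break
        else:
            raise RuntimeError("could not draw a split containing both classes")
        plans.append(
            SplitPlan(
                iteration=it,
                seed=seed,
                train_ids=tuple(ids[i] for i in sorted(train_idx)),
                test_ids=tuple(ids[i] for i in sorted(test_idx)),
            )
        )
    return plans


def confusion(true_labels, predicted_labels, positive_class: str = GOOD) -> ConfusionCounts:
    """Standard 2x2 tally with a configurable positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    known = {GOOD, POOR}
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in known or p not in known:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        t_pos, p_pos = t == positive_class, p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and p_pos:
            fp += 1
        elif not t_pos and not p_pos:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from a confusion tally.

    A metric whose denominator is zero is reported as None (undefined),
    mirroring how a fold with no positive predictions has no precision.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    out: dict = {"accuracy": (c.tp + c.tn) / c.total}
    out["precision"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    out["recall"] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    if out["precision"] and out["recall"]:
        pr, rc = out["precision"], out["recall"]
        out["f1"] = 2 * pr * rc / (pr + rc)
    elif out["precision"] is None or out["recall"] is None:
        out["f1"] = None
    else:
        out["f1"] = 0.0
    return out


def roc_auc(scores, true_labels, positive_class: str = GOOD):
    """ROC curve over all score thresholds (descending, ties grouped) and
    the trapezoidal AUC, which equals the Mann-Whitney pairwise
    concordance probability."""
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if t == positive_class else 0 for t in true_labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the test set")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(1 - sorted_y)
    # group tied thresholds: keep the last index of each distinct score
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.concatenate([distinct, [len(sorted_scores) - 1]])
    tpr = np.concatenate([[0.0], tps[idx] / n_pos])
    fpr = np.concatenate([[0.0], fps[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def _mean_sd(values):
    vals = [v for v in values if v is not None]
    if not vals:
        return None, None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def aggregate(per_iteration: list[dict], rocs: list[tuple]) -> MetricsReport:
    """Mean and sample SD per metric, plus the vertically averaged ROC
    on a 0..1 false-positive-rate grid (step 0.01) with its +/- 1 SD
    band clipped to [0, 1]."""
    if not per_iteration:
        raise ValueError("no iterations to aggregate")
    if len(per_iteration) < 2:
        raise ValueError("aggregation needs at least 2 iterations")
    report = MetricsReport(per_iteration=per_iteration, rocs=rocs)
    for key in ("accuracy", "precision", "recall", "f1", "auc"):
        m, s = _mean_sd([it.get(key) for it in per_iteration])
        report.mean[key] = m
        report.sd[key] = s
    interp = np.vstack(
        [np.interp(FPR_GRID, fpr, tpr) for fpr, tpr in rocs]
    )
    mean_tpr = interp.mean(axis=0)
    sd_tpr = interp.std(axis=0, ddof=1)
    report.mean_roc = (FPR_GRID.copy(), mean_tpr)
    report.roc_band = (
        np.clip(mean_tpr - sd_tpr, 0, 1),
        np.clip(mean_tpr + sd_tpr, 0, 1),
    )
    return report


def plot_roc(report: MetricsReport, path, title: str = "ROC"):
    """Write a ROC figure: per-iteration dashed curves, mean solid curve,
    +/- 1 SD shaded band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, (fpr, tpr) in enumerate(report.rocs):
        ax.plot(fpr, tpr, "--", lw=0.8, alpha=0.7, label=f"iteration {i + 1}")
    grid, mean_tpr = report.mean_roc
    lo, hi = report.roc_band
    ax.fill_between(grid, lo, hi, color="gray", alpha=0.3, label="+/- 1 SD")
    auc_txt = f"{report.mean['auc']:.2f} +/- {report.sd['auc']:.2f}"
    ax.plot(grid, mean_tpr, "b-", lw=2, label=f"mean ROC (AUC {auc_txt})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
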