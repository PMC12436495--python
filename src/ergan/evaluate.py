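"""Classification metrics and the real-only vs real+synthetic experiment.

Metrics are precision, recall, F1, sensitivity, specificity, balanced
accuracy and ROC-AUC (the probability that a random positive outscores a
random negative, ties counted one half).  The positive class is the case
group (label 1).  Specificity is TN / (TN + FP); an alternative
``literal_specificity`` flag computes TN / (TN + TP) for auditing a known
typo in one published formula — it is never used by default because it
breaks the balanced-accuracy semantics.

``run_experiment`` reproduces the augmentation protocol: stratified 75:25
hold-out, conditional-GAN training on the train side only, then per
condition (real only / real + synthetic) and per flash strength subset a
stratified five-fold cross-validation whose fold models are evaluated on
the untouched test side and averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import cgan as cgan_mod
from . import classify as clf_mod
from . import cwt as cwt_mod
from .dataio import LabeledDataset, kfold_indices, normalize, split_train_test


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts for binary labels (positive class = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(y_true, scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: needs both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    balanced_accuracy: float | None = None
    auc: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "ba": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def compute_metrics(
    counts: ConfusionCounts,
    scores=None,
    y_true=None,
    literal_specificity: bool = False,
) -> MetricsReport:
    """Metric suite from confusion counts (plus scores for AUC).

    Ratios with a zero denominator are reported as None with a reason in
    ``undefined`` rather than silently coerced to 0.
    """
    r = MetricsReport(counts=counts)
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def ratio(num, den, name):
        if den == 0:
            r.undefined[name] = f"denominator zero ({name})"
            return None
        return num / den

    r.precision = ratio(tp, tp + fp, "precision")
    r.recall = ratio(tp, tp + fn, "recall")
    r.sensitivity = r.recall
    spec_den = (tn + tp) if literal_specificity else (tn + fp)
    r.specificity = ratio(tn, spec_den, "specificity")
    if r.precision is not None and r.recall is not None:
        if r.precision + r.recall == 0:
            r.undefined["f1"] = "precision + recall is zero"
        else:
            r.f1 = 2 * r.precision * r.recall / (r.precision + r.recall)
    else:
        r.undefined["f1"] = "precision or recall undefined"
    if r.sensitivity is not None and r.specificity is not None:
        r.balanced_accuracy = (r.sensitivity + r.specificity) / 2.0
    else:
        r.undefined["balanced_accuracy"] = "sensitivity or specificity undefined"
    if scores is not None and y_true is not None:
        try:
            r.auc = roc_auc(y_true, scores)
        except ValueError as exc:
            r.undefined["auc"] = str(exc)
    return r


def average_reports(reports: list[MetricsReport]) -> dict:
    """Fold-average each metric, ignoring undefined entries."""
    out = {}
    for key in ("ba", "precision", "recall", "f1", "auc"):
        vals = [rep.as_row()[key] for rep in reports if rep.as_row()[key] is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


@dataclass(frozen=True)
class ExperimentGrid:
    """Which cells of the comparison table to run."""

    conditions: tuple[str, ...] = ("real_only", "real_plus_synthetic")
    strengths: tuple = ("all",)  # flash strengths and/or "all"
    families: tuple[str, ...] = ("TST",)  # subset of {"TST", "ViT"}
    folds: int = 5


def run_experiment(
    ds: LabeledDataset,
    grid: ExperimentGrid = ExperimentGrid(),
    cgan_cfg: cgan_mod.CGANTrainConfig | None = None,
    tst_cfg: clf_mod.TSTConfig | None = None,
    vit_cfg: clf_mod.ViTConfig | None = None,
    seed: int = 0,
    ratio_real_to_synth: float = 2.0,
    holdout_fraction: float = 0.25,
    eval_on: str = "test",  # "test" (untouched hold-out) or "fold_val"
) -> pd.DataFrame:
    """Run the augmentation-benefit comparison and return the report table.

    One row per (family, strength, condition) with fold-averaged metrics.
    Strength cells with fewer than 2 x folds records are marked
    insufficient.  Test records never enter any fold's fit set; the CGAN
    sees only the train side of the hold-out.
    """
    if eval_on not in ("test", "fold_val"):
        raise ValueError(f"eval_on must be 'test' or 'fold_val', got {eval_on}")
    tst_cfg = tst_cfg or clf_mod.TSTConfig()
    vit_cfg = vit_cfg or clf_mod.ViTConfig()

    split = split_train_test(ds, fraction=holdout_fraction, seed=seed)
    train = normalize(split.train, "minmax")
    test = normalize(split.test, using=train.normalization)

    model = None
    if "real_plus_synthetic" in grid.conditions:
        cgan_cfg = cgan_cfg or cgan_mod.CGANTrainConfig(scale_factor=0.125, epochs=800)
        model = cgan_mod.train_cgan(train, cgan_cfg)

    scalo_cache: dict[str, np.ndarray] = {}

    def scalograms(d: LabeledDataset) -> np.ndarray:
        missing = [i for i, rid in enumerate(d.meta["id"]) if rid not in scalo_cache]
        if missing:
            imgs = cwt_mod.scalogram_batch(d.X[missing], side=vit_cfg.side)
            for j, i in enumerate(missing):
                scalo_cache[d.meta["id"].iloc[i]] = imgs[j]
        return np.stack([scalo_cache[rid] for rid in d.meta["id"]])

    rows = []
    for family in grid.families:
        for strength in grid.strengths:
            if strength == "all":
                tr_cell = train
                te_cell = test
            else:
                tr_cell = train.subset(np.flatnonzero(train.strengths == strength))
                te_cell = test.subset(np.flatnonzero(test.strengths == strength))
            for condition in grid.conditions:
                row = {"network": family, "strength": strength, "condition": condition}
                if len(tr_cell) < 2 * grid.folds or len(set(tr_cell.y)) < 2:
                    rows.append({**row, "insufficient": True})
                    continue
                cell = tr_cell
                if condition == "real_plus_synthetic":
                    cell = cgan_mod.augment(
                        tr_cell, model, ratio_real_to_synth, seed=seed
                    )
                synth_mask = cell.meta["synthetic"].to_numpy()
                real_idx = np.flatnonzero(~synth_mask)
                synth_idx = np.flatnonzero(synth_mask)
                real_cell = cell.subset(real_idx)
                fold_reports = []
                for f, (fit_idx, val_idx) in enumerate(
                    kfold_indices(real_cell, k=grid.folds, seed=seed)
                ):
                    fit = real_cell.subset(fit_idx)
                    if len(synth_idx):
                        fit = fit.concat(cell.subset(synth_idx))
                    val = real_cell.subset(val_idx)
                    ev = val if eval_on == "fold_val" else te_cell
                    if family == "TST":
                        m = clf_mod.train_tst(
                            fit.X, fit.y, val.X, val.y, tst_cfg, seed=seed * 97 + f
                        )
                        pred = clf_mod.predict(m, ev.X)
                    else:
                        m = clf_mod.train_vit(
                            scalograms(fit), fit.y, scalograms(val), val.y,
                            vit_cfg, seed=seed * 97 + f,
                        )
                        pred = clf_mod.predict(m, scalograms(ev))
                    rep = compute_metrics(
                        confusion(ev.y, pred["label"]), pred["prob"], ev.y
                    )
                    fold_reports.append(rep)
                rows.append({**row, "insufficient": False,
                             **average_reports(fold_reports)})
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> str:
    """Text rendering of the report table, one block per condition."""
    lines = []
    for condition, sub in table.groupby("condition", sort=False):
        lines.append(f"== {condition} ==")
        lines.append(f"{'Network':<8}{'Strength':>9}{'BA':>8}{'P':>8}{'R':>8}"
                     f"{'F1':>8}{'AUC':>8}")
        for _, r in sub.iterrows():
            if r.get("insufficient", False):
                lines.append(f"{r['network']:<8}{str(r['strength']):>9}"
                             + "  (insufficient records)")
                continue
            vals = "".join(
                f"{r[k]:>8.3f}" if pd.notna(r[k]) else f"{'--':>8}"
                for k in ("ba", "precision", "recall", "f1", "auc")
            )
            lines.append(f"{r['network']:<8}{str(r['strength']):>9}{vals}")
    return "\n".join(lines)
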