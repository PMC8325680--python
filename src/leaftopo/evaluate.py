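"""Score-level fusion, repeated-split evaluation, F1, one-way ANOVA.

Score fusion follows G(X) = argmax (1/T) sum_t g_t(x_t): the class-
probability vectors of the per-period models are averaged with equal
weights and the argmax taken (ties broken by lowest class index).

The one-way ANOVA uses the classical decomposition
    S1^2 = sum_i n_i (Ybar_i - Ybar)^2 / (K - 1)   (between groups)
    S2^2 = sum_i sum_j (Y_ij - Ybar_i)^2 / (N - K) (within groups)
    F    = S1^2 / S2^2
with the p-value from the exact F(K-1, N-K) upper tail; the critical
value at alpha is reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FusionConfig, TrainConfig, accuracy, build_fusion_model, \
    predict, train


@dataclass
class ScoreMatrix:
    """Rows are per-model class-probability vectors for one fused sample."""

    scores: np.ndarray  # (T, C)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, float))
        if self.scores.shape[0] < 1:
            raise ValueError("need at least one model row")
        sums = self.scores.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("rows must be probability vectors")


def fuse_scores(m: ScoreMatrix) -> tuple[np.ndarray, int]:
    """Equal-weight mean of the rows and its argmax class."""
    fused = m.scores.mean(axis=0)
    return fused, int(fused.argmax())


def per_class_f1(predictions, labels) -> np.ndarray:
    """F1 per class; 0 for classes never predicted and never hit."""
    from sklearn.metrics import f1_score

    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    classes = np.unique(labels)
    return f1_score(labels, predictions, labels=classes, average=None,
                    zero_division=0.0)


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p_value: float
    reject_at_alpha: bool
    alpha: float = 0.05
    critical_value: float = field(default=np.nan)


def one_way_anova(groups, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA over K groups of observations."""
    from scipy import stats

    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    K = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    s1 = float((ns * (means - grand) ** 2).sum() / (K - 1))
    s2 = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
               / (N - K))
    df = (K - 1, N - K)
    if s2 == 0.0:
        if s1 == 0.0:
            raise ZeroDivisionError(
                "all groups constant and equal: F undefined (0/0)")
        return AnovaResult(np.inf, df, 0.0, True, alpha,
                           float(stats.f.ppf(1 - alpha, *df)))
    F = s1 / s2
    p = float(stats.f.sf(F, *df))
    crit = float(stats.f.ppf(1 - alpha, *df))
    return AnovaResult(float(F), df, p, p < alpha, alpha, crit)


# -- repeated-split evaluation ---------------------------------------------

def evaluate_repeated_splits(dataset, tcfg: TrainConfig, n_iters: int = 10,
                             fcfg: FusionConfig | None = None) -> dict:
    """Train/test over n_iters reshuffled splits; report accuracies.

    Iteration i reuses the training configuration with seed
    tcfg.seed + i, so runs are reproducible and distinct.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    fcfg = fcfg or FusionConfig()
    n_classes = int(max(r.label for r in dataset)) + 1
    accs = []
    for i in range(n_iters):
        it_cfg = TrainConfig(**{**tcfg.__dict__, "seed": tcfg.seed + i})
        model = build_fusion_model(fcfg, n_classes, seed=it_cfg.seed)
        model, hist = train(model, dataset, it_cfg)
        accs.append(accuracy(model, dataset, hist["split"]["test"]))
    accs = np.array(accs)
    return {"accuracies": accs.tolist(),
            "mean": float(accs.mean()),
            "std": float(accs.std(ddof=1)) if n_iters > 1 else 0.0,
            "n_iters": n_iters}


def evaluate_multiperiod_fusion(datasets_by_period: dict, tcfg: TrainConfig,
                                fcfg: FusionConfig | None = None) -> dict:
    """Train one model per growth period and fuse test-set scores.

    Pairing rule: within each cultivar, the k-th test leaf of each period
    (ordered by index within the per-period test set) forms one fused
    sample; the fused count per class is the minimum across periods.  The
    rule is recorded in the output metadata.
    """
    fcfg = fcfg or FusionConfig()
    periods = list(datasets_by_period)
    n_classes = int(max(r.label for r in datasets_by_period[periods[0]])) + 1

    per_period_probs = {}
    per_period_acc = {}
    for p in periods:
        ds = datasets_by_period[p]
        model = build_fusion_model(fcfg, n_classes, seed=tcfg.seed)
        model, hist = train(model, ds, tcfg)
        test_idx = hist["split"]["test"]
        recs = [ds[i] for i in test_idx]
        probs = predict(model, recs)
        labels = np.array([r.label for r in recs])
        per_period_acc[p] = float((probs.argmax(axis=1) == labels).mean())
        by_class: dict[int, list[np.ndarray]] = {}
        for pr, lab in zip(probs, labels):
            by_class.setdefault(int(lab), []).append(pr)
        per_period_probs[p] = by_class

    fused_correct = 0
    fused_total = 0
    for c in range(n_classes):
        counts = [len(per_period_probs[p].get(c, [])) for p in periods]
        for k in range(min(counts)):
            rows = np.stack([per_period_probs[p][c][k] for p in periods])
            _, pred = fuse_scores(ScoreMatrix(rows))
            fused_correct += int(pred == c)
            fused_total += 1
    fused_acc = fused_correct / max(fused_total, 1)
    return {"per_period_accuracy": per_period_acc,
            "fused_accuracy": float(fused_acc),
            "n_fused_samples": fused_total,
            "pairing": "k-th test leaf per class per period, by test index"}
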