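"""ROC analysis, Youden-optimal cut-offs, and cut-off transfer validation.

Candidate thresholds are the observed unique metric values, with inclusive
comparison under the metric's orientation: for ADC-like metrics lower values
indicate malignancy, so a node is called metastatic when its value is less
than or equal to the cut-off; for size-like metrics (short-axis diameter,
Node-RADS) the comparison is greater-or-equal. The area under the curve is
the trapezoid over the resulting operating points, which for this threshold
set equals the pairwise concordance probability (ties counted half).

The 95% AUC confidence interval uses DeLong's nonparametric variance by
default, with a stratified bootstrap as an option; upper bounds are
truncated at 1. A fixed external cut-off can be transfer-validated on any
target set, excluding (and counting) records where the metric is absent.
Single-predictor logistic regression (maximum likelihood, logit link) with
McFadden's pseudo-R^2 backs the regression-derived performance figures.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import statsmodels.api as sm

from .data import AnalysisSet, TruthStatus, metric_values

__all__ = [
    "Orientation",
    "RocResult",
    "CutoffResult",
    "ConfusionMatrix",
    "DiagnosticPerformance",
    "LogisticFit",
    "default_orientation",
    "roc_curve",
    "auc_ci",
    "youden_optimal_cutoff",
    "classify_at_cutoff",
    "performance_metrics",
    "transfer_validation",
    "logistic_fit_single",
    "round_half_up",
]


class Orientation(enum.Enum):
    LOWER_IS_POSITIVE = "lower_is_positive"
    HIGHER_IS_POSITIVE = "higher_is_positive"


def default_orientation(metric: str) -> Orientation:
    """Field convention: restricted diffusion (low ADC and low ratios) marks
    malignancy; larger diameter and higher Node-RADS categories do."""
    if metric in ("sad", "node_rads"):
        return Orientation.HIGHER_IS_POSITIVE
    return Orientation.LOWER_IS_POSITIVE


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching report-table print precision."""
    if x is None or not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pos_mask(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, TruthStatus):
            out.append(lab is TruthStatus.METASTATIC)
        elif isinstance(lab, str):
            out.append(TruthStatus(lab) is TruthStatus.METASTATIC)
        else:
            out.append(bool(lab))
    return np.asarray(out, dtype=bool)


@dataclass
class RocResult:
    """An ROC curve with its source observations retained for CI methods.

    ``points`` are ``(threshold, sensitivity, 1-specificity)`` tuples in
    sweep order, starting at the degenerate call-nothing point (threshold
    ``None``) and ending at the call-everything point.
    """

    points: list[tuple[float | None, float, float]]
    auc: float
    orientation: Orientation
    n_pos: int
    n_neg: int
    auc_ci: tuple[float, float] | None = None
    values: np.ndarray = field(default=None, repr=False)
    pos: np.ndarray = field(default=None, repr=False)


@dataclass
class CutoffResult:
    """Youden-optimal operating point of an ROC curve."""

    cutoff: float
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    orientation: Orientation


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticPerformance:
    """The six confusion-matrix metrics; an undefined denominator yields
    ``None`` with the metric named in ``undefined`` (never a silent zero)."""

    sens: float | None
    spec: float | None
    ppv: float | None
    npv: float | None
    acc: float | None
    youden_j: float | None
    effective_n: int
    undefined: tuple[str, ...] = ()

    @property
    def fnr(self) -> float | None:
        """False-negative rate, 1 - sensitivity."""
        return None if self.sens is None else 1.0 - self.sens


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    loglik: float
    null_loglik: float
    mcfadden_r2: float
    converged: bool
    separation: bool


# ---------------------------------------------------------------------------
# ROC construction
# ---------------------------------------------------------------------------


def roc_curve(values, labels, orientation: Orientation) -> RocResult:
    """Empirical ROC over the observed unique values as thresholds."""
    v = np.asarray(values, dtype=float)
    pos = _pos_mask(labels)
    if v.shape[0] != pos.shape[0]:
        raise ValueError(
            f"values and labels length mismatch: {v.shape[0]} vs {pos.shape[0]}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite (drop absent entries first)")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC requires both classes; got {n_pos} positive and {n_neg} negative"
        )

    thresholds = np.unique(v)
    if orientation is Orientation.LOWER_IS_POSITIVE:
        sweep = thresholds  # ascending: predictions grow as t increases
        pred = v[None, :] <= sweep[:, None]
    else:
        sweep = thresholds[::-1]  # descending: predictions grow as t decreases
        pred = v[None, :] >= sweep[:, None]
    sens = pred[:, pos].mean(axis=1)
    fpr = pred[:, ~pos].mean(axis=1)

    points = [(None, 0.0, 0.0)]
    points += [(float(t), float(s), float(f)) for t, s, f in zip(sweep, sens, fpr)]
    xs = np.concatenate([[0.0], fpr])
    ys = np.concatenate([[0.0], sens])
    auc = float(np.trapezoid(ys, xs))
    return RocResult(
        points=points,
        auc=auc,
        orientation=orientation,
        n_pos=n_pos,
        n_neg=n_neg,
        values=v,
        pos=pos,
    )


def _oriented_scores(roc: RocResult) -> np.ndarray:
    # higher score = more malignant, regardless of metric orientation
    if roc.orientation is Orientation.LOWER_IS_POSITIVE:
        return -roc.values
    return roc.values


def _concordance_auc(x: np.ndarray, y: np.ndarray) -> float:
    """AUC as pairwise concordance (positives x vs negatives y, half ties)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return (gt + 0.5 * eq) / (x.size * y.size)


def auc_ci(
    roc: RocResult,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """95% confidence interval for the AUC; upper bound truncated at 1."""
    s = _oriented_scores(roc)
    x, y = s[roc.pos], s[~roc.pos]
    if method == "delong":
        if roc.n_pos < 2 or roc.n_neg < 2:
            raise ValueError(
                "DeLong variance needs at least 2 observations per class; "
                "use method='bootstrap'"
            )
        psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
        v10 = psi.mean(axis=1)  # structural components of the positives
        v01 = psi.mean(axis=0)
        var = v10.var(ddof=1) / roc.n_pos + v01.var(ddof=1) / roc.n_neg
        se = math.sqrt(var)
        lo, hi = roc.auc - 1.959963984540054 * se, roc.auc + 1.959963984540054 * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, x.size, x.size)]
            yb = y[rng.integers(0, y.size, y.size)]
            aucs[b] = _concordance_auc(xb, yb)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    ci = (max(float(lo), 0.0), min(float(hi), 1.0))
    roc.auc_ci = ci
    return ci


# ---------------------------------------------------------------------------
# cut-off selection and classification
# ---------------------------------------------------------------------------


def youden_optimal_cutoff(roc: RocResult) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity (fewer false negatives, the
    screening emphasis), then toward the threshold with the larger margin to
    the next observed value, then toward the smaller threshold.
    """
    uniq = np.unique(roc.values)
    gaps = {}
    for i, t in enumerate(uniq):
        if roc.orientation is Orientation.LOWER_IS_POSITIVE:
            gaps[float(t)] = float(uniq[i + 1] - t) if i + 1 < uniq.size else math.inf
        else:
            gaps[float(t)] = float(t - uniq[i - 1]) if i > 0 else math.inf

    best = None
    for t, sens, fpr in roc.points:
        if t is None:
            continue
        j = sens - fpr
        key = (j, sens, gaps[t], -t)
        if best is None or key > best[0]:
            best = (key, t, sens, fpr)
    _, t, sens, fpr = best
    return CutoffResult(
        cutoff=t,
        youden_j=sens + (1.0 - fpr) - 1.0,
        sens_at_cutoff=sens,
        spec_at_cutoff=1.0 - fpr,
        orientation=roc.orientation,
    )


def classify_at_cutoff(values, cutoff: float, orientation: Orientation):
    """Predict metastatic per value at a fixed cut-off (inclusive).

    Absent values (``None``/NaN) yield absent predictions (``None``).
    """
    if cutoff is None or not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff!r}")
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(None)
        elif orientation is Orientation.LOWER_IS_POSITIVE:
            out.append(v <= cutoff)
        else:
            out.append(v >= cutoff)
    return out


def confusion_from_predictions(truth_labels, predictions) -> ConfusionMatrix:
    """Tally a confusion matrix, skipping absent predictions."""
    pos = _pos_mask(truth_labels)
    tp = fp = tn = fn = 0
    for is_pos, pred in zip(pos, predictions, strict=True):
        if pred is None:
            continue
        if is_pos:
            tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def performance_metrics(cm: ConfusionMatrix) -> DiagnosticPerformance:
    """Sens/spec/PPV/NPV/accuracy/Youden J from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn, "sens")
    spec = ratio(cm.tn, cm.tn + cm.fp, "spec")
    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv")
    acc = (cm.tp + cm.tn) / cm.total
    j = None if sens is None or spec is None else sens + spec - 1.0
    return DiagnosticPerformance(
        sens=sens,
        spec=spec,
        ppv=ppv,
        npv=npv,
        acc=acc,
        youden_j=j,
        effective_n=cm.total,
        undefined=tuple(undefined),
    )


def transfer_validation(
    cutoff,
    target_set,
    metric: str,
    orientation: Orientation | None = None,
    reader=None,
) -> tuple[ConfusionMatrix, DiagnosticPerformance]:
    """Evaluate a fixed, externally derived cut-off on a target set.

    ``cutoff`` may be a :class:`CutoffResult` (carrying its orientation) or
    a bare number (then ``orientation`` defaults to the metric convention).
    ``target_set`` is an :class:`AnalysisSet` or a list of records; pass
    ``reader`` to restrict a two-reader set to one reader's measurements.
    Records with the metric absent are excluded and counted.
    """
    if isinstance(cutoff, CutoffResult):
        orientation = cutoff.orientation
        cut = cutoff.cutoff
    else:
        cut = float(cutoff)
        if orientation is None:
            orientation = default_orientation(metric)
    records = target_set.records if isinstance(target_set, AnalysisSet) else list(target_set)
    if reader is not None:
        records = [r for r in records if r.reader == reader]
    seen = set()
    truth, vals = [], []
    n_absent = 0
    for r in records:
        if r.key in seen:
            raise ValueError(
                "multiple rows per node in transfer validation; restrict to "
                "one reader"
            )
        seen.add(r.key)
        v = metric_values(r, metric)
        if v is None:
            n_absent += 1
            continue
        truth.append(r.truth_status)
        vals.append(v)
    pos = _pos_mask(truth)
    if len(vals) == 0 or pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError(
            f"metric {metric!r} must be present for at least one node of "
            f"each class in the target set"
        )
    preds = classify_at_cutoff(vals, cut, orientation)
    cm = confusion_from_predictions(truth, preds)
    perf = performance_metrics(cm)
    cm.n_excluded_absent = n_absent
    return cm, perf


# ---------------------------------------------------------------------------
# single-predictor logistic regression
# ---------------------------------------------------------------------------

_MAXITER = 100


def _separated(v: np.ndarray, pos: np.ndarray) -> bool:
    # complete separation for a single predictor: the classes' supports are
    # disjoint intervals
    return v[pos].max() < v[~pos].min() or v[pos].min() > v[~pos].max()


def logistic_fit_single(values, labels) -> LogisticFit:
    """Maximum-likelihood Bernoulli fit with logit link, one predictor.

    Complete separation is detected from the data (disjoint class supports)
    and reported via the ``separation`` flag instead of silently diverging;
    coefficients from the capped iteration are still returned.
    """
    v = np.asarray(values, dtype=float)
    pos = _pos_mask(labels)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if pos.all() or (~pos).all():
        raise ValueError("logistic fit requires both classes present")
    separation = _separated(v, pos)
    X = sm.add_constant(v)
    model = sm.Logit(pos.astype(float), X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=_MAXITER, disp=0)
        except Exception:
            res = model.fit(method="bfgs", maxiter=_MAXITER, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged and not separation:
        raise RuntimeError(
            f"logistic fit did not converge within {_MAXITER} iterations; "
            f"last parameters {res.params.tolist()}"
        )
    llf, llnull = float(res.llf), float(res.llnull)
    r2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    return LogisticFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        loglik=llf,
        null_loglik=llnull,
        mcfadden_r2=r2,
        converged=converged,
        separation=separation,
    )
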