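"""Monte-Carlo cross-validation protocols for classification and imputation.

Two procedures are implemented:

* **Hybrid cross + external validation for classification** — per iteration,
  roughly 85% of the complete samples of each month go to calibration; the
  remaining complete samples form the internal cross-validation pool. The
  partial samples are divided once per run: a fixed external pool (about one
  third per month) that is *never* used for calibration across iterations,
  with the remaining partial samples always in the calibration set. The
  metric is the percentage of correctly classified validation samples (%CC),
  averaged over iterations, swept over the model order (number of PCs or
  latent variables).

* **Monte-Carlo cross-validation for %FAME imputation** — per iteration, 20%
  of the complete samples of each month are held out, their entire fatty-acid
  block is masked, the model is fitted on the rest, and the held-out block is
  predicted (PPCA: conditional mean given minerals; PLSR: regression from
  minerals). RMSECV and R^2 are computed per iteration on the autoscaled
  scale and averaged; original-scale values are also reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import COMPLETE, PARTIAL, ProfileMatrix
from .lda import fit_lda
from .pls import fit_pls, fit_plsda
from .ppca import PPCAResults, fit_ppca
from .preprocess import fit_scaler, transform

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
def percent_correct(predicted, truth) -> float:
    """Percentage (0-100) of matching labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0 or predicted.shape != truth.shape:
        raise ValidationError("empty or mismatched label arrays")
    return 100.0 * float(np.mean(predicted == truth))

def rmse(residuals) -> float:
    """Root mean squared residual."""
    r = np.asarray(residuals, float).ravel()
    if r.size == 0:
        raise ValidationError("empty residual set")
    return float(np.sqrt(np.mean(r * r)))

def r_squared(residuals, totals) -> float:
    """1 - SSE/SST where ``totals`` are deviations from the calibration mean."""
    r = np.asarray(residuals, float).ravel()
    t = np.asarray(totals, float).ravel()
    if r.size == 0 or t.size == 0:
        raise ValidationError("empty residual/total set")
    sst = float(np.sum(t * t))
    if sst == 0.0:
        raise ValidationError("zero total sum of squares")
    return 1.0 - float(np.sum(r * r)) / sst


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------
@dataclass
class SplitPlan:
    """Disjoint sample-id sets of one Monte-Carlo iteration."""

    calibration_complete: list[str]
    calibration_partial: list[str]
    validation_complete: list[str]
    validation_partial_external: list[str]

    def __post_init__(self) -> None:
        sets = [
            set(self.calibration_complete),
            set(self.calibration_partial),
            set(self.validation_complete),
            set(self.validation_partial_external),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValidationError("split plan sets are not disjoint")

    @property
    def calibration_ids(self) -> list[str]:
        return self.calibration_complete + self.calibration_partial

    @property
    def validation_ids(self) -> list[str]:
        return self.validation_complete + self.validation_partial_external


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _by_month(matrix: ProfileMatrix, tag: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for sid, label, t in zip(matrix.sample_ids, matrix.labels, matrix.completeness):
        if t == tag:
            out.setdefault(label, []).append(sid)
    return out


def draw_external_pool(
    matrix: ProfileMatrix, seed=0, external_fraction: float = 1.0 / 3.0
) -> list[str]:
    """Fix, once per run, the external-validation partial samples per month.

    About a third of each month's partial samples (nearest rounding, at least
    one when any exist) are reserved exclusively for external validation.
    """
    rng = _rng(seed)
    pool: list[str] = []
    for month, ids in sorted(_by_month(matrix, PARTIAL).items()):
        k = int(round(external_fraction * len(ids)))
        k = min(max(k, 1), len(ids)) if ids else 0
        pool += sorted(rng.choice(ids, size=k, replace=False).tolist())
    return pool


def make_classification_split(
    matrix: ProfileMatrix,
    seed=0,
    calibration_complete_fraction: float = 0.85,
    external_ids: list[str] | None = None,
    external_fraction: float = 1.0 / 3.0,
) -> SplitPlan:
    """One iteration's calibration/validation split.

    Per month, about 85% of complete samples (nearest rounding, always
    leaving at least one out) are drawn for calibration; the rest form the
    internal cross-validation pool. Partial samples not in the external pool
    are calibration members every iteration.
    """
    rng = _rng(seed)
    if external_ids is None:
        external_ids = draw_external_pool(matrix, rng, external_fraction)
    external = set(external_ids)

    cal_c: list[str] = []
    val_c: list[str] = []
    for month, ids in sorted(_by_month(matrix, COMPLETE).items()):
        n = len(ids)
        if n < 2:
            raise ValidationError(
                f"month {month!r} has {n} complete sample(s); need >= 2 to split"
            )
        n_cal = min(int(round(calibration_complete_fraction * n)), n - 1)
        n_cal = max(n_cal, 1)
        chosen = set(rng.choice(ids, size=n_cal, replace=False).tolist())
        cal_c += sorted(chosen)
        val_c += sorted(set(ids) - chosen)

    partial_ids = [s for ids in _by_month(matrix, PARTIAL).values() for s in ids]
    cal_p = sorted(set(partial_ids) - external)
    return SplitPlan(
        calibration_complete=cal_c,
        calibration_partial=cal_p,
        validation_complete=val_c,
        validation_partial_external=sorted(external),
    )


# ---------------------------------------------------------------------------
# metric curves
# ---------------------------------------------------------------------------
@dataclass
class MetricCurve:
    """Model order versus averaged metric with per-iteration values."""

    metric_name: str
    orders: list[int]
    per_iteration: np.ndarray  # (n_orders, n_iterations)
    higher_is_better: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_iteration = np.asarray(self.per_iteration, float)
        if self.per_iteration.shape[0] != len(self.orders):
            raise ValidationError("per_iteration rows must match orders")

    @property
    def mean_metric(self) -> np.ndarray:
        return self.per_iteration.mean(axis=1)

    @property
    def selected_order(self) -> int:
        m = self.mean_metric
        idx = int(np.argmax(m) if self.higher_is_better else np.argmin(m))
        return self.orders[idx]

    @property
    def best_mean(self) -> float:
        m = self.mean_metric
        return float(m.max() if self.higher_is_better else m.min())

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "orders": list(self.orders),
            "mean_metric": self.mean_metric.tolist(),
            "per_iteration": self.per_iteration.tolist(),
            "selected_order": self.selected_order,
            "higher_is_better": self.higher_is_better,
            "extras": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.extras.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricCurve":
        return cls(
            metric_name=d["metric_name"],
            orders=list(d["orders"]),
            per_iteration=np.asarray(d["per_iteration"], float),
            higher_is_better=bool(d.get("higher_is_better", True)),
            extras=dict(d.get("extras", {})),
        )


def _quiet_fit_ppca(matrix, q, tol, max_iter):
    """Fit without per-fit convergence warnings; the run-level diagnostics
    (convergence fraction, worst log-likelihood increment) report EM health."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_ppca(matrix, q, tol=tol, max_iter=max_iter)


class _FitDiagnostics:
    """Tracks EM health over every PPCA fit in a run."""

    def __init__(self) -> None:
        self.min_ll_increment = np.inf
        self.all_converged = True
        self.n_fits = 0

    def update(self, res: PPCAResults) -> None:
        self.n_fits += 1
        self.all_converged &= res.converged
        if res.ll_trace.size > 1:
            inc = np.min(np.diff(res.ll_trace)) / (1.0 + abs(res.loglike))
            self.min_ll_increment = min(self.min_ll_increment, float(inc))

    def as_extras(self) -> dict:
        return {
            "n_ppca_fits": self.n_fits,
            "all_converged": bool(self.all_converged),
            "min_ll_increment_normalized": (
                None if not np.isfinite(self.min_ll_increment) else self.min_ll_increment
            ),
        }


# ---------------------------------------------------------------------------
# protocol A: classification
# ---------------------------------------------------------------------------
def run_classification_validation(
    matrix: ProfileMatrix,
    model_kind: str = "ppca_lda",
    orders=range(1, 9),
    n_iterations: int = 20,
    seed: int = 0,
    calibration_complete_fraction: float = 0.85,
    external_fraction: float = 1.0 / 3.0,
    lda_first_two: bool = False,
    ppca_tol: float = 1e-5,
    ppca_max_iter: int = 1000,
) -> MetricCurve:
    """Sweep model order and average validation %CC over Monte-Carlo splits.

    ``model_kind`` is "ppca_lda" (PPCA scores + linear discriminant, fitted on
    complete *and* partial calibration samples) or "plsda" (minerals only).
    With ``lda_first_two`` the discriminant sees only the first two score
    axes regardless of the PPCA order.
    """
    orders = [int(q) for q in orders]
    if not orders or min(orders) < 1:
        raise ValidationError("orders must be positive integers")
    if model_kind not in ("ppca_lda", "plsda"):
        raise ValidationError(f"unknown model_kind {model_kind!r}")
    mineral_cols = matrix.mineral_idx
    if model_kind == "plsda" and max(orders) > int(mineral_cols.sum()):
        raise ValidationError("PLS-DA order cannot exceed the number of mineral predictors")

    external_ids = draw_external_pool(
        matrix, np.random.default_rng([seed, 2**20]), external_fraction
    )
    classes = sorted(set(matrix.labels))
    diag = _FitDiagnostics()
    pcc = np.empty((len(orders), n_iterations))
    pcc_int = np.full((len(orders), n_iterations), np.nan)
    pcc_ext = np.full((len(orders), n_iterations), np.nan)

    for it in range(n_iterations):
        rng_it = np.random.default_rng([seed, it])
        plan = make_classification_split(
            matrix,
            rng_it,
            calibration_complete_fraction=calibration_complete_fraction,
            external_ids=external_ids,
        )
        cal = matrix.subset_ids(plan.calibration_ids)
        val = matrix.subset_ids(plan.validation_ids)
        scaler = fit_scaler(cal)
        cal_t = transform(scaler, cal)
        val_t = transform(scaler, val)
        truth = np.asarray(val.labels)
        is_internal = np.array(
            [sid in set(plan.validation_complete) for sid in val.sample_ids]
        )
        for k, q in enumerate(orders):
            if model_kind == "ppca_lda":
                res = _quiet_fit_ppca(cal_t, q, ppca_tol, ppca_max_iter)
                diag.update(res)
                z_cal = res.scores(cal_t).scores
                z_val = res.scores(val_t).scores
                if lda_first_two and q > 2:
                    z_cal, z_val = z_cal[:, :2], z_val[:, :2]
                lda = fit_lda(z_cal, cal_t.labels, classes=classes)
                pred = lda.predict(z_val)
            else:
                Xc = cal_t.values[:, mineral_cols]
                Xv = val_t.values[:, mineral_cols]
                plsda = fit_plsda(Xc, cal_t.labels, q, classes=classes)
                pred = plsda.predict(Xv)
            pcc[k, it] = percent_correct(pred, truth)
            if is_internal.any():
                pcc_int[k, it] = percent_correct(pred[is_internal], truth[is_internal])
            if (~is_internal).any():
                pcc_ext[k, it] = percent_correct(pred[~is_internal], truth[~is_internal])
        logger.info("classification iteration %d/%d done", it + 1, n_iterations)

    extras = {
        "model_kind": model_kind,
        "internal_mean": np.nanmean(pcc_int, axis=1),
        "external_mean": np.nanmean(pcc_ext, axis=1),
        "external_ids": external_ids,
        "seed": seed,
    }
    if model_kind == "ppca_lda":
        extras.update(diag.as_extras())
    return MetricCurve(
        metric_name="%CC", orders=orders, per_iteration=pcc, higher_is_better=True,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# protocol B: imputation
# ---------------------------------------------------------------------------
def make_imputation_holdout(
    matrix: ProfileMatrix, seed=0, holdout_fraction: float = 0.2
) -> list[str]:
    """Per month, hold out ~20% of complete samples (nearest rounding, min 1)."""
    rng = _rng(seed)
    held: list[str] = []
    for month, ids in sorted(_by_month(matrix, COMPLETE).items()):
        n = len(ids)
        if n < 2:
            raise ValidationError(
                f"month {month!r} has {n} complete sample(s); need >= 2"
            )
        k = min(max(int(round(holdout_fraction * n)), 1), n - 1)
        held += sorted(rng.choice(ids, size=k, replace=False).tolist())
    return held


def run_imputation_validation(
    matrix: ProfileMatrix,
    model_kind: str = "ppca",
    orders=range(1, 9),
    n_iterations: int = 20,
    seed: int = 0,
    holdout_fraction: float = 0.2,
    ppca_tol: float = 1e-5,
    ppca_max_iter: int = 1000,
) -> dict[str, MetricCurve]:
    """Monte-Carlo cross-validation of fatty-acid block imputation.

    Held-out complete samples have their %FAME block masked and predicted
    from their minerals. Returns ``{"rmsecv": curve, "r2": curve}`` on the
    autoscaled scale (R^2 in percent); original-scale RMSECV is in
    ``extras["rmsecv_original_scale_mean"]``.
    """
    orders = [int(q) for q in orders]
    if model_kind not in ("ppca", "plsr"):
        raise ValidationError(f"unknown model_kind {model_kind!r}")
    fame_cols = matrix.fame_idx
    mineral_cols = matrix.mineral_idx
    if not fame_cols.any():
        raise ValidationError("matrix has no FAME variables to impute")
    if model_kind == "plsr" and max(orders) > int(mineral_cols.sum()):
        raise ValidationError("PLSR order cannot exceed the number of mineral predictors")

    diag = _FitDiagnostics()
    shape = (len(orders), n_iterations)
    rmse_it = np.empty(shape)
    r2_it = np.empty(shape)
    rmse_orig_it = np.empty(shape)
    pooled_sq: list[list[float]] = [[] for _ in orders]

    for it in range(n_iterations):
        rng_it = np.random.default_rng([seed, it])
        held = make_imputation_holdout(matrix, rng_it, holdout_fraction)
        held_set = set(held)
        cal_ids = [s for s in matrix.sample_ids if s not in held_set]
        cal = matrix.subset_ids(cal_ids)
        val = matrix.subset_ids(held)
        scaler = fit_scaler(cal)
        cal_t = transform(scaler, cal)
        val_t = transform(scaler, val)
        truth = val_t.values[:, fame_cols]  # held-out rows are complete
        # masked copy of the validation rows: minerals only
        v_mask = val_t.mask.copy()
        v_mask[:, fame_cols] = False
        val_masked = val_t.with_values_mask(val_t.values, v_mask)
        cal_complete = cal_t.subset(cal_t.complete_idx)
        fame_scale = scaler.scale[fame_cols]
        for k, q in enumerate(orders):
            if model_kind == "ppca":
                res = _quiet_fit_ppca(cal_t, q, ppca_tol, ppca_max_iter)
                diag.update(res)
                filled = res.reconstruct(val_masked)
                pred = filled.values[:, fame_cols]
            else:
                reg = fit_pls(
                    cal_complete.values[:, mineral_cols],
                    cal_complete.values[:, fame_cols],
                    q,
                )
                pred = reg.predict(val_masked.values[:, mineral_cols])
            resid = pred - truth
            rmse_it[k, it] = rmse(resid)
            # scaler centers on calibration, so calibration FAME means are 0
            # on this scale and SST is the plain sum of squares of the truth
            r2_it[k, it] = 100.0 * r_squared(resid, truth)
            rmse_orig_it[k, it] = rmse(resid * fame_scale[None, :])
            pooled_sq[k].extend((resid.ravel() ** 2).tolist())
        logger.info("imputation iteration %d/%d done", it + 1, n_iterations)

    extras_common = {"model_kind": model_kind, "seed": seed}
    if model_kind == "ppca":
        extras_common.update(diag.as_extras())
    rmse_curve = MetricCurve(
        metric_name="RMSECV",
        orders=orders,
        per_iteration=rmse_it,
        higher_is_better=False,
        extras={
            **extras_common,
            "rmsecv_original_scale_mean": rmse_orig_it.mean(axis=1),
            "rmsecv_pooled": np.array([np.sqrt(np.mean(s)) for s in pooled_sq]),
        },
    )
    r2_curve = MetricCurve(
        metric_name="R2",
        orders=orders,
        per_iteration=r2_it,
        higher_is_better=True,
        extras=dict(extras_common),
    )
    return {"rmsecv": rmse_curve, "r2": r2_curve}
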