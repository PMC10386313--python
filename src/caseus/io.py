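"""CSV/JSON input-output for profile matrices, models and validation reports.

Missing cells are accepted as empty, "NA" or "NaN" (case-insensitive) on
read and always written back as "NA". Reports are plain CSV (one row per
model order, one column per iteration) plus a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ProfileMatrix, completeness_from_mask, infer_roles
from .validation import MetricCurve

_NA_TOKENS = {"", "na", "nan"}
_META_COLS = ("sample_id", "month", "completeness")


class ProfileParseError(ValueError):
    pass


def read_profile_csv(
    path,
    roles: Mapping[str, str] | None = None,
    id_col: str = "sample_id",
    label_col: str = "month",
) -> ProfileMatrix:
    """Read a profile matrix from CSV.

    The file needs a header row; ``sample_id`` and ``month`` columns are
    used when present, all remaining columns are variables. The mask is
    derived from NA cells, completeness tags from the mask. Variable roles
    come from the ``roles`` mapping when given, else from the default
    heuristic (mineral iff the name is one of the eight elements).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    var_cols = [c for c in df.columns if c not in _META_COLS and c != id_col and c != label_col]
    n, p = len(df), len(var_cols)
    values = np.empty((n, p))
    mask = np.ones((n, p), dtype=bool)
    for j, col in enumerate(var_cols):
        for i, tok in enumerate(df[col].tolist()):
            t = tok.strip()
            if t.lower() in _NA_TOKENS:
                values[i, j] = np.nan
                mask[i, j] = False
            else:
                try:
                    values[i, j] = float(t)
                except ValueError:
                    raise ProfileParseError(
                        f"non-numeric value {tok!r} at row {i + 2}, column {col!r}"
                    ) from None
    sample_ids = (
        df[id_col].tolist() if id_col in df.columns else [f"S{i:03d}" for i in range(n)]
    )
    if len(set(sample_ids)) != n:
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ProfileParseError(f"duplicate sample ids: {dup}")
    labels = df[label_col].tolist() if label_col in df.columns else ["unlabelled"] * n
    if roles is not None:
        var_roles = [roles[v] if v in roles else infer_roles([v])[0] for v in var_cols]
    else:
        var_roles = infer_roles(var_cols)
    return ProfileMatrix(
        values=values,
        mask=mask,
        sample_ids=sample_ids,
        labels=labels,
        completeness=completeness_from_mask(mask),
        var_names=var_cols,
        var_roles=var_roles,
    )


def write_profile_csv(matrix: ProfileMatrix, path) -> Path:
    """Write a profile matrix; unobserved cells become "NA"."""
    path = Path(path)
    df = matrix.to_dataframe()
    # full-precision repr so read(write(x)) is the identity on observed cells
    for col in matrix.var_names:
        df[col] = [
            "NA" if not np.isfinite(v) else repr(float(v)) for v in df[col].tolist()
        ]
    df.to_csv(path, index=False, na_rep="NA")
    return path


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------
def metric_curve_frame(curve: MetricCurve) -> pd.DataFrame:
    df = pd.DataFrame(
        curve.per_iteration,
        columns=[f"iter_{i}" for i in range(curve.per_iteration.shape[1])],
    )
    df.insert(0, "mean", curve.mean_metric)
    df.insert(0, "order", curve.orders)
    return df


def write_metric_curve_csv(curve: MetricCurve, path) -> Path:
    path = Path(path)
    df = metric_curve_frame(curve)
    df.to_csv(path, index=False, float_format=None)
    return path


def read_metric_curve_csv(path, metric_name: str = "", higher_is_better: bool = True) -> MetricCurve:
    df = pd.read_csv(path)
    iters = [c for c in df.columns if c.startswith("iter_")]
    return MetricCurve(
        metric_name=metric_name,
        orders=[int(o) for o in df["order"]],
        per_iteration=df[iters].to_numpy(),
        higher_is_better=higher_is_better,
    )


def write_report(
    curves: Mapping[str, MetricCurve],
    out_dir,
    prefix: str = "report",
    models: Mapping[str, dict] | None = None,
    tables: Mapping[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write validation curves (CSV), a JSON summary, and optional extras.

    ``models`` maps names to already-serialized model dicts (e.g.
    ``PPCAResults.to_dict()``); ``tables`` to DataFrames such as score or
    loading coordinates for plotting.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"curves": {}}
    for name, curve in curves.items():
        p = write_metric_curve_csv(curve, out_dir / f"{prefix}_{name}.csv")
        written.append(p)
        summary["curves"][name] = {
            "metric_name": curve.metric_name,
            "orders": list(curve.orders),
            "mean_metric": curve.mean_metric.tolist(),
            "selected_order": curve.selected_order,
            "best_mean": curve.best_mean,
            "file": p.name,
        }
    if models:
        summary["models"] = dict(models)
    if tables:
        for name, df in tables.items():
            p = out_dir / f"{prefix}_{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    sp = out_dir / f"{prefix}_summary.json"
    sp.write_text(json.dumps(_jsonable(summary), indent=2))
    written.append(sp)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
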