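"""Core data container for sample-by-variable concentration profiles.

A :class:`ProfileMatrix` holds a samples x variables matrix of concentrations
(fatty acids as % FAME, minerals as % w/w) together with an observation mask,
per-sample production-month labels and complete/partial tags, and per-variable
roles. It is the object every other module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical production months of the study design, in seasonal order.
MONTHS: tuple[str, ...] = ("January", "April", "June")

#: The eight minerals quantified alongside the fatty-acid profile.
MINERALS: tuple[str, ...] = ("Ca", "Mg", "Na", "K", "P", "S", "Zn", "Fe")

ROLE_FAME = "FAME"
ROLE_MINERAL = "mineral"

COMPLETE = "complete"
PARTIAL = "partial"


class ProfileMatrixError(ValueError):
    """Raised for inconsistent profile-matrix construction or parsing."""


def _as_str_list(x: Iterable, n: int, what: str) -> list[str]:
    out = [str(v) for v in x]
    if len(out) != n:
        raise ProfileMatrixError(f"{what} has length {len(out)}, expected {n}")
    return out


@dataclass
class ProfileMatrix:
    """Concentration matrix with missingness mask and sample/variable metadata.

    Parameters
    ----------
    values : ndarray, shape (n, p)
        Concentrations. Entries where ``mask`` is False are undefined (stored
        as NaN) and are never read by downstream code.
    mask : ndarray of bool, shape (n, p)
        True where the entry is observed.
    sample_ids, labels, completeness : sequences of length n
        Identifier, production month, and "complete"/"partial" tag per sample.
    var_names, var_roles : sequences of length p
        Variable name and role ("FAME" or "mineral").
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    completeness: list[str] = field(default_factory=list)
    var_names: list[str] = field(default_factory=list)
    var_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ProfileMatrixError("values must be 2-D")
        n, p = self.values.shape
        if self.mask.shape != (n, p):
            raise ProfileMatrixError(
                f"mask shape {self.mask.shape} != values shape {(n, p)}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(n)]
        if not self.labels:
            self.labels = ["unlabelled"] * n
        if not self.var_names:
            self.var_names = [f"V{j:03d}" for j in range(p)]
        if not self.var_roles:
            self.var_roles = infer_roles(self.var_names)
        if not self.completeness:
            self.completeness = completeness_from_mask(self.mask)
        self.sample_ids = _as_str_list(self.sample_ids, n, "sample_ids")
        self.labels = _as_str_list(self.labels, n, "labels")
        self.completeness = _as_str_list(self.completeness, n, "completeness")
        self.var_names = _as_str_list(self.var_names, p, "var_names")
        self.var_roles = _as_str_list(self.var_roles, p, "var_roles")
        if len(set(self.sample_ids)) != n:
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ProfileMatrixError(f"duplicate sample ids: {dup}")
        bad_roles = sorted(set(self.var_roles) - {ROLE_FAME, ROLE_MINERAL})
        if bad_roles:
            raise ProfileMatrixError(f"unknown variable roles: {bad_roles}")
        for i, tag in enumerate(self.completeness):
            row_obs = self.mask[i]
            if tag == COMPLETE and not row_obs.all():
                raise ProfileMatrixError(
                    f"sample {self.sample_ids[i]} tagged complete but has "
                    f"{int((~row_obs).sum())} missing entries"
                )
            if tag == PARTIAL and row_obs.all():
                raise ProfileMatrixError(
                    f"sample {self.sample_ids[i]} tagged partial but is fully observed"
                )
            if tag not in (COMPLETE, PARTIAL):
                raise ProfileMatrixError(f"unknown completeness tag {tag!r}")
        # keep unobserved cells undefined on a single canonical value
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan

    # -- basic geometry -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def fame_idx(self) -> np.ndarray:
        return np.array([r == ROLE_FAME for r in self.var_roles])

    @property
    def mineral_idx(self) -> np.ndarray:
        return np.array([r == ROLE_MINERAL for r in self.var_roles])

    @property
    def complete_idx(self) -> np.ndarray:
        return np.array([c == COMPLETE for c in self.completeness])

    def subset(self, rows: Sequence[int] | np.ndarray) -> "ProfileMatrix":
        """Row subset (copy) preserving all metadata."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return ProfileMatrix(
            values=self.values[rows],
            mask=self.mask[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            labels=[self.labels[i] for i in rows],
            completeness=[self.completeness[i] for i in rows],
            var_names=list(self.var_names),
            var_roles=list(self.var_roles),
        )

    def subset_ids(self, ids: Sequence[str]) -> "ProfileMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ProfileMatrixError(f"unknown sample ids: {missing}")
        return self.subset([index[s] for s in ids])

    def copy(self) -> "ProfileMatrix":
        return replace(
            self,
            values=self.values.copy(),
            mask=self.mask.copy(),
            sample_ids=list(self.sample_ids),
            labels=list(self.labels),
            completeness=list(self.completeness),
            var_names=list(self.var_names),
            var_roles=list(self.var_roles),
        )

    def with_values_mask(self, values: np.ndarray, mask: np.ndarray) -> "ProfileMatrix":
        """New matrix with replaced values/mask; completeness tags re-derived."""
        return ProfileMatrix(
            values=values,
            mask=mask,
            sample_ids=list(self.sample_ids),
            labels=list(self.labels),
            completeness=completeness_from_mask(np.asarray(mask, bool)),
            var_names=list(self.var_names),
            var_roles=list(self.var_roles),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Wide DataFrame with sample_id/month/completeness columns then variables."""
        df = pd.DataFrame(self.values, columns=self.var_names)
        df.insert(0, "completeness", self.completeness)
        df.insert(0, "month", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def completeness_from_mask(mask: np.ndarray) -> list[str]:
    """Tag each row complete iff every entry is observed, partial otherwise."""
    return [COMPLETE if row.all() else PARTIAL for row in np.asarray(mask, bool)]


def infer_roles(var_names: Sequence[str]) -> list[str]:
    """Default role heuristic: mineral iff the name is one of the 8 elements."""
    mineral_set = set(MINERALS)
    return [ROLE_MINERAL if v in mineral_set else ROLE_FAME for v in var_names]
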