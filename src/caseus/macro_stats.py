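"""Tukey HSD comparisons of macro-composition parameters from summary stats.

The macro-composition of the cheese (pH, moisture, fat and protein on dry
matter, NaCl, ash, proteolysis indices) is compared across the three
production months with Tukey's honestly-significant-difference test computed
directly from per-group mean, standard deviation and sample size:

    MSE  = pooled within-group variance  = sum (n_i - 1) s_i^2 / sum (n_i - 1)
    q_ij = |m_i - m_j| / sqrt( (MSE / 2) (1/n_i + 1/n_j) )

with p-values from the studentized range distribution with k groups and
sum(n_i - 1) error degrees of freedom. Unequal group sizes use the
Tukey-Kramer harmonic correction above. Group means that do not differ at
the chosen alpha share a compact-display letter.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .core import MONTHS


class MacroStatsError(ValueError):
    pass


# Reference seasonal macro-composition summary for Pecorino Romano PDO
# (mean, SD per production month; w/w % unless noted). Per-month sample size
# is not part of the summary; n = 15 (45 samples over 3 months) is the
# package default assumption.
MACRO_COMPOSITION_CSV = """\
parameter,January_mean,January_sd,April_mean,April_sd,June_mean,June_sd
pH,5.07,0.12,5.10,0.12,5.01,0.14
Moisture,31.86,1.43,31.51,0.97,31.57,1.05
Fat/DM,49.54,1.31,47.60,1.40,50.58,1.28
Protein/DM,36.65,0.94,38.22,1.12,35.43,1.10
Fat/Protein,1.35,0.05,1.25,0.05,1.43,0.06
NaCl,4.48,0.88,4.59,0.83,5.02,0.98
Ash,7.20,0.83,7.48,0.81,7.57,0.95
SN/TN,14.95,2.25,14.28,3.11,13.99,2.07
SN-TCA/TN,21.21,2.13,11.92,2.36,11.22,2.24
SN-PTA/TN,9.71,2.51,9.27,1.79,9.08,1.89
"""


def macro_composition_table() -> pd.DataFrame:
    """Long-format reference table: parameter, group, mean, sd, n (default 15)."""
    wide = pd.read_csv(StringIO(MACRO_COMPOSITION_CSV))
    rows = []
    for _, r in wide.iterrows():
        for month in MONTHS:
            rows.append(
                {
                    "parameter": r["parameter"],
                    "group": month,
                    "mean": r[f"{month}_mean"],
                    "sd": r[f"{month}_sd"],
                    "n": 15,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TukeyResult:
    """All pairwise comparisons of one parameter."""

    groups: list[str]
    means: np.ndarray
    pairs: list[tuple[str, str]]
    q_stats: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    df_error: int
    mse: float
    letters: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_1": [a for a, _ in self.pairs],
                "group_2": [b for _, b in self.pairs],
                "q": self.q_stats,
                "p_value": self.p_values,
                "significant": self.significant,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Tukey HSD from summary statistics (alpha={self.alpha}, "
            f"df={self.df_error}, MSE={self.mse:.4g})",
        ]
        for (a, b), q, p, s in zip(self.pairs, self.q_stats, self.p_values, self.significant):
            mark = "*" if s else " "
            lines.append(f"  {a:>8s} vs {b:<8s}  q={q:7.3f}  p={p:7.4f} {mark}")
        lines.append(
            "  letters: " + ", ".join(f"{g}={self.letters[g]}" for g in self.groups)
        )
        return "\n".join(lines)


def tukey_from_summary(
    means, sds, ns, groups=None, alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD pairwise comparisons from per-group (mean, sd, n).

    Zero pooled variance is handled by convention: p = 1 for equal means,
    p = 0 for unequal means.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    k = means.size
    if k < 2:
        raise MacroStatsError("need at least 2 groups")
    if sds.size != k or ns.size != k:
        raise MacroStatsError("means, sds, ns must have equal length")
    if (ns < 2).any():
        raise MacroStatsError("every group needs n >= 2")
    if (sds < 0).any():
        raise MacroStatsError("standard deviations must be non-negative")
    if groups is None:
        groups = [f"g{i + 1}" for i in range(k)]
    groups = [str(g) for g in groups]

    df_error = int(np.sum(ns - 1))
    mse = float(np.sum((ns - 1) * sds**2) / df_error)
    pairs, qs, ps = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse <= 0:
                q = np.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            else:
                q = diff / np.sqrt(0.5 * mse * (1.0 / ns[i] + 1.0 / ns[j]))
                p = float(studentized_range.sf(q, k, df_error))
            pairs.append((groups[i], groups[j]))
            qs.append(q)
            ps.append(p)
    qs = np.asarray(qs)
    ps = np.asarray(ps)
    sig = ps < alpha
    letters = assign_letters(
        {pair: bool(s) for pair, s in zip(pairs, sig)}, dict(zip(groups, means))
    )
    return TukeyResult(
        groups=groups,
        means=means,
        pairs=pairs,
        q_stats=qs,
        p_values=ps,
        significant=sig,
        alpha=alpha,
        df_error=df_error,
        mse=mse,
        letters=letters,
    )


def assign_letters(
    significant: dict[tuple[str, str], bool], means: dict[str, float]
) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Insert-and-absorb construction; letters are assigned in order of the
    descending mean of each letter set's best member, so the highest mean
    always carries "a".
    """
    groups = sorted(means, key=lambda g: -means[g])
    sig = {}
    for (a, b), s in significant.items():
        sig[(a, b)] = s
        sig[(b, a)] = s
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
        if not sig.get((a, b), False):
            continue
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets += [s - {a}, s - {b}]
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = []
        for s in new_sets:
            if any(s < t for t in new_sets) or s in letter_sets:
                continue
            letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def tukey_table(
    stats: pd.DataFrame | None = None, alpha: float = 0.05, default_n: int = 15
) -> pd.DataFrame:
    """Run Tukey comparisons for every parameter of a long-format table.

    ``stats`` needs columns parameter, group, mean, sd and optionally n;
    defaults to the built-in seasonal macro-composition reference.
    Returns one row per parameter/pair with p-values and the letter display.
    """
    if stats is None:
        stats = macro_composition_table()
    stats = stats.copy()
    if "n" not in stats.columns:
        stats["n"] = default_n
    rows = []
    for param, grp in stats.groupby("parameter", sort=False):
        res = tukey_from_summary(
            grp["mean"].to_numpy(),
            grp["sd"].to_numpy(),
            grp["n"].to_numpy(),
            groups=grp["group"].tolist(),
            alpha=alpha,
        )
        for (a, b), q, p, s in zip(res.pairs, res.q_stats, res.p_values, res.significant):
            rows.append(
                {
                    "parameter": param,
                    "group_1": a,
                    "group_2": b,
                    "q": q,
                    "p_value": p,
                    "significant": s,
                    "letters": "; ".join(f"{g}:{res.letters[g]}" for g in res.groups),
                }
            )
    return pd.DataFrame(rows)
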