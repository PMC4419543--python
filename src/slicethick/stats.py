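"""Study-level statistics: thickness error, ANOVA and Tukey HSD grouping.

A sectioning study measures several slices per (step size, speed) cell.  The
accuracy metric per cell is the relative thickness error

    error% = (mean measured thickness - step size) / step size x 100

and the per-tissue overall error is the plain average of the defined cell
errors (cells where no slices were obtained contribute nothing).  Effects of
step size and speed on thickness are tested with fixed-effects ANOVA
(two-way with interaction when both factors vary, one-way otherwise),
followed by Tukey's honestly-significant-difference test; groups are
summarised with a compact letter display where sharing a letter means "not
significantly different" at alpha = 0.05.

ANOVA model fitting is delegated to statsmodels (OLS + anova_lm); the letter
display uses the insert-and-absorb algorithm, which guarantees the sharing
relation reproduces the thresholded pairwise-significance matrix exactly.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError

__all__ = [
    "thickness_error_pct",
    "summarize_combos",
    "overall_error",
    "two_way_anova",
    "one_way_anova",
    "tukey_grouping",
    "compact_letter_display",
    "TukeyGrouping",
]

REQUIRED_COLUMNS = ("tissue", "step_size_um", "speed_mm_s", "thickness_um")


def thickness_error_pct(mean_um, step_size_um):
    """Relative thickness error in percent: (mean - step)/step x 100.

    Works elementwise on scalars, arrays or Series.  Invariant to any unit
    change applied consistently to both arguments.
    """
    mean_um = np.asanyarray(mean_um, dtype=float)
    step = np.asanyarray(step_size_um, dtype=float)
    if np.any(step <= 0):
        raise ValidationError("step_size_um must be > 0")
    out = (mean_um - step) / step * 100.0
    return out if out.ndim else float(out)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if records is None or len(records) == 0:
        raise ValidationError("empty record table")
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"record table lacks columns {missing}")
    if (records["thickness_um"] <= 0).any():
        raise ValidationError("thickness_um values must be > 0")
    return records


def summarize_combos(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per (tissue, step, speed) cell: n, mean, SD and thickness error.

    Only cells present in the records yield a row; absent cells (no slices
    obtained) are explicitly missing rather than zero.  SD uses the sample
    (n-1) formula; single-slice cells get NaN SD.
    """
    _check_records(records)
    grouped = (
        records.groupby(["tissue", "step_size_um", "speed_mm_s"], sort=True)[
            "thickness_um"
        ]
        .agg(n="size", mean_um="mean", sd_um=lambda v: v.std(ddof=ddof))
        .reset_index()
    )
    grouped["error_pct"] = thickness_error_pct(
        grouped["mean_um"], grouped["step_size_um"]
    )
    return grouped


def overall_error(combos: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue overall thickness error: the mean of the cell errors.

    Carried at full precision; see
    :func:`slicethick.datasets.overall_error_discrepancies` for how this can
    differ in the last decimal from a value computed on rounded cell means.
    """
    if combos is None or len(combos) == 0:
        raise ValidationError("no combo summaries to average")
    combos = combos.dropna(subset=["error_pct"])
    if len(combos) == 0:
        raise ValidationError("no combo has a defined error_pct")
    out = (
        combos.groupby("tissue", sort=False)["error_pct"]
        .agg(n_combos="size", overall_error_pct="mean")
        .reset_index()
    )
    return out


def _tidy_anova(table: pd.DataFrame, rename: dict) -> pd.DataFrame:
    out = table.rename(index=rename).rename(
        columns={"df": "df", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}
    )
    out["mean_sq"] = out["sum_sq"] / out["df"]
    return out[["df", "sum_sq", "mean_sq", "F", "p"]]


def two_way_anova(
    records: pd.DataFrame,
    factor_a: str = "step_size_um",
    factor_b: str = "speed_mm_s",
    response: str = "thickness_um",
    interaction: bool = True,
    typ: int | None = None,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA of ``response`` on two crossed factors.

    ``typ`` selects the sums-of-squares decomposition: Type I on balanced
    designs (where all types coincide), Type II otherwise -- chosen
    automatically when None.  Requires >= 2 levels per factor, and >= 2
    observations per cell when the interaction term is included.

    Returns a tidy table indexed by effect (factor names, ``A:B`` for the
    interaction, ``residual``) with columns df, sum_sq, mean_sq, F, p.
    """
    if records is None or len(records) == 0:
        raise ValidationError("empty record table")
    for f in (factor_a, factor_b, response):
        if f not in records.columns:
            raise ValidationError(f"missing column {f!r}")
    for f in (factor_a, factor_b):
        if records[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has < 2 levels")
    cell_sizes = records.groupby([factor_a, factor_b]).size()
    if interaction and (cell_sizes < 2).any():
        raise ValidationError(
            "cells with a single observation cannot support an interaction "
            "term; call with interaction=False"
        )
    if typ is None:
        typ = 1 if cell_sizes.nunique() == 1 else 2
    op = "*" if interaction else "+"
    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))", data=records
    ).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    rename = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    }
    return _tidy_anova(table, rename)


def one_way_anova(
    records: pd.DataFrame,
    factor: str = "step_size_um",
    response: str = "thickness_um",
) -> pd.DataFrame:
    """Fixed-effects one-way ANOVA (used when only one parameter was varied)."""
    if records is None or len(records) == 0:
        raise ValidationError("empty record table")
    if factor not in records.columns or response not in records.columns:
        raise ValidationError(f"missing column {factor!r} or {response!r}")
    if records[factor].nunique() < 2:
        raise ValidationError(f"factor {factor!r} has < 2 levels")
    model = smf.ols(f"Q('{response}') ~ C(Q('{factor}'))", data=records).fit()
    table = sm.stats.anova_lm(model, typ=1)
    return _tidy_anova(table, {f"C(Q('{factor}'))": factor, "Residual": "residual"})


@dataclass(frozen=True)
class TukeyGrouping:
    """Tukey HSD post-hoc result with compact letters.

    ``letters[g]`` is the letter set of group ``g``; two groups are *not*
    significantly different at ``alpha`` exactly when their letter sets
    intersect.  ``p_values`` is the symmetric matrix of HSD-adjusted p-values.
    """

    groups: tuple
    means: dict
    letters: dict
    p_values: pd.DataFrame
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.groups),
                "mean": [self.means[g] for g in self.groups],
                "letters": ["".join(sorted(self.letters[g])) for g in self.groups],
            }
        )


def _letter_symbols():
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def compact_letter_display(groups, different) -> dict:
    """Insert-and-absorb compact letter display.

    Parameters
    ----------
    groups : sequence of hashable labels.
    different : callable (g1, g2) -> bool
        True when the pair is significantly different.

    Returns
    -------
    dict mapping each group to a frozenset of letters such that two groups
    share a letter **iff** ``different`` is False for the pair.  This "iff"
    both ways is a property of insert-and-absorb: splitting a column on a
    significant pair never separates a non-significant one, and absorption
    only removes redundant subset columns.
    """
    groups = list(groups)
    columns: list[set] = [set(groups)]
    for g1, g2 in itertools.combinations(groups, 2):
        if not different(g1, g2):
            continue
        new_columns: list[set] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            col
            for i, col in enumerate(new_columns)
            if col
            and not any(
                col < other or (col == other and i > j)
                for j, other in enumerate(new_columns)
            )
        ]
    letters: dict = {g: set() for g in groups}
    for sym, col in zip(_letter_symbols(), columns):
        for g in col:
            letters[g].add(sym)
    return {g: frozenset(v) for g, v in letters.items()}


def tukey_grouping(
    records: pd.DataFrame,
    factor: str = "step_size_um",
    response: str = "thickness_um",
    by_cell: bool = False,
    alpha: float = 0.05,
) -> TukeyGrouping:
    """All-pairwise Tukey HSD comparisons with a compact letter display.

    With ``by_cell=True`` the groups are the step x speed cells jointly
    (labels ``"step/speed"``), mirroring per-cell bar plots; otherwise the
    groups are the levels of ``factor``.
    """
    if records is None or len(records) == 0:
        raise ValidationError("empty record table")
    if by_cell:
        labels = (
            records["step_size_um"].astype(str) + "/" + records["speed_mm_s"].astype(str)
        )
    else:
        labels = records[factor].astype(str)
    if labels.nunique() < 2:
        raise ValidationError("need >= 2 groups for pairwise comparisons")
    values = records[response].to_numpy(dtype=float)
    hsd = pairwise_tukeyhsd(values, labels.to_numpy(), alpha=alpha)
    group_names = tuple(hsd.groupsunique)
    pmat = pd.DataFrame(1.0, index=group_names, columns=group_names)
    for (g1, g2), p in zip(itertools.combinations(group_names, 2), hsd.pvalues):
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = float(p)
    letters = compact_letter_display(
        group_names, lambda a, b: pmat.loc[a, b] < alpha
    )
    means = {
        g: float(values[labels.to_numpy() == g].mean()) for g in group_names
    }
    return TukeyGrouping(group_names, means, letters, pmat, alpha=alpha)
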