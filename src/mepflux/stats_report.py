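"""Group statistics for treatment comparisons.

One-way ANOVA across drought treatments, Tukey's HSD post hoc test with a
compact letter display (groups sharing no letter differ at the chosen
alpha), Shapiro-Wilk normality checks, and percent-/fold-change effect
summaries against the control group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TreatmentGroups",
    "LetterDisplay",
    "one_way_anova",
    "tukey_hsd",
    "compact_letters",
    "shapiro_wilk",
    "effect_summary",
    "report_table",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class TreatmentGroups:
    """Replicate values per treatment group for one measured variable."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]
    variable_id: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must have equal length")
        if len(self.labels) < 2:
            raise ValueError("at least 2 groups are required")
        vals = tuple(np.asarray(v, dtype=float) for v in self.values)
        for lab, v in zip(self.labels, vals):
            if v.size < 2:
                raise ValueError(f"group {lab!r} needs >= 2 replicates")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variable_id: str = "",
                   group_col: str = "treatment", value_col: str = "value"):
        labels, values = [], []
        for lab, grp in df.groupby(group_col, sort=False):
            labels.append(str(lab))
            values.append(grp[value_col].to_numpy(dtype=float))
        return cls(tuple(labels), tuple(values), variable_id)


@dataclass(frozen=True)
class LetterDisplay:
    """Compact significance letters per group at a given alpha."""

    labels: tuple[str, ...]
    letters: tuple[str, ...]
    alpha: float = 0.05

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.labels, self.letters))


def one_way_anova(groups: TreatmentGroups) -> tuple[float, float, tuple[int, int]]:
    """Classical one-way fixed-effects ANOVA.

    Returns (F, p, (df_between, df_within)).  Groups with identical values
    throughout yield F = 0, p = 1.
    """
    vals = groups.values
    k = len(vals)
    n = sum(v.size for v in vals)
    df = (k - 1, n - k)
    grand = np.concatenate(vals).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in vals)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0, df
        return float("inf"), 0.0, df
    f_stat = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(f_stat, *df))
    return float(f_stat), p, df


def tukey_hsd(groups: TreatmentGroups, alpha: float = 0.05):
    """Tukey's HSD pairwise comparisons (Tukey-Kramer for unbalanced data).

    Returns a DataFrame indexed by group pairs with the studentized-range
    adjusted p-value and a significance flag at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    res = sps.tukey_hsd(*groups.values)
    rows = []
    for i, j in itertools.combinations(range(len(groups.labels)), 2):
        p = float(res.pvalue[i, j])
        rows.append({
            "group_1": groups.labels[i],
            "group_2": groups.labels[j],
            "p_adj": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)


def _insert_absorb(sets: list[set[int]]) -> list[set[int]]:
    # drop duplicates and letter sets fully contained in another
    uniq: list[set[int]] = []
    for s in sets:
        if s and s not in uniq:
            uniq.append(s)
    return [s for s in uniq if not any(s < t for t in uniq)]


def compact_letters(
    pairwise_significant: np.ndarray,
    group_order: tuple[str, ...] | list[str],
    alpha: float = 0.05,
) -> LetterDisplay:
    """Compact letter display from a pairwise-significance matrix.

    ``pairwise_significant`` is a symmetric boolean matrix; entry (i, j)
    True means groups i and j differ significantly.  Uses the
    insertion-absorption algorithm: two groups share a letter exactly when
    their comparison is non-significant.
    """
    sig = np.asarray(pairwise_significant, dtype=bool)
    k = len(group_order)
    if sig.shape != (k, k):
        raise ValueError("pairwise matrix must be k x k for k groups")
    if not np.array_equal(sig, sig.T) or np.any(np.diag(sig)):
        raise ValueError("pairwise matrix must be symmetric with a False diagonal")

    letter_sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        new_sets: list[set[int]] = []
        for s in letter_sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        letter_sets = _insert_absorb(new_sets)

    # deterministic letter order: by smallest member in group order
    letter_sets.sort(key=lambda s: sorted(s))
    if len(letter_sets) > len(_LETTERS):
        raise ValueError("too many letter groups")
    per_group = []
    for g in range(k):
        word = "".join(_LETTERS[idx] for idx, s in enumerate(letter_sets) if g in s)
        per_group.append(word)
    return LetterDisplay(tuple(group_order), tuple(per_group), alpha)


def letters_from_tukey(groups: TreatmentGroups, alpha: float = 0.05) -> LetterDisplay:
    """Tukey HSD followed by compact-letter assignment."""
    tk = tukey_hsd(groups, alpha)
    k = len(groups.labels)
    sig = np.zeros((k, k), dtype=bool)
    index = {lab: i for i, lab in enumerate(groups.labels)}
    for rec in tk.itertuples():
        i, j = index[rec.group_1], index[rec.group_2]
        sig[i, j] = sig[j, i] = rec.significant
    return compact_letters(sig, groups.labels, alpha)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def effect_summary(groups: TreatmentGroups, control: str = "control") -> pd.DataFrame:
    """Per-group mean, SE, and percent/fold change relative to control.

    Percent change is the decrease 100 (mean_ctrl − mean_trt)/mean_ctrl
    (negative for increases); fold change is mean_trt / mean_ctrl.  Both
    are NaN-flagged when the control mean is zero.
    """
    if control not in groups.labels:
        raise ValueError(f"control group {control!r} not present")
    means = {lab: float(v.mean()) for lab, v in zip(groups.labels, groups.values)}
    ctrl_mean = means[control]
    rows = []
    for lab, v in zip(groups.labels, groups.values):
        se = float(v.std(ddof=1) / np.sqrt(v.size))
        if ctrl_mean == 0:
            warnings.warn("control mean is zero; percent/fold change undefined",
                          UserWarning, stacklevel=2)
            pct, fold = np.nan, np.nan
        else:
            pct = 100.0 * (ctrl_mean - means[lab]) / ctrl_mean
            fold = means[lab] / ctrl_mean
        rows.append({"group": lab, "n": v.size, "mean": means[lab], "se": se,
                     "percent_change_vs_control": pct, "fold_change_vs_control": fold})
    return pd.DataFrame(rows)


def report_table(
    data: pd.DataFrame,
    alpha: float = 0.05,
    control: str = "control",
) -> pd.DataFrame:
    """Full statistical report for a tidy measurement table.

    ``data`` has columns variable_id, treatment, tree_id, value.  For each
    variable: ANOVA F and p, Shapiro-Wilk p on residuals, Tukey letters,
    per-group mean ± SE and effect sizes vs. control.
    """
    req = {"variable_id", "treatment", "value"}
    if not req.issubset(data.columns):
        raise ValueError(f"data needs columns {sorted(req)}")
    rows = []
    for var, sub in data.groupby("variable_id", sort=False):
        groups = TreatmentGroups.from_frame(sub, variable_id=str(var))
        f_stat, p, _ = one_way_anova(groups)
        resid = np.concatenate([v - v.mean() for v in groups.values])
        try:
            _, shapiro_p = shapiro_wilk(resid)
        except ValueError:
            shapiro_p = np.nan
        if not np.isnan(shapiro_p) and shapiro_p < alpha:
            warnings.warn(f"{var}: residuals depart from normality "
                          f"(Shapiro-Wilk p = {shapiro_p:.3g})",
                          UserWarning, stacklevel=2)
        letters = letters_from_tukey(groups, alpha).as_dict() if p < alpha else {
            lab: "a" for lab in groups.labels
        }
        eff = effect_summary(groups, control=control)
        for rec in eff.itertuples():
            rows.append({
                "variable_id": var, "group": rec.group, "n": rec.n,
                "mean": rec.mean, "se": rec.se,
                "percent_change_vs_control": rec.percent_change_vs_control,
                "fold_change_vs_control": rec.fold_change_vs_control,
                "anova_F": f_stat, "anova_p": p, "shapiro_p": shapiro_p,
                "letters": letters[rec.group],
            })
    return pd.DataFrame(rows)
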