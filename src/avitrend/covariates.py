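"""Derived covariates: abundance quartile classes and collinearity screens.

Species are ranked by their population point estimate and split into four
contiguous classes of (as near as possible) equal size, labelled rare,
scarce, common and abundant from the bottom quartile up.  Associations
between candidate predictors are screened pairwise with the statistic
matched to the variable types: Pearson's r (continuous–continuous),
Cramér's V (nominal–nominal), and R² from a single-term regression
(continuous–nominal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PopulationEstimate, ValidationError

QUARTILE_LABELS = ("rare", "scarce", "common", "abundant")


@dataclass(frozen=True)
class AbundanceClass:
    species_id: str
    abundance_class: str


def assign_quartiles(
    estimates: list[PopulationEstimate],
    labels: tuple[str, ...] = QUARTILE_LABELS,
) -> list[AbundanceClass]:
    """Equal-count abundance classes from ranked point estimates.

    Species are sorted ascending by point estimate (ties broken by stable
    species_id order) and split into four contiguous classes.  When n is not
    divisible by 4 the remainder goes to the rarer classes first, keeping
    "abundant" strictly the top quartile.
    """
    n = len(estimates)
    if n < 4:
        raise ValueError("need at least 4 species to form quartiles")
    ids = [e.species_id for e in estimates]
    if len(set(ids)) != n:
        raise ValidationError("duplicate species in estimates")
    order = sorted(range(n), key=lambda i: (estimates[i].point, ids[i]))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    out: list[AbundanceClass] = [None] * n  # type: ignore[list-item]
    pos = 0
    for q, size in enumerate(sizes):
        for i in order[pos : pos + size]:
            out[i] = AbundanceClass(ids[i], labels[q])
        pos += size
    return out


def cramers_v(x, y) -> float:
    """Cramér's V for two nominal variables (in [0, 1])."""
    table = pd.crosstab(pd.Series(x), pd.Series(y))
    if table.size == 0 or min(table.shape) < 2:
        return np.nan
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.to_numpy().sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def _anova_r2(cont: np.ndarray, nom) -> float:
    """R² of a single-term regression of a continuous on a nominal variable."""
    df = pd.DataFrame({"y": cont, "g": pd.Categorical(nom)})
    grand = df["y"].mean()
    ss_tot = float(((df["y"] - grand) ** 2).sum())
    if ss_tot == 0:
        return np.nan
    ss_between = float(
        df.groupby("g", observed=True)["y"]
        .agg(lambda v: len(v) * (v.mean() - grand) ** 2)
        .sum()
    )
    return ss_between / ss_tot


def collinearity_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise association statistics for a mixed covariate table.

    Returns a long-format frame with columns ``var1, var2, statistic, value``
    where ``statistic`` is ``pearson_r``, ``cramers_v`` or ``r2``.  Constant
    columns yield NaN (the statistic is undefined) rather than an error.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    cols = list(table.columns)
    is_cont = {c: pd.api.types.is_numeric_dtype(table[c]) for c in cols}
    rows = []
    for i, c1 in enumerate(cols):
        for c2 in cols[i + 1 :]:
            x, y = table[c1], table[c2]
            if is_cont[c1] and is_cont[c2]:
                stat = "pearson_r"
                if x.nunique() < 2 or y.nunique() < 2:
                    val = np.nan
                else:
                    val = float(stats.pearsonr(x, y)[0])
            elif not is_cont[c1] and not is_cont[c2]:
                stat = "cramers_v"
                val = cramers_v(x, y)
            else:
                stat = "r2"
                cont, nom = (x, y) if is_cont[c1] else (y, x)
                if cont.nunique() < 2 or nom.nunique() < 2:
                    val = np.nan
                else:
                    val = _anova_r2(cont.to_numpy(dtype=float), nom)
            rows.append({"var1": c1, "var2": c2, "statistic": stat, "value": val})
    return pd.DataFrame(rows)
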