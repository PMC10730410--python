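"""Carrier vs non-carrier contrasts of diagnostic-category prevalence.

For each diagnostic category, carriers and non-carriers of a risk allele
are compared with a two-sided Fisher exact test on the 2x2 table, with the
Haldane-Anscombe correction on zero cells for the odds ratio, and BH FDR
across categories. Age is compared by rank-sum, sex by Fisher; an optional
sex- and age-adjusted logistic model checks that neither drives an apparent
category association.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .association import bh_fdr

__all__ = ["carrier_contrast"]


def _table_or(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio with Haldane correction and Fisher exact p (uncorrected)."""
    _, p = stats.fisher_exact([[a, b], [c, d]])
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(p)


def carrier_contrast(
    dx: pd.DataFrame,
    carrier: pd.Series,
    categories: list[str] | None = None,
    adjusted: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-category prevalence contrast between carriers and non-carriers.

    ``dx`` holds binary category flags plus optional age/sex columns;
    ``carrier`` is a boolean series aligned to its index. Returns the
    category table (n with/without dx per group, OR, p, q) and a dict of
    demographic comparisons (age rank-sum, sex Fisher). With
    ``adjusted=True`` each category also gets a sex- and age-adjusted
    logistic coefficient for carrier status as a sensitivity model.
    """
    carrier = carrier.reindex(dx.index).astype(bool)
    n_car = int(carrier.sum())
    n_non = int((~carrier).sum())
    if n_car == 0 or n_non == 0:
        raise ValueError("need at least one carrier and one non-carrier")
    if categories is None:
        categories = [
            c for c in dx.columns
            if c not in ("age", "sex") and set(dx[c].dropna().unique()) <= {0, 1}
        ]
    rows = []
    for cat in categories:
        flags = dx[cat].astype(int)
        a = int(flags[carrier].sum())          # carriers with dx
        b = n_car - a
        c = int(flags[~carrier].sum())         # non-carriers with dx
        d = n_non - c
        or_, p = _table_or(a, b, c, d)
        row = {
            "category": cat,
            "carriers_with_dx": a, "carriers_total": n_car,
            "noncarriers_with_dx": c, "noncarriers_total": n_non,
            "or": or_, "p": p,
        }
        if adjusted and {"age", "sex"} <= set(dx.columns):
            design = sm.add_constant(
                np.column_stack([
                    carrier.to_numpy(dtype=float),
                    dx["sex"].to_numpy(dtype=float),
                    dx["age"].to_numpy(dtype=float),
                ]),
                prepend=False,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = sm.Logit(flags.to_numpy(dtype=float), design).fit(
                        disp=0, maxiter=100
                    )
                    row["adjusted_beta"] = float(fit.params[0])
                    row["adjusted_p"] = float(fit.pvalues[0])
                except (PerfectSeparationError, np.linalg.LinAlgError):
                    row["adjusted_beta"] = np.nan
                    row["adjusted_p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())

    demo: dict = {}
    if "age" in dx.columns:
        u, p_age = stats.mannwhitneyu(
            dx.loc[carrier, "age"], dx.loc[~carrier, "age"],
            alternative="two-sided",
        )
        demo["age_p"] = float(p_age)
    if "sex" in dx.columns:
        sex = dx["sex"].astype(int)
        table = [
            [int(sex[carrier].sum()), int((1 - sex[carrier]).sum())],
            [int(sex[~carrier].sum()), int((1 - sex[~carrier]).sum())],
        ]
        demo["sex_or"], demo["sex_p"] = _table_or(*np.ravel(table))
    return out, demo
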