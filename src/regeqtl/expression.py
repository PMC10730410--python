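"""Case/control differential expression with permutation empirical p-values.

The contrast follows the group-as-outcome convention: per gene, a logistic
regression of group membership on z-scored expression plus sex and age (and
a study indicator when more than one study is present), with Wald tests and
BH FDR across genes. The more conventional expression-as-outcome direction
is available behind ``direction="expression"``. Small-sample empirical
p-values permute group labels within study strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .association import bh_fdr

__all__ = ["DEResult", "de_test", "empirical_p", "sex_stratified"]


@dataclass
class DEResult:
    gene: str
    coefficient: float
    se: float
    z: float
    p: float
    q: float = float("nan")
    p_emp: float = float("nan")
    sex_specific: str = "none"


def _design(meta: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "study":
            studies = sorted(meta["study"].unique())
            for s in studies[1:]:
                cols.append((meta["study"] == s).astype(float).to_numpy())
        else:
            cols.append(meta[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(meta), 0))


def _fit_gene(
    expr_z: np.ndarray, status: np.ndarray, cov: np.ndarray
) -> tuple[float, float] | None:
    design = sm.add_constant(np.column_stack([expr_z, cov]), prepend=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(status, design).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return None
    beta, se = float(fit.params[0]), float(fit.bse[0])
    if not np.isfinite(se) or se == 0 or se > 50:
        return None
    return beta, se


def de_test(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    case_label: str = "case",
    control_label: str = "control",
    covariates: list[str] | None = None,
    direction: str = "group",
) -> pd.DataFrame:
    """Per-gene differential expression between two groups.

    ``expr`` is genes x samples; ``meta`` carries group/sex/age/study per
    sample. Expression is z-scored per gene before the fit. Genes with
    constant expression are skipped with a warning; separated fits are
    flagged by omission. Returns a table with coefficient, p and BH q.
    """
    keep = meta["group"].isin([case_label, control_label])
    meta = meta[keep]
    expr = expr.loc[:, meta.index]
    if meta["group"].nunique() < 2:
        raise ValueError("both contrast groups must be present")
    if covariates is None:
        covariates = ["sex", "age"]
        if "study" in meta and meta["study"].nunique() > 1:
            covariates = covariates + ["study"]
    status = (meta["group"] == case_label).to_numpy(dtype=float)
    cov = _design(meta, covariates)
    rows = []
    for gene, values in expr.iterrows():
        x = values.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"gene {gene}: constant expression, skipped")
            continue
        xz = (x - x.mean()) / x.std()
        if direction == "group":
            out = _fit_gene(xz, status, cov)
        elif direction == "expression":
            design = sm.add_constant(np.column_stack([status, cov]), prepend=False)
            fit = sm.OLS(xz, design).fit()
            out = float(fit.params[0]), float(fit.bse[0])
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if out is None:
            continue
        beta, se = out
        z = beta / se
        rows.append(
            {"gene": gene, "coefficient": beta, "se": se, "z": z,
             "p": float(2 * stats.norm.sf(abs(z)))}
        )
    df = pd.DataFrame(rows, columns=["gene", "coefficient", "se", "z", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = []
    return df


def empirical_p(
    observed_stat: float,
    expr_gene: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    case_label: str = "case",
    B: int = 1000,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> float:
    """Permutation p for one gene's Wald z, stratified by study.

    Group labels are permuted within study strata (preserving each study's
    case/control margin exactly); p = (b+1)/(B+1) with b the count of
    permuted |z| >= observed |z|.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x = np.asarray(expr_gene, dtype=float)
    xz = (x - x.mean()) / x.std()
    status = (meta["group"] == case_label).to_numpy(dtype=float)
    strata = (
        meta["study"].to_numpy() if "study" in meta
        else np.zeros(len(meta), dtype=int)
    )
    for s in np.unique(strata):
        labels = status[strata == s]
        if len(np.unique(labels)) < 2:
            raise ValueError(f"degenerate stratum {s!r}: one group absent")
    if covariates is None:
        covariates = ["sex", "age"]
        if "study" in meta and meta["study"].nunique() > 1:
            covariates = covariates + ["study"]
    cov = _design(meta, covariates)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(B):
        perm = status.copy()
        for s in np.unique(strata):
            mask = strata == s
            perm[mask] = rng.permutation(perm[mask])
        out = _fit_gene(xz, perm, cov)
        if out is None:
            continue
        beta, se = out
        if abs(beta / se) >= abs(observed_stat):
            b += 1
    return (b + 1) / (B + 1)


def sex_stratified(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    case_label: str = "case",
    control_label: str = "control",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Sex-specific differential-expression calls.

    Runs the contrast separately per sex and labels a gene male-specific
    when q < 0.05 in males but > 0.05 in females (and vice versa); genes
    significant in both sexes get ``none``. If a sex is absent from either
    group its stratum is skipped and no specificity is assigned.
    """
    results = {}
    for sex, label in ((1, "male"), (0, "female")):
        sub = meta[meta["sex"] == sex]
        if sub.empty or sub["group"].nunique() < 2:
            warnings.warn(f"{label} stratum absent or degenerate; skipped")
            continue
        res = de_test(
            expr.loc[:, sub.index], sub, case_label, control_label,
            covariates=["age"] + (["study"] if "study" in sub and sub["study"].nunique() > 1 else []),
        )
        results[label] = res.set_index("gene")["q"]
    if set(results) != {"male", "female"}:
        return pd.DataFrame(columns=["gene", "q_male", "q_female", "sex_specific"])
    genes = results["male"].index.intersection(results["female"].index)
    qm = results["male"].loc[genes]
    qf = results["female"].loc[genes]
    call = np.where(
        (qm < fdr_threshold) & (qf > fdr_threshold), "male",
        np.where((qf < fdr_threshold) & (qm > fdr_threshold), "female", "none"),
    )
    return pd.DataFrame(
        {"gene": genes, "q_male": qm.to_numpy(), "q_female": qf.to_numpy(),
         "sex_specific": call}
    ).reset_index(drop=True)
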