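"""Replication of index eQTLs against independent cohorts.

Aggregate allele-frequency resources provide only AC/AN per variant, so the
contrast reconstructs the 2x2 allele-count table, tests it with a two-sided
Fisher exact test, and reports the allelic odds ratio with a Woolf (log)
confidence interval. A locus replicates only when the independent case
cohort differs from controls at the nominal level AND every contrast agrees
in direction with the discovery (WGS) effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CohortFrequency", "AFContrast", "af_contrast", "cross_cohort_confirm"]


@dataclass(frozen=True)
class CohortFrequency:
    """Alt-allele count / total allele number for one variant in one cohort."""

    variant_id: str
    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.an < 0 or not 0 <= self.ac <= self.an:
            raise ValueError(
                f"invalid allele counts ac={self.ac}, an={self.an} "
                f"for {self.variant_id}"
            )

    @property
    def af(self) -> float:
        if self.an == 0:
            raise ValueError(f"an=0 for {self.variant_id}")
        return self.ac / self.an


@dataclass(frozen=True)
class AFContrast:
    or_: float
    ci95: tuple[float, float]
    p: float
    direction: int  # sign of log OR


def af_contrast(case: CohortFrequency, control: CohortFrequency) -> AFContrast:
    """Allelic 2x2 contrast of two cohorts' alt-allele frequencies.

    Zero cells get the Haldane-Anscombe 0.5 correction for the OR and CI;
    the exact p is computed on the uncorrected table.
    """
    if case.an == 0 or control.an == 0:
        raise ValueError("allele number must be > 0 in both cohorts")
    a, b = case.ac, case.an - case.ac
    c, d = control.ac, control.an - control.ac
    table = np.array([[a, b], [c, d]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AFContrast(
        or_=float(np.exp(log_or)),
        ci95=(float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))),
        p=float(p),
        direction=int(np.sign(log_or)),
    )


def _freq_lookup(df: pd.DataFrame) -> dict[str, CohortFrequency]:
    return {
        r.variant_id: CohortFrequency(r.variant_id, int(r.ac), int(r.an))
        for r in df.itertuples()
    }


def cross_cohort_confirm(
    wgs_indices: pd.DataFrame,
    array_cases: pd.DataFrame,
    aggregate_controls: pd.DataFrame,
    array_controls: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus replication decision table for WGS-significant indices.

    ``wgs_indices`` needs ``variant_id`` and ``beta`` (discovery direction);
    the frequency tables need variant_id/ac/an. A locus is retained iff the
    array-case contrast (vs array controls when supplied, else vs the
    aggregate controls) is nominally significant with matching direction,
    and the aggregate-control contrast also matches direction. Loci missing
    from a source are recorded untestable and not retained.
    """
    cases = _freq_lookup(array_cases)
    agg = _freq_lookup(aggregate_controls)
    actrl = _freq_lookup(array_controls) if array_controls is not None else None
    rows = []
    for rec in wgs_indices.itertuples():
        vid = rec.variant_id
        wgs_dir = int(np.sign(rec.beta))
        row = {
            "variant_id": vid,
            "wgs_direction": wgs_dir,
            "testable": True,
            "retained": False,
            "array_p": np.nan,
            "array_or": np.nan,
            "array_direction": 0,
            "aggregate_or": np.nan,
            "aggregate_direction": 0,
        }
        control1 = (actrl or agg).get(vid)
        if vid not in cases or control1 is None or vid not in agg:
            row["testable"] = False
            rows.append(row)
            continue
        c1 = af_contrast(cases[vid], control1)
        c2 = af_contrast(cases[vid], agg[vid])
        row.update(
            array_p=c1.p, array_or=c1.or_, array_direction=c1.direction,
            aggregate_or=c2.or_, aggregate_direction=c2.direction,
        )
        row["retained"] = bool(
            c1.p < alpha
            and c1.direction == wgs_dir
            and c2.direction == wgs_dir
        )
        rows.append(row)
    return pd.DataFrame(rows)
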