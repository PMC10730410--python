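"""Ancestry estimation and relatedness pruning.

Gates which samples enter association: LD-prune variants, run PCA on
standardized dosages, estimate each sample's ancestry as a mixture of five
continental populations in top-PC space, and drop one member of every pair
related above a pi-hat threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset

__all__ = [
    "AncestryEstimate",
    "RelatednessEstimate",
    "ld_prune",
    "compute_pca",
    "project",
    "estimate_ancestry",
    "pairwise_ibd",
    "remove_relateds",
]

POPULATIONS = ("EUR", "AFR", "EAS", "AMR", "SAS")


@dataclass(frozen=True)
class AncestryEstimate:
    """Per-sample mixture weights over the five reference populations."""

    sample: str
    proportions: dict[str, float]

    def weight(self, label: str) -> float:
        return self.proportions.get(label, 0.0)


@dataclass(frozen=True)
class RelatednessEstimate:
    """Method-of-moments IBD probabilities for one sample pair."""

    sample_a: str
    sample_b: str
    ibd0: float
    ibd1: float
    ibd2: float

    @property
    def pihat(self) -> float:
        return self.ibd2 + 0.5 * self.ibd1


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over shared non-missing samples."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("r2 undefined for a constant dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: GenotypeDataset,
    r2_threshold: float = 0.2,
    window_size: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained variant column indices.

    Within each sliding window (in variant count), any pair with dosage
    r^2 > threshold loses its later-in-position member; windows advance by
    ``step`` so no retained within-window pair exceeds the threshold.
    """
    if window_size < step:
        raise ValueError("window_size must be >= step")
    m = genotypes.n_variants
    keep = np.ones(m, dtype=bool)
    order = np.lexsort(
        (genotypes.variants["pos"].to_numpy(),
         genotypes.variants["contig"].to_numpy())
    )
    dose = genotypes.dosage
    start = 0
    while start < m:
        window = [i for i in order[start:start + window_size] if keep[i]]
        changed = True
        while changed:
            changed = False
            for ai in range(len(window)):
                a = window[ai]
                if not keep[a]:
                    continue
                for bi in range(ai + 1, len(window)):
                    b = window[bi]
                    if not keep[b]:
                        continue
                    try:
                        r2 = _dosage_r2(dose[:, a], dose[:, b])
                    except ValueError:
                        continue
                    if r2 > r2_threshold:
                        # b is later in position order within the window
                        keep[b] = False
                        changed = True
        start += step
    return np.flatnonzero(keep)


def _standardize(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center by 2p, scale by sqrt(2p(1-p)); missing imputed to the mean."""
    p = np.nanmean(dosage, axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    mono = sd == 0
    if mono.any():
        warnings.warn(f"dropping {int(mono.sum())} monomorphic variants before PCA")
    x = dosage[:, ~mono].copy()
    mu = 2 * p[~mono]
    x = np.where(np.isnan(x), mu, x)
    x = (x - mu) / sd[~mono]
    return x, mu, sd[~mono]


def compute_pca(
    genotypes: GenotypeDataset, k: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k PCA of standardized dosages.

    Returns (scores, loadings): scores is samples x k, loadings is a
    (m_used, k) matrix such that ``standardized_dosage @ loadings`` recovers
    the scores. Monomorphic variants are dropped with a warning.
    """
    if genotypes.n_samples < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples for k={k} components")
    x, mu, sd = _standardize(genotypes.dosage)
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    loadings = vt[:k].T
    scores = (x - x.mean(axis=0)) @ loadings
    df = pd.DataFrame(
        scores, index=genotypes.samples.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    # stash standardization so held-out samples can be projected
    df.attrs["center"] = x.mean(axis=0)
    df.attrs["mu"] = mu
    df.attrs["sd"] = sd
    return df, loadings


def project(dosage: np.ndarray, scores: pd.DataFrame,
            loadings: np.ndarray) -> np.ndarray:
    """Project raw dosage rows into an existing PC space."""
    mu, sd = scores.attrs["mu"], scores.attrs["sd"]
    x = np.atleast_2d(np.asarray(dosage, dtype=float))
    x = np.where(np.isnan(x), mu, x)
    x = (x - mu) / sd
    return (x - scores.attrs["center"]) @ loadings


def estimate_ancestry(
    sample_scores: pd.DataFrame,
    reference_scores: pd.DataFrame,
    reference_labels: pd.Series,
    min_weight: float = 0.90,
    target: str = "EUR",
    ridge: float = 0.0,
) -> tuple[list[AncestryEstimate], pd.Index]:
    """Mixture weights over population centroids in top-PC space.

    Solves sum-to-one generalized least squares under the Mahalanobis metric
    whose covariance is the pooled within-population covariance of the
    reference PCs, then projects the weights onto the probability simplex.
    Returns the estimates and the index of samples retained by the
    ``weight(target) >= min_weight`` rule (strict "at least").
    """
    labels = sorted(reference_labels.unique())
    cents = np.vstack([
        reference_scores[reference_labels == lab].mean(axis=0) for lab in labels
    ])
    resid = np.vstack([
        reference_scores[reference_labels == lab]
        - reference_scores[reference_labels == lab].mean(axis=0)
        for lab in labels
    ])
    cov = np.cov(resid.T) + ridge * np.eye(resid.shape[1])
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular within-population covariance; pass ridge > 0"
        ) from exc

    C = cents.T  # (k, npop)
    A = C.T @ cov_inv @ C
    ones = np.ones(len(labels))
    estimates = []
    retained = []
    for sample, row in sample_scores.iterrows():
        b = C.T @ cov_inv @ row.to_numpy()
        # equality-constrained GLS: minimize (x-Cw)' S^-1 (x-Cw) s.t. 1'w = 1
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular centroid system; pass ridge > 0"
            ) from exc
        lam = (ones @ Ainv @ b - 1) / (ones @ Ainv @ ones)
        w = Ainv @ (b - lam * ones)
        w = _project_simplex(w)
        est = AncestryEstimate(str(sample), dict(zip(labels, w.tolist())))
        estimates.append(est)
        if est.weight(target) >= min_weight:
            retained.append(sample)
    return estimates, pd.Index(retained)


def _project_simplex(w: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(w)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1 - css) / (np.arange(len(w)) + 1) > 0)[0][-1]
    theta = (1 - css[rho]) / (rho + 1)
    return np.maximum(w + theta, 0)


def pairwise_ibd(
    genotypes: GenotypeDataset, freqs: np.ndarray | None = None
) -> list[RelatednessEstimate]:
    """Method-of-moments IBD from identity-by-state counts.

    Uses the classic IBS decomposition: observed counts of IBS 0/1/2 across
    variants are compared with their expectations under IBD states 0/1/2
    given population allele frequencies, solved sequentially for P(IBD=k)
    and clamped to [0, 1] with renormalization.
    """
    dose = genotypes.dosage
    n, m = dose.shape
    if n < 2:
        return []
    p = np.nanmean(dose, axis=0) / 2.0 if freqs is None else np.asarray(freqs)
    q = 1 - p
    # per-variant IBS expectations under each IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    out = []
    ids = list(genotypes.samples.index)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dose[i], dose[j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            diff = np.abs(a[ok] - b[ok])
            ibs0 = diff == 2
            ibs1 = diff == 1
            E0_0, E0_1, E0_2 = e0_ibs0[ok].sum(), e0_ibs1[ok].sum(), e0_ibs2[ok].sum()
            E1_1, E1_2 = e1_ibs1[ok].sum(), e1_ibs2[ok].sum()
            n_ok = int(ok.sum())
            n0, n1 = int(ibs0.sum()), int(ibs1.sum())
            n2 = n_ok - n0 - n1
            p0 = n0 / E0_0 if E0_0 > 0 else 0.0
            p1 = (n1 - p0 * E0_1) / E1_1 if E1_1 > 0 else 0.0
            p2 = (n2 - p0 * E0_2 - p1 * E1_2) / n_ok if n_ok > 0 else 0.0
            probs = np.clip([p0, p1, p2], 0, 1)
            total = probs.sum()
            if total > 0:
                probs = probs / total
            out.append(RelatednessEstimate(ids[i], ids[j], *probs.tolist()))
    return out


def remove_relateds(
    genotypes: GenotypeDataset,
    pihat_threshold: float = 0.12,
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> tuple[pd.Index, list[RelatednessEstimate]]:
    """Drop one random member of every pair with pi-hat above the threshold.

    Flagged pairs are processed sorted by (pi-hat descending, pair id) so the
    seeded random removals are reproducible. Returns the retained sample ids
    and all flagged pair estimates.
    """
    if genotypes.n_samples < 2:
        return genotypes.samples.index, []
    ests = pairwise_ibd(genotypes, freqs=freqs)
    flagged = [e for e in ests if e.pihat > pihat_threshold]
    flagged.sort(key=lambda e: (-e.pihat, e.sample_a, e.sample_b))
    rng = np.random.default_rng(seed)
    removed: set[str] = set()
    for e in flagged:
        if e.sample_a in removed or e.sample_b in removed:
            continue
        removed.add(e.sample_a if rng.random() < 0.5 else e.sample_b)
    retained = pd.Index([s for s in genotypes.samples.index if s not in removed])
    return retained, flagged
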