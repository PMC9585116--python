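"""Two-city cohort statistics: propensity matching, differential detection,
and maternal-cord correlation.

Cities are compared after 1:1 nearest-neighbor propensity matching without
replacement on four sociodemographic covariates, so detection differences
reflect geography rather than cohort composition.  Per chemical, detection
counts in the matched samples form a 2x2 table tested with a two-sided
Fisher's exact test (probability-mass convention); abundance ratios are
Fresno/San Francisco means of post-correction natural-scale abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError
from .types import COVARIATES, MatchedCohort, PropensityModel

# ---------------------------------------------------------------------------
# Propensity model and matching
# ---------------------------------------------------------------------------


def _design_matrix(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.get_dummies(
        cohort[list(covariates)].astype(str), drop_first=True, dtype=float
    )
    X.insert(0, "intercept", 1.0)
    X.index = cohort["participant_id"]
    return X


def estimate_propensity(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PropensityModel:
    """Logistic regression of living in Fresno on indicator-coded covariates.

    Fitted by iteratively reweighted least squares with a small ridge
    penalty (default 1e-6) that keeps the solve well-posed under separable
    data; the fit is deterministic.
    """
    cities = set(cohort["city"].unique())
    if len(cities) < 2:
        raise ValidationError("both cities must be present to fit a propensity model")
    X = _design_matrix(cohort, covariates)
    y = (cohort["city"] == "Fresno").to_numpy(dtype=float)
    A = X.to_numpy()
    beta = np.zeros(A.shape[1])
    pen = ridge * np.eye(A.shape[1])
    pen[0, 0] = 0.0  # do not shrink the intercept
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = A.T @ (y - mu) - ridge * np.r_[0.0, beta[1:]]
        if np.abs(grad).max() < tol:
            break
        H = (A * w[:, None]).T @ A + pen + 1e-12 * np.eye(A.shape[1])
        beta = beta + np.linalg.solve(H, grad)
    eta = np.clip(A @ beta, -30, 30)
    scores = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index, name="propensity")
    return PropensityModel(
        coef=pd.Series(beta, index=X.columns),
        scores=scores,
        covariates=tuple(covariates),
    )


def match_nearest_neighbor(
    model: PropensityModel,
    cohort: pd.DataFrame,
    seed: Optional[int] = None,
    jitter: float = 0.0,
    matrix: str = "maternal",
) -> MatchedCohort:
    """1:1 nearest-neighbor matching without replacement on propensity scores.

    Fresno participants are processed in descending propensity order; each
    takes the closest still-unmatched San Francisco participant (ties to the
    smaller id).  With ``jitter`` > 0 and a seed, scores are perturbed by
    that amount before matching — the reseeded-repeat harness used to check
    robustness of downstream results; the default is fully deterministic.
    """
    scores = model.scores.copy()
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        scores = scores + rng.normal(0.0, jitter, len(scores))
    by_city = cohort.set_index("participant_id")["city"]
    fres = [p for p in scores.index if by_city.get(p) == "Fresno"]
    sf = [p for p in scores.index if by_city.get(p) == "SanFrancisco"]
    if not fres or not sf:
        raise ValidationError("matching requires participants from both cities")
    fres.sort(key=lambda p: (-scores[p], p))
    pool = sorted(sf)
    pairs = []
    for f in fres:
        if not pool:
            break
        best = min(pool, key=lambda s: (abs(scores[s] - scores[f]), s))
        pairs.append((f, best))
        pool.remove(best)
    return MatchedCohort(pairs=pairs, matrix=matrix)


def standardized_mean_differences(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    subset: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Per-covariate mean absolute standardized difference between cities.

    Each categorical level becomes an indicator; its SMD is
    ``|p_F - p_S| / sqrt((v_F + v_S)/2)``; a covariate's value is the mean
    over its levels.  ``subset`` restricts to the matched participants.
    """
    df = cohort
    if subset is not None:
        df = cohort[cohort["participant_id"].isin(set(subset))]
    out = {}
    f = df[df["city"] == "Fresno"]
    s = df[df["city"] == "SanFrancisco"]
    for cov in covariates:
        levels = sorted(cohort[cov].astype(str).unique())
        smds = []
        for lv in levels:
            pf = (f[cov].astype(str) == lv).mean()
            ps = (s[cov].astype(str) == lv).mean()
            v = (pf * (1 - pf) + ps * (1 - ps)) / 2.0
            smds.append(abs(pf - ps) / np.sqrt(v) if v > 0 else 0.0)
        out[cov] = float(np.mean(smds))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Transformations and tests
# ---------------------------------------------------------------------------


def log_transform(abundance, zero_sub: float = 0.1):
    """Natural log with the zero floor: abundances of 0 become ``zero_sub``.

    Keeps zeros finite on the log scale while preserving the 0 boundary of
    raw abundances.  Negative input is invalid.
    """
    arr = np.asarray(abundance, dtype=float)
    if (arr < 0).any():
        raise ValidationError("abundances must be non-negative")
    out = np.log(np.where(arr == 0, zero_sub, arr))
    if isinstance(abundance, pd.DataFrame):
        return pd.DataFrame(out, index=abundance.index, columns=abundance.columns)
    if isinstance(abundance, pd.Series):
        return pd.Series(out, index=abundance.index, name=abundance.name)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Probability-mass convention: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (within 1e-7 relative slack).  Any zero margin gives
    p = 1 by convention.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValidationError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    N = a + b + c + d
    K = a + b  # row-1 margin
    n1 = a + c  # column-1 margin
    if K == 0 or K == N or n1 == 0 or n1 == N or N == 0:
        return 1.0
    lo = max(0, K + n1 - N)
    hi = min(K, n1)
    ks = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(ks, N, K, n1)
    p_obs = sps.hypergeom.pmf(a, N, K, n1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    # the full support sums to 1 analytically; snap rounding noise
    if p >= 1.0 - 1e-9:
        return 1.0
    return p


def differential_detection(
    detected: pd.DataFrame,
    sample_city: pd.Series,
    abundance: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chemical differential detection between cities on matched samples.

    ``detected`` is chemicals x samples boolean; ``sample_city`` maps those
    samples to cities.  Returns detection frequencies per city, the Fisher
    p, the differential flag (p < alpha), and — when ``abundance`` (natural
    scale, post-correction) is given — the Fresno/San Francisco ratio of
    mean abundances.
    """
    city = sample_city.reindex(detected.columns)
    if city.isna().any():
        raise ValidationError("city missing for some samples")
    f_cols = detected.columns[city == "Fresno"]
    s_cols = detected.columns[city == "SanFrancisco"]
    nf, ns = len(f_cols), len(s_cols)
    rows = []
    for chem in detected.index:
        det_f = int(detected.loc[chem, f_cols].sum())
        det_s = int(detected.loc[chem, s_cols].sum())
        p = fisher_exact_2x2(det_f, nf - det_f, det_s, ns - det_s)
        row = {
            "chemical": chem,
            "n_fresno": nf,
            "n_sf": ns,
            "detected_fresno": det_f,
            "detected_sf": det_s,
            "df_fresno": det_f / nf if nf else np.nan,
            "df_sf": det_s / ns if ns else np.nan,
            "fisher_p": p,
            "differential": p < alpha,
        }
        if abundance is not None:
            mf = float(abundance.loc[chem, f_cols].mean())
            ms = float(abundance.loc[chem, s_cols].mean())
            row["abundance_ratio"] = mf / ms if ms > 0 else np.inf
            row["direction"] = "fresno_higher" if mf >= ms else "sf_higher"
        rows.append(row)
    return pd.DataFrame(rows)


def paired_correlation(x, y) -> float:
    """Pearson correlation of paired (e.g. maternal vs cord) log abundances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedStatisticError("paired correlation needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Batch-mixing diagnostic
# ---------------------------------------------------------------------------


@dataclass
class BatchMixing:
    """R-squared of batch on the top principal components of the sample cloud."""

    r2_per_component: list
    explained_variance_ratio: list

    @property
    def weighted_r2(self) -> float:
        w = np.asarray(self.explained_variance_ratio)
        r = np.asarray(self.r2_per_component)
        return float((w * r).sum() / w.sum()) if w.sum() > 0 else 0.0


def batch_mixing_check(
    log_abundance: pd.DataFrame,
    batch: pd.Series,
    n_components: int = 2,
) -> BatchMixing:
    """Quantify how much batch structure the top principal components carry.

    Samples (columns) are projected onto the top components of the
    chemical x sample matrix; for each component the one-way ANOVA R² of
    scores on batch is reported.  Run before and after correction, the drop
    in R² is the diagnostic that batch effects were removed.
    """
    M = log_abundance.to_numpy(dtype=float).T  # samples x chemicals
    b = batch.reindex(log_abundance.columns)
    if b.isna().any():
        raise ValidationError("batch label missing for some samples")
    if M.shape[0] <= n_components:
        raise ValidationError("need more samples than components")
    counts = b.value_counts()
    if (counts < 2).any():
        raise ValidationError("every batch needs at least 2 samples")
    M = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    evr = (S[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)).tolist()
    r2 = []
    groups = b.to_numpy()
    for j in range(k):
        y = scores[:, j]
        sst = ((y - y.mean()) ** 2).sum()
        if sst <= 0:
            r2.append(0.0)
            continue
        ssb = 0.0
        for lv in np.unique(groups):
            yl = y[groups == lv]
            ssb += len(yl) * (yl.mean() - y.mean()) ** 2
        r2.append(float(ssb / sst))
    if len(np.unique(groups)) == 1:
        r2 = [0.0] * k
    return BatchMixing(r2_per_component=r2, explained_variance_ratio=evr)
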