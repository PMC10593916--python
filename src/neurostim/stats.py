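"""Modulation statistics: permutation-tested mixed-effects models and
effect sizes.

The central model is a random-intercept linear mixed-effects (LME) model

    y = X beta + Z alpha + eps,      alpha ~ N(0, sigma_a^2 I),
                                     eps   ~ N(0, sigma_e^2 I),

with the image condition as fixed effect and the subject as random
intercept.  The model is fitted by REML: the variance ratio
theta = sigma_a^2 / sigma_e^2 is profiled out by a 1-D search (log grid
plus local refinement to a relative tolerance of 1e-8), and the fixed
effects are the GLS solution at the optimum.  Because the random effect is
a subject intercept, V = I + theta * Z Z' is block diagonal and every
quantity reduces to closed forms in per-subject sums, which also makes the
permutation null (condition labels re-drawn within subject, the model
refitted each time) cheap to evaluate for thousands of permutations at
once.

Significance follows the permutation convention: the two-sided p-value is
the fraction of permuted refits whose coefficient is at least as large in
magnitude as the observed one (denominator exactly n_perm, so the smallest
attainable p is 0).  Multiple comparisons are handled by Benjamini-
Hochberg FDR, effect sizes by Cohen's d with the pooled n-1 standard
deviation, and encoding accuracy by the Pearson correlation between
predicted and repeat-averaged measured responses over images seen at least
twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests

_THETA_GRID = np.concatenate([[0.0], np.geomspace(1e-8, 1e6, 57)])


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def zscore_responses(table: pd.DataFrame,
                     scope: Sequence[str] = ("subject_id", "region")
                     ) -> pd.DataFrame:
    """Z-score responses within each scope group (population-sd convention).

    Uses the divide-by-n standard deviation; raises if any group has fewer
    than two distinct values (its z-scores would be undefined).
    """
    out = table.copy()
    grouped = out.groupby(list(scope), sort=False)["response"]
    sd = grouped.transform(lambda v: v.std(ddof=0))
    if (sd <= 0).any() or sd.isna().any():
        raise ValueError("constant (or singleton) responses within a scope")
    out["response"] = (out["response"] - grouped.transform("mean")) / sd
    return out


# ---------------------------------------------------------------------------
# REML machinery (random-intercept model)
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    beta: float                      # fixed-effect coefficient of interest
    random_sd: float                 # sigma_a
    resid_sd: float                  # sigma_e
    subject_effects: np.ndarray      # BLUPs, one per subject
    n_obs: int
    contrast: tuple = ()
    all_betas: np.ndarray | None = None


@dataclass
class PermutationResult:
    beta_obs: float
    null_betas: np.ndarray
    p_two_sided: float


def _subject_codes(subject) -> tuple[np.ndarray, list]:
    labels = pd.unique(np.asarray(subject))
    lookup = {s: i for i, s in enumerate(labels)}
    return np.array([lookup[s] for s in np.asarray(subject)]), list(labels)


class _RemlProblem:
    """Sufficient statistics for the profiled REML criterion, general X."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray):
        self.n, self.p = X.shape
        self.S = codes.max() + 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.SX = np.zeros((self.S, self.p))
        self.Sy = np.zeros(self.S)
        self.ni = np.zeros(self.S)
        np.add.at(self.SX, codes, X)
        np.add.at(self.Sy, codes, y)
        np.add.at(self.ni, codes, 1.0)

    def _core(self, theta: float):
        w = theta / (1.0 + theta * self.ni)
        A = self.XtX - np.einsum("i,ij,ik->jk", w, self.SX, self.SX)
        c = self.Xty - (w * self.Sy) @ self.SX
        qy = self.yty - float(w @ self.Sy**2)
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            # a permuted design can make the fixed effects collinear under
            # the GLS metric; fall back to the minimum-norm solution
            beta = np.linalg.lstsq(A, c, rcond=None)[0]
        quad = qy - float(beta @ c)
        return w, A, beta, max(quad, 1e-300)

    def neg2ll(self, theta: float) -> float:
        w, A, _, quad = self._core(theta)
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e300        # degenerate design under this metric
        return (float(np.log1p(theta * self.ni).sum()) + logdet
                + (self.n - self.p) * np.log(quad))

    def fit_at(self, theta: float):
        w, A, beta, quad = self._core(theta)
        sig_e2 = quad / (self.n - self.p)
        sig_a2 = theta * sig_e2
        # BLUPs: theta * (per-subject residual sum) / (1 + theta * n_i)
        resid_sums = self.Sy - self.SX @ beta
        alpha = theta * resid_sums / (1.0 + theta * self.ni)
        return beta, np.sqrt(sig_a2), np.sqrt(sig_e2), alpha


def _optimize_theta(prob: _RemlProblem) -> float:
    vals = np.array([prob.neg2ll(t) for t in _THETA_GRID])
    i = int(np.argmin(vals))
    lo = _THETA_GRID[max(i - 1, 0)]
    hi = _THETA_GRID[min(i + 1, len(_THETA_GRID) - 1)]
    if lo == hi:
        return float(lo)
    # refine in log(theta + eps); relative tolerance ~1e-8 on the ratio
    eps = 1e-12
    res = optimize.minimize_scalar(
        lambda u: prob.neg2ll(np.exp(u) - eps),
        bounds=(np.log(lo + eps), np.log(hi + eps)), method="bounded",
        options={"xatol": 1e-9})
    theta = max(float(np.exp(res.x) - eps), 0.0)
    return theta if prob.neg2ll(theta) <= vals[i] else float(_THETA_GRID[i])


def _fit_reml(y: np.ndarray, X: np.ndarray, codes: np.ndarray):
    prob = _RemlProblem(np.asarray(y, float), np.asarray(X, float), codes)
    theta = _optimize_theta(prob)
    return prob.fit_at(theta)


def _binary_condition(condition) -> tuple[np.ndarray, tuple]:
    arr = np.asarray(condition)
    levels = np.unique(arr)
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {len(levels)}")
    return (arr == levels[1]).astype(float), (levels[0], levels[1])


def fit_lme(y, condition, subject) -> LMEFit:
    """Random-intercept LME of response on a binary image condition.

    The fixed-effect coefficient ``beta`` is the (GLS) condition effect:
    positive when the second condition level (sorted order) elicits larger
    responses.  Variance components are REML estimates via the profiled
    1-D search described in the module docstring.
    """
    y = np.asarray(y, dtype=float)
    x, contrast = _binary_condition(condition)
    codes, _ = _subject_codes(subject)
    if codes.max() < 1:
        raise ValueError("need at least two subjects")
    X = np.column_stack([np.ones_like(y), x])
    betas, sig_a, sig_e, alpha = _fit_reml(y, X, codes)
    return LMEFit(beta=float(betas[1]), random_sd=sig_a, resid_sd=sig_e,
                  subject_effects=alpha, n_obs=len(y), contrast=contrast,
                  all_betas=betas)


# -- vectorized binary-contrast REML over many permutation columns ----------

class _BinaryPermProblem:
    """REML fits of [1, x] models for many candidate label columns at once."""

    def __init__(self, y: np.ndarray, Xp: np.ndarray, codes: np.ndarray):
        self.n, self.P = Xp.shape
        S = codes.max() + 1
        self.ni = np.bincount(codes, minlength=S).astype(float)
        self.Sy = np.bincount(codes, weights=y, minlength=S)
        self.yty = float(y @ y)
        self.Sytot = float(y.sum())
        self.Sx = np.zeros((S, self.P))
        self.Sxy = np.zeros((S, self.P))
        for i in range(S):
            rows = codes == i
            self.Sx[i] = Xp[rows].sum(axis=0)
            self.Sxy[i] = y[rows] @ Xp[rows]
        self.t1 = Xp.sum(axis=0)          # x'x = sum(x) for binary x
        self.Sxytot = self.Sxy.sum(axis=0)

    def _pieces(self, theta: np.ndarray):
        w = theta[None, :] / (1.0 + theta[None, :] * self.ni[:, None])
        a = self.n - (w * self.ni[:, None] ** 2).sum(axis=0)
        d = self.t1 - (w * self.Sx**2).sum(axis=0)
        c = self.t1 - (w * self.Sx * self.ni[:, None]).sum(axis=0)
        e = self.Sytot - (w * self.ni[:, None] * self.Sy[:, None]).sum(axis=0)
        f = self.Sxytot - (w * self.Sx * self.Sy[:, None]).sum(axis=0)
        qy = self.yty - (w * self.Sy[:, None] ** 2).sum(axis=0)
        det = a * d - c**2
        beta = (a * f - c * e) / det
        beta0 = (d * e - c * f) / det
        quad = np.maximum(qy - (beta0 * e + beta * f), 1e-300)
        logv = np.log1p(theta[None, :] * self.ni[:, None]).sum(axis=0)
        return beta, det, quad, logv

    def neg2ll(self, theta: np.ndarray) -> np.ndarray:
        beta, det, quad, logv = self._pieces(theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = logv + np.log(det) + (self.n - 2) * np.log(quad)
        return np.where(det > 0, out, np.inf)

    def betas(self, theta: np.ndarray) -> np.ndarray:
        return self._pieces(theta)[0]


def _perm_betas(y: np.ndarray, Xp: np.ndarray, codes: np.ndarray
                ) -> np.ndarray:
    """REML condition coefficients for every permuted label column."""
    prob = _BinaryPermProblem(y, Xp, codes)
    P = Xp.shape[1]
    nll = np.stack([prob.neg2ll(np.full(P, t)) for t in _THETA_GRID])
    best = np.argmin(nll, axis=0)
    eps = 1e-12
    lo = np.log(_THETA_GRID[np.maximum(best - 1, 0)] + eps)
    hi = np.log(_THETA_GRID[np.minimum(best + 1, len(_THETA_GRID) - 1)] + eps)
    # iterative shrinking-bracket refinement of the per-column optimum
    for _ in range(16):
        cand = np.linspace(lo, hi, 7)                       # (7, P)
        vals = np.stack([prob.neg2ll(np.exp(c) - eps) for c in cand])
        k = np.argmin(vals, axis=0)
        lo = cand[np.maximum(k - 1, 0), np.arange(P)]
        hi = cand[np.minimum(k + 1, 6), np.arange(P)]
    theta = np.maximum(np.exp((lo + hi) / 2) - eps, 0.0)
    return prob.betas(theta)


def permutation_test(y, condition, subject, n_perm: int = 1000,
                     seed: int = 0, *, scheme: str = "within"
                     ) -> PermutationResult:
    """Permutation p-value for the LME condition coefficient.

    Condition labels are re-drawn ``n_perm`` times (by default permuted
    within subject, preserving subject exchangeability; ``scheme='global'``
    permutes across the whole table) and the model refitted each time.
    The two-sided p-value is the fraction of permuted coefficients at
    least as large in magnitude as the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    x, contrast = _binary_condition(condition)
    codes, _ = _subject_codes(subject)
    # observed beta through the same estimator as the permuted refits
    # (works down to a single subject)
    beta_obs = float(_perm_betas(y, x[:, None], codes)[0])
    rng = np.random.default_rng(seed)
    Xp = np.empty((len(y), n_perm))
    if scheme == "within":
        for i in range(codes.max() + 1):
            rows = np.flatnonzero(codes == i)
            block = np.broadcast_to(x[rows], (n_perm, rows.size))
            Xp[rows] = rng.permuted(block, axis=1).T
    elif scheme == "global":
        block = np.broadcast_to(x, (n_perm, len(y)))
        Xp = rng.permuted(block, axis=1).T
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    null = _perm_betas(y, Xp, codes)
    p = float(np.mean(np.abs(null) >= abs(beta_obs)))
    return PermutationResult(beta_obs=beta_obs, null_betas=null,
                             p_two_sided=p)


# ---------------------------------------------------------------------------
# FDR, effect sizes, accuracy
# ---------------------------------------------------------------------------

def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def cohens_d(group_max, group_avg) -> float:
    """Standardized Max-minus-Avg mean difference (pooled n-1 sd)."""
    a = np.asarray(group_max, dtype=float)
    b = np.asarray(group_avg, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                     / (len(a) + len(b) - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def encoding_accuracy(predictions: Mapping[str, float] | pd.Series,
                      table: pd.DataFrame) -> float:
    """Pearson r between predictions and repeat-averaged measurements.

    Only images measured at least twice qualify; at least three such
    images are required for the correlation to be meaningful.
    """
    preds = pd.Series(predictions, dtype=float)
    counts = table.groupby("image_id")["response"].count()
    qualified = counts[counts >= 2].index
    means = (table[table["image_id"].isin(qualified)]
             .groupby("image_id")["response"].mean())
    common = means.index.intersection(preds.index)
    if len(common) < 3:
        raise ValueError("need at least 3 images with >=2 repeats")
    return float(sps.pearsonr(preds[common], means[common])[0])


def subject_similarity_matrix(table: pd.DataFrame, region: str
                              ) -> pd.DataFrame:
    """Across-subject response similarity with within-subject reliability.

    Off-diagonal (i, j): Pearson r between subject i's and j's per-image
    mean responses over the common twice-measured image set; diagonal:
    r between each subject's first and second measurements (test-retest
    reliability, the noise ceiling for the off-diagonal entries).
    """
    sub = table[table["region"] == region]
    subjects = sorted(sub["subject_id"].unique())
    per: dict[str, pd.DataFrame] = {}
    common: pd.Index | None = None
    for s in subjects:
        t = sub[sub["subject_id"] == s]
        counts = t.groupby("image_id")["response"].count()
        ids = counts[counts >= 2].index
        per[s] = t[t["image_id"].isin(ids)]
        common = ids if common is None else common.intersection(ids)
    if common is None or len(common) < 3:
        raise ValueError("no common twice-measured images across subjects")
    common = sorted(common)
    mat = np.eye(len(subjects))
    means = {}
    for s in subjects:
        t = per[s][per[s]["image_id"].isin(common)]
        means[s] = t.groupby("image_id")["response"].mean().loc[common]
        r1 = t[t["repeat_index"] == 1].set_index("image_id")["response"].loc[common]
        r2 = t[t["repeat_index"] == 2].set_index("image_id")["response"].loc[common]
        mat[subjects.index(s), subjects.index(s)] = sps.pearsonr(r1, r2)[0]
    for i, si in enumerate(subjects):
        for j in range(i + 1, len(subjects)):
            r = sps.pearsonr(means[si], means[subjects[j]])[0]
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=subjects, columns=subjects)


def accuracy_vs_d_correlation(accuracies, ds, n_perm: int = 1000,
                              seed: int = 0) -> tuple[float, float]:
    """Pooled Pearson r between accuracy and Cohen's d, permutation p.

    The null re-pairs the two vectors ``n_perm`` times (two-sided).
    """
    a = np.asarray(accuracies, dtype=float)
    d = np.asarray(ds, dtype=float)
    if len(a) != len(d) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    r = float(sps.pearsonr(a, d)[0])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = sps.pearsonr(a, rng.permutation(d))[0]
    p = float(np.mean(np.abs(null) >= abs(r)))
    return r, p


def hierarchy_trend_lme(t_stats: pd.DataFrame, levels: Mapping[str, int],
                        *, n_perm: int = 1000, seed: int = 0
                        ) -> tuple[LMEFit, float]:
    """Trend of personalization strength along a regional hierarchy.

    ``t_stats`` has one row per (subject, region, contrast_type) with a
    ``t_stat`` column; ``levels`` codes each region's hierarchical level as
    an integer.  Fits a random-intercept LME with the level and the
    contrast type as fixed effects and returns the level coefficient with
    its permutation p-value (levels permuted within subject).
    """
    df = t_stats.copy()
    df["level"] = df["region"].map(levels).astype(float)
    if df["level"].nunique() < 2:
        raise ValueError("need at least two hierarchy levels")
    ctypes = sorted(df["contrast_type"].unique())
    dummies = np.column_stack([(df["contrast_type"] == c).astype(float)
                               for c in ctypes[1:]]) \
        if len(ctypes) > 1 else np.empty((len(df), 0))
    y = df["t_stat"].to_numpy(dtype=float)
    codes, _ = _subject_codes(df["subject_id"])
    lvl = df["level"].to_numpy()

    def level_beta(levels_col: np.ndarray) -> tuple:
        X = np.column_stack([np.ones(len(df)), levels_col, dummies])
        return _fit_reml(y, X, codes)

    betas, sig_a, sig_e, alpha = level_beta(lvl)
    fit = LMEFit(beta=float(betas[1]), random_sd=sig_a, resid_sd=sig_e,
                 subject_effects=alpha, n_obs=len(df),
                 contrast=("level",), all_betas=betas)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = lvl.copy()
        for i in range(codes.max() + 1):
            rows = np.flatnonzero(codes == i)
            perm[rows] = perm[rows][rng.permutation(rows.size)]
        null[k] = level_beta(perm)[0][1]
    p = float(np.mean(np.abs(null) >= abs(fit.beta)))
    return fit, p


def nat_syn_accuracy_compare(accuracies_nat, accuracies_syn
                             ) -> tuple[float, float]:
    """Paired t statistic and Pearson r between natural/synthetic accuracies."""
    a = np.asarray(accuracies_nat, dtype=float)
    b = np.asarray(accuracies_syn, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(a, b):
        t = 0.0
    else:
        t = float(sps.ttest_rel(a, b).statistic)
    r = float(sps.pearsonr(a, b)[0])
    return t, r
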