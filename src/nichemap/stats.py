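"""Inferential layer: stratified PERMANOVA, PCA contributions, sparse PLS-DA
and paired permutation tests.

The two workhorses follow a statsmodels-style model/results split:
``Permanova(X, groups, strata).fit()`` and ``SparsePLSDA(X, y).fit()`` return
results objects carrying the estimates, permutation p-values and a
``summary()`` table.

Design notes
------------
* Features are z-scored by default before any multivariate analysis because
  the columns mix units (um, cells/mm^2, %, counts); zero-variance columns
  are dropped with a warning.
* PERMANOVA permutations shuffle group labels *within* patient strata by
  default — the cohort design is paired (every patient contributes each
  region) — and p-values use the (1 + more-extreme) / (1 + B) convention so
  p >= 1/(B+1) > 0.
* Paired permutation tests use the paired t statistic with a sign-flip null,
  enumerated exactly whenever 2^n_pairs does not exceed the permutation
  budget.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .spatial import FeatureMatrix
from .util import zscore_columns

# ---------------------------------------------------------------------------
# missing-feature imputation (multivariate-analysis boundary)
# ---------------------------------------------------------------------------

def impute_missing(
    fm: FeatureMatrix, distance_ceiling_um: float = 1000.0
) -> FeatureMatrix:
    """Complete a feature matrix for PCA / PERMANOVA / sPLS-DA.

    Missing pair distances (a cluster absent from a sample) are set to the
    core diameter as a ceiling encoding "not co-occurring"; missing
    neighborhood interactions to 0; missing abundances to 0.
    """
    df = fm.data.copy()
    for col in df.columns:
        if not df[col].isna().any():
            continue
        fill = distance_ceiling_um if col.startswith("dist_") else 0.0
        df[col] = df[col].fillna(fill)
    prov = dict(fm.provenance)
    prov["imputation"] = {
        "dist": distance_ceiling_um, "neigh": 0.0, "abundance": 0.0,
    }
    return FeatureMatrix(data=df, clusters=fm.clusters, provenance=prov)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PairwiseContrast:
    group_a: str
    group_b: str
    pseudo_F: float
    raw_p: float
    holm_p: float


@dataclass
class PermanovaResults:
    """Pseudo-F, R^2 and permutation p-value of a one-factor PERMANOVA."""

    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    n: int
    groups: list
    df_between: int
    df_within: int
    stratified: bool
    pairwise: list[PairwiseContrast] | None = None

    def summary(self) -> str:
        lines = [
            "PERMANOVA (Euclidean distance on standardised features)",
            f"  n = {self.n}, groups = {len(self.groups)} {tuple(self.groups)}",
            f"  permutations = {self.n_permutations}"
            + (" (stratified by patient)" if self.stratified else ""),
            f"  pseudo-F({self.df_between}, {self.df_within}) = {self.pseudo_F:.4f}",
            f"  R^2 = {self.R2:.4f}",
            f"  p = {self.p_value:.4f}",
        ]
        if self.pairwise:
            lines.append("  pairwise contrasts (Holm-adjusted):")
            for c in self.pairwise:
                lines.append(
                    f"    {c.group_a} vs {c.group_b}: F = {c.pseudo_F:.4f}, "
                    f"p = {c.raw_p:.4f}, holm p = {c.holm_p:.4f}"
                )
        return "\n".join(lines)


def _group_codes(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels))
    index = {g: k for k, g in enumerate(groups)}
    return np.array([index[v] for v in labels], dtype=np.int64), groups


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from a squared-distance matrix and group codes.

    Uses the sums-of-squares identity SS = sum of within-set squared
    distances / set size (equivalent to Gower-centred trace forms).
    """
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx):
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0.0:
        if ss_between <= 0.0:
            return 0.0, 0.0  # fully degenerate: all distances zero
        return np.inf, 1.0
    F = (ss_between / df_b) / (ss_within / df_w)
    R2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(F), float(R2)


class Permanova:
    """One-factor permutational multivariate ANOVA on Euclidean distances.

    Parameters
    ----------
    X : DataFrame or ndarray
        Complete samples x features matrix (impute upstream).
    groups : sequence
        Group label per row (e.g. region class).
    strata : sequence, optional
        Stratum per row (e.g. patient); permutations shuffle labels within
        strata only.  ``None`` gives unrestricted permutations.
    scale : bool
        Z-score columns first (default True; zero-variance columns dropped).
    """

    def __init__(self, X, groups, strata=None, scale: bool = True):
        if isinstance(X, FeatureMatrix):
            X = X.data
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ParameterError("X must be complete; run impute_missing first")
        codes, group_names = _group_codes(groups)
        if len(group_names) < 2:
            raise ParameterError("need at least two groups")
        counts = np.bincount(codes)
        if (counts < 2).any():
            raise ParameterError("every group needs at least two rows")
        if scale and X.shape[1] > 0:
            X, _ = zscore_columns(X)
        self.X = X
        self.codes = codes
        self.group_names = group_names
        self.strata = None if strata is None else np.asarray(strata, dtype=object)
        if len(X):
            d = pdist(X.to_numpy(dtype=float)) if X.shape[1] else np.zeros(
                len(codes) * (len(codes) - 1) // 2
            )
            self.d2 = squareform(d**2)
        else:
            raise ParameterError("empty matrix")

    def _permuted_codes(self, rng) -> np.ndarray:
        codes = self.codes
        if self.strata is None:
            return rng.permutation(codes)
        out = codes.copy()
        for s in pd.unique(self.strata):
            idx = np.flatnonzero(self.strata == s)
            out[idx] = codes[idx][rng.permutation(len(idx))]
        return out

    def fit(self, permutations: int = 9999, seed: int | None = None) -> PermanovaResults:
        g = len(self.group_names)
        F_obs, R2 = _pseudo_f(self.d2, self.codes, g)
        if self.strata is not None:
            degenerate = [
                s
                for s in pd.unique(self.strata)
                if len(set(self.codes[self.strata == s])) < 2
            ]
            if degenerate:
                warnings.warn(
                    f"{len(degenerate)} stratum/strata carry a single group label "
                    "and contribute no permutation variation"
                )
        rng = np.random.default_rng(seed)
        more_extreme = 0
        for _ in range(permutations):
            F_perm, _ = _pseudo_f(self.d2, self._permuted_codes(rng), g)
            if F_perm >= F_obs:
                more_extreme += 1
        p = (1.0 + more_extreme) / (1.0 + permutations)
        return PermanovaResults(
            pseudo_F=F_obs,
            R2=R2,
            p_value=p,
            n_permutations=permutations,
            seed=seed,
            n=len(self.codes),
            groups=self.group_names,
            df_between=g - 1,
            df_within=len(self.codes) - g,
            stratified=self.strata is not None,
        )


def permanova(
    X, groups, strata=None, n_permutations: int = 9999, seed: int | None = None,
    scale: bool = True,
) -> PermanovaResults:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(X, groups, strata=strata, scale=scale).fit(
        permutations=n_permutations, seed=seed
    )


def holm_adjust(raw_p) -> np.ndarray:
    """Holm step-down family-wise adjustment of a vector of p-values."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        return raw_p
    return multipletests(raw_p, method="holm")[1]


def pairwise_permanova(
    X, groups, strata=None, n_permutations: int = 9999, seed: int | None = None,
    scale: bool = True,
) -> list[PairwiseContrast]:
    """PERMANOVA on every unordered pair of groups, Holm-adjusted."""
    if isinstance(X, FeatureMatrix):
        X = X.data
    X = pd.DataFrame(X)
    labels = np.asarray(groups, dtype=object)
    names = sorted(set(labels))
    if len(names) < 2:
        raise ParameterError("need at least two groups")
    contrasts = []
    raw = []
    for a, b in itertools.combinations(names, 2):
        mask = (labels == a) | (labels == b)
        sub_strata = None if strata is None else np.asarray(strata, dtype=object)[mask]
        res = Permanova(
            X.loc[mask],
            labels[mask],
            strata=sub_strata,
            scale=scale,
        ).fit(permutations=n_permutations, seed=seed)
        contrasts.append((a, b, res.pseudo_F, res.p_value))
        raw.append(res.p_value)
    holm = holm_adjust(raw)
    return [
        PairwiseContrast(a, b, F, p, float(h))
        for (a, b, F, p), h in zip(contrasts, holm)
    ]


# ---------------------------------------------------------------------------
# PCA contribution ranking
# ---------------------------------------------------------------------------

@dataclass
class PcaContribution:
    """Per-feature contribution (%) to the leading principal components."""

    contributions: pd.DataFrame  # features x components, percent
    reference: float             # 100 / p: the equal-contribution line
    explained_variance_ratio: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def top(self, component: int = 1, n: int = 10) -> pd.Series:
        col = f"PC{component}"
        return self.contributions[col].sort_values(ascending=False).head(n)


def pca_contributions(X, n_components: int = 2, scale: bool = True) -> PcaContribution:
    """SVD of the column-centred (and z-scored) matrix; the contribution of
    feature f to component c is 100 * loading(f, c)^2 (loadings unit-norm).

    The equal-contribution reference line is 100 / p for p retained features.
    """
    if isinstance(X, FeatureMatrix):
        X = X.data
    X = pd.DataFrame(X)
    dropped: list[str] = []
    if scale:
        X, dropped = zscore_columns(X)
    if X.shape[1] < 2:
        raise ParameterError("need at least two (non-constant) features")
    n_components = min(n_components, X.shape[1], len(X) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X.to_numpy(dtype=float))
    load2 = pca.components_**2  # rows are unit-norm components
    contrib = pd.DataFrame(
        100.0 * load2.T / load2.sum(axis=1),
        index=X.columns,
        columns=[f"PC{c+1}" for c in range(n_components)],
    )
    return PcaContribution(
        contributions=contrib,
        reference=100.0 / X.shape[1],
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class SparsePLSDAResults:
    """Loadings, scores and selected variables of a fitted sparse PLS-DA."""

    x_weights: pd.DataFrame   # features x components, unit-norm sparse weights
    scores: pd.DataFrame      # samples x components
    selected: list[list[str]]  # per component, nonzero-weight feature names
    keep_x: list[int]
    classes: list
    n_iter: list[int]

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def top_features(self, component: int = 1, n: int = 10) -> pd.Series:
        col = f"comp{component}"
        w = self.x_weights[col]
        return w.reindex(w.abs().sort_values(ascending=False).index).head(n)

    def summary(self) -> str:
        lines = [
            f"sparse PLS-DA: {self.n_components} component(s), "
            f"classes {tuple(self.classes)}",
        ]
        for c in range(self.n_components):
            sel = self.selected[c]
            lines.append(
                f"  component {c+1}: keepX = {self.keep_x[c]}, "
                f"{len(sel)} selected variable(s)"
            )
            for name in sel[:10]:
                lines.append(f"    {name}: {self.x_weights.iloc[:, c][name]:+.4f}")
        return "\n".join(lines)


def _soft_threshold_keep(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``a`` at the (keep+1)-th largest magnitude, keeping at
    most ``keep`` nonzero entries (mixOmics-style variable selection)."""
    if keep >= len(a):
        return a.copy()
    mags = np.abs(a)
    lam = np.partition(mags, len(a) - keep - 1)[len(a) - keep - 1]
    out = np.sign(a) * np.maximum(mags - lam, 0.0)
    return out


class SparsePLSDA:
    """Sparse partial least squares discriminant analysis.

    The class vector is one-hot encoded and centred; per component the first
    singular-vector pair of X_deflated' Y is found by power iteration with
    soft-thresholding of the X-weight (at most ``keep_x`` nonzero entries),
    then X and Y are deflated by regression on the component score.
    Deterministic: SVD initialisation, fixed tolerance.
    """

    def __init__(
        self,
        X,
        y,
        n_components: int = 2,
        keep_x: int | list[int] = 25,
        scale: bool = True,
        max_iter: int = 500,
        tol: float = 1e-12,
    ):
        if isinstance(X, FeatureMatrix):
            X = X.data
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ParameterError("X must be complete; run impute_missing first")
        y = np.asarray(y, dtype=object)
        self.classes = sorted(set(y))
        if len(self.classes) < 2:
            raise ParameterError("need at least two classes")
        if scale:
            X, _ = zscore_columns(X)
        else:
            X = X - X.mean(axis=0)
        p = X.shape[1]
        if isinstance(keep_x, int):
            keep_x = [keep_x] * n_components
        if len(keep_x) != n_components:
            raise ParameterError("keep_x must have one entry per component")
        if any(k < 1 for k in keep_x):
            raise ParameterError("keep_x entries must be >= 1")
        self.keep_x = [min(k, p) for k in keep_x]
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.X = X
        Y = pd.get_dummies(pd.Categorical(y, categories=self.classes)).to_numpy(float)
        self.Y = Y - Y.mean(axis=0)

    def fit(self) -> SparsePLSDAResults:
        Xd = self.X.to_numpy(dtype=float).copy()
        Yd = self.Y.copy()
        n, p = Xd.shape
        weights = np.zeros((p, self.n_components))
        scores = np.zeros((n, self.n_components))
        selected: list[list[str]] = []
        n_iter: list[int] = []
        cols = list(self.X.columns)
        for c in range(self.n_components):
            M = Xd.T @ Yd
            # deterministic init: leading singular vectors of M
            U, _, Vt = np.linalg.svd(M, full_matrices=False)
            a = U[:, 0]
            b = Vt[0]
            it = 0
            for it in range(1, self.max_iter + 1):
                a_new = _soft_threshold_keep(M @ b, self.keep_x[c])
                norm = np.linalg.norm(a_new)
                if norm == 0:  # all weights thresholded away; keep previous
                    a_new = a
                    break
                a_new = a_new / norm
                b_new = M.T @ a_new
                bn = np.linalg.norm(b_new)
                b_new = b_new / bn if bn > 0 else b_new
                if np.max(np.abs(a_new - a)) < self.tol:
                    a, b = a_new, b_new
                    break
                a, b = a_new, b_new
            t = Xd @ a
            tt = float(t @ t)
            if tt > 0:
                p_load = Xd.T @ t / tt
                c_load = Yd.T @ t / tt
                Xd = Xd - np.outer(t, p_load)
                Yd = Yd - np.outer(t, c_load)
            weights[:, c] = a
            scores[:, c] = t
            selected.append([cols[j] for j in np.flatnonzero(a != 0.0)])
            n_iter.append(it)
        comp_names = [f"comp{c+1}" for c in range(self.n_components)]
        return SparsePLSDAResults(
            x_weights=pd.DataFrame(weights, index=cols, columns=comp_names),
            scores=pd.DataFrame(scores, index=self.X.index, columns=comp_names),
            selected=selected,
            keep_x=self.keep_x,
            classes=self.classes,
            n_iter=n_iter,
        )


def splsda_fit(
    X, y, n_components: int = 2, keep_x: int | list[int] = 25, scale: bool = True
) -> SparsePLSDAResults:
    """Functional wrapper around :class:`SparsePLSDA`."""
    return SparsePLSDA(X, y, n_components=n_components, keep_x=keep_x, scale=scale).fit()


# ---------------------------------------------------------------------------
# paired permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    """Paired permutation t-test result (sign-flip null on differences)."""

    statistic: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int | None
    mean_difference: float
    n_pairs: int

    def summary(self) -> str:
        kind = "exact enumeration" if self.exact else "Monte Carlo"
        return (
            f"paired permutation t-test: n = {self.n_pairs}, "
            f"t = {self.statistic:.4f}, mean diff = {self.mean_difference:.4f}, "
            f"p = {self.p_value:.4g} ({kind}, {self.n_permutations} sign patterns)"
        )


def _paired_t(d: np.ndarray) -> float:
    m = d.mean()
    s = d.std(ddof=1)
    if s == 0.0:
        return 0.0 if m == 0.0 else float(np.sign(m)) * np.inf
    return float(m / (s / np.sqrt(len(d))))


def paired_permutation_test(
    x_a,
    x_b=None,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermTestResult:
    """Two-sided paired permutation test on per-patient values.

    The statistic is the paired t on differences ``x_a - x_b`` (pass
    ``x_b=None`` to test pre-computed differences against zero); the null is
    generated by random sign-flips of the differences.  All 2^n sign
    patterns are enumerated when that does not exceed ``n_permutations``.
    """
    a = np.asarray(x_a, dtype=float)
    d = a if x_b is None else a - np.asarray(x_b, dtype=float)
    n = len(d)
    if x_b is not None and len(np.asarray(x_b)) != n:
        raise ParameterError("paired samples must have equal length")
    if n < 3:
        raise ParameterError("need at least three pairs")
    if np.all(d == 0.0):
        return PermTestResult(0.0, 1.0, 0, True, seed, 0.0, n)
    t_obs = _paired_t(d)
    thresh = abs(t_obs) * (1.0 - 1e-12)
    if 2**n <= n_permutations:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        signs = 2 * bits - 1
        flipped = signs * d
        with np.errstate(invalid="ignore", divide="ignore"):
            means = flipped.mean(axis=1)
            sds = flipped.std(axis=1, ddof=1)
            ts = np.where(
                sds > 0,
                means / (sds / np.sqrt(n)),
                np.where(means == 0, 0.0, np.sign(means) * np.inf),
            )
        p = float(np.mean(np.abs(ts) >= thresh))
        return PermTestResult(t_obs, p, 2**n, True, seed, float(d.mean()), n)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    flipped = signs * d
    with np.errstate(invalid="ignore", divide="ignore"):
        means = flipped.mean(axis=1)
        sds = flipped.std(axis=1, ddof=1)
        ts = np.where(
            sds > 0,
            means / (sds / np.sqrt(n)),
            np.where(means == 0, 0.0, np.sign(means) * np.inf),
        )
    more = int(np.sum(np.abs(ts) >= thresh))
    p = (1.0 + more) / (1.0 + n_permutations)
    return PermTestResult(t_obs, p, n_permutations, False, seed, float(d.mean()), n)
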