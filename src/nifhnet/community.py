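"""Community structure statistics: perMANOVA, regression trees, PCA, OLS.

Covers the multivariate side of the dead-wood analysis: Bray-Curtis
dissimilarities of the nifH MOTU clone-count matrix, permutational MANOVA
with a sequential (Type I) sum-of-squares decomposition over an ordered term
list, k-means decay classes on remaining mass, multivariate regression trees
(MRT) on Euclidean distances, PCA biplot scores of the MRT group means, and
the sporocarp-richness regressions with stepwise backward selection.

The perMANOVA follows the Gower-centering construction: with
``A = -D**2 / 2`` and ``G = J A J`` (``J`` the centering projector), the sum
of squares explained by a design matrix ``X`` is ``tr(H G)`` with ``H`` the
hat projector of ``X``; pseudo-F compares term mean squares to the residual
mean square, and p-values count permutations with an F at least as large,
as ``(count + 1) / (n_perm + 1)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "bray_curtis",
    "kmeans_decay_classes",
    "DecayClassAssignment",
    "permanova",
    "PermanovaResult",
    "mrt",
    "MrtNode",
    "pca_group_means",
    "richness_models",
    "polynomial_fit",
    "TABLE1_TERMS",
]

#: Ordered perMANOVA term list of the published community analysis:
#: tree species, decay class (numeric, single df), management type and all
#: their interactions.
TABLE1_TERMS = (
    "species",
    "decay_class",
    "management",
    "species:decay_class",
    "species:management",
    "decay_class:management",
    "species:decay_class:management",
)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between rows (logs)."""
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if zero_rows.size:
        names = [str(matrix.index[i]) for i in zero_rows]
        raise ValueError(f"all-zero rows cannot enter Bray-Curtis: {names}")
    dist = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


# --------------------------------------------------------------------------
# Decay classes: exact 1-D k-means

@dataclass
class DecayClassAssignment:
    """Log -> decay class (1..k) with class centers in remaining-mass %."""

    classes: pd.Series  # int class labels, 1 = least decomposed
    centers: np.ndarray  # remaining-mass center per class, descending
    within_ss: float


def _interval_ss(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Sum of squares of sorted values[i:j] about their mean (prefix sums)."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def kmeans_decay_classes(
    remaining_mass: pd.Series | np.ndarray,
    k: int = 4,
    seed: int | None = None,
) -> DecayClassAssignment:
    """Assign decay classes 1..k by k-means on 1-D remaining-mass values.

    In one dimension the k-means optimum consists of contiguous intervals of
    the sorted values, so the globally optimal clustering is found exactly by
    dynamic programming over interval partitions; the result is deterministic
    and ``seed`` is accepted only for interface compatibility.  Classes are
    numbered by descending center (class 1 = most intact wood).
    """
    series = pd.Series(remaining_mass)
    values = series.to_numpy(dtype=float)
    if len(np.unique(values)) < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)
    prefix = np.concatenate(([0.0], np.cumsum(x)))
    prefix2 = np.concatenate(([0.0], np.cumsum(x * x)))

    # dp[c][j] = min SS splitting first j points into c clusters
    dp = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                if dp[c - 1][i] == np.inf:
                    continue
                cand = dp[c - 1][i] + _interval_ss(prefix, prefix2, i, j)
                if cand < best - 1e-12:
                    best, arg = cand, i
            dp[c][j] = best
            back[c][j] = arg

    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c][j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = n

    labels_sorted = np.empty(n, dtype=int)
    centers = []
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        labels_sorted[i:j] = c
        centers.append(x[i:j].mean())
    centers = np.asarray(centers)
    # order classes by descending center: highest remaining mass = class 1
    rank = np.empty(k, dtype=int)
    rank[np.argsort(-centers)] = np.arange(1, k + 1)
    labels = np.empty(n, dtype=int)
    labels[order] = rank[labels_sorted]
    return DecayClassAssignment(
        classes=pd.Series(labels, index=series.index, name="decay_class"),
        centers=np.sort(centers)[::-1],
        within_ss=float(dp[k][n]),
    )


# --------------------------------------------------------------------------
# perMANOVA

@dataclass
class PermanovaResult:
    """Sequential perMANOVA decomposition (one row per term + residual/total)."""

    table: pd.DataFrame  # index: terms, Residual, Total; cols Df SS MS F R2 p
    n_permutations: int

    @property
    def total_df(self) -> int:
        return int(self.table.loc["Total", "Df"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "Df"])


def _term_design(metadata: pd.DataFrame, term: str, numeric: set[str]) -> np.ndarray:
    """Treatment-coded columns for one (possibly interaction) term."""
    parts = term.split(":")
    blocks = []
    for var in parts:
        if var not in metadata.columns:
            raise ValueError(f"unknown model variable {var!r}")
        col = metadata[var]
        if var in numeric:
            v = col.to_numpy(dtype=float)
            blocks.append((v - v.mean())[:, None])
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"factor {var!r} has a single level")
            blocks.append(dummies.to_numpy())
    design = blocks[0]
    for b in blocks[1:]:
        design = np.einsum("ij,ik->ijk", design, b).reshape(len(b), -1)
    return design


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    metadata: pd.DataFrame,
    terms: tuple[str, ...] | list[str] = TABLE1_TERMS,
    numeric: tuple[str, ...] = ("decay_class",),
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Distance-based MANOVA with sequential term sums of squares.

    ``terms`` are fitted in order of entry; interaction terms are written
    ``a:b``.  Variables listed in ``numeric`` enter as centered single-df
    covariates (decay class does, matching the published single-df row),
    all others as treatment-coded factors.  Rows are permuted freely.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if len(metadata) != n:
        raise ValueError("metadata rows must match distance matrix")
    numeric_set = set(numeric)

    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = float(np.trace(g))

    intercept = np.ones((n, 1))
    cum = intercept
    hats = [_hat(cum)]
    dfs: list[int] = []
    for term in terms:
        x = _term_design(metadata, term, numeric_set)
        new = np.hstack([cum, x])
        rank_old = np.linalg.matrix_rank(cum)
        rank_new = np.linalg.matrix_rank(new)
        df = rank_new - rank_old
        if df < x.shape[1]:
            raise ValueError(f"design is rank deficient: term {term!r} is aliased "
                             "with earlier terms")
        dfs.append(df)
        cum = new
        hats.append(_hat(cum))

    h_prev = hats[0]
    ss_terms = []
    for h in hats[1:]:
        ss_terms.append(float(np.trace(h @ g)) - float(np.trace(h_prev @ g)))
        h_prev = h
    ss_resid = ss_total - float(np.trace(hats[-1] @ g))
    df_resid = (n - 1) - sum(dfs)
    if df_resid <= 0:
        raise ValueError("model leaves no residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    f_obs = np.array([(ss / df) / ms_resid for ss, df in zip(ss_terms, dfs)])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    # Projector differences let each permuted G yield all term SS at once.
    h_diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    h_full = hats[-1]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p = np.array([float(np.sum(hd * gp.T)) for hd in h_diffs])
        ss_res_p = ss_total - float(np.sum(h_full * gp.T))
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_resid)
        exceed += f_p >= f_obs
    pvals = (exceed + 1) / (n_permutations + 1)

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append((term, df, ss, ss / df, f, ss / ss_total, p))
    rows.append(("Residual", df_resid, ss_resid, ms_resid, np.nan,
                 ss_resid / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, np.nan, 1.0, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "Df", "SS", "MS", "F", "R2", "p"]
    ).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_permutations)


# --------------------------------------------------------------------------
# Multivariate regression tree

@dataclass
class MrtNode:
    """One node of a multivariate regression tree."""

    samples: list  # row labels in this node
    ss: float  # sum of squared Euclidean distances to the node mean
    depth: int
    split_var: str | None = None
    split_rule: str | None = None  # human-readable rule for the left child
    left: "MrtNode | None" = None
    right: "MrtNode | None" = None
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["MrtNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {"n": len(self.samples), "ss": self.ss, "depth": self.depth}
        if self.is_leaf:
            d["leaf_id"] = self.leaf_id
            d["samples"] = [str(s) for s in self.samples]
        else:
            d.update(split_var=self.split_var, split_rule=self.split_rule,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


def _node_ss(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    return float(((y - y.mean(axis=0)) ** 2).sum())


def candidate_splits(col: pd.Series, ordered: bool) -> list[tuple[str, np.ndarray]]:
    """(rule, left-mask) candidates: thresholds if ordered, bipartitions if not."""
    out: list[tuple[str, np.ndarray]] = []
    values = col.to_numpy()
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        return out
    if ordered:
        for cut in levels[:-1]:
            out.append((f"<= {cut}", values <= cut))
    else:
        # enumerate bipartitions; fix the first level to the left side
        rest = levels[1:]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                left = {levels[0], *combo}
                if len(left) == len(levels):
                    continue
                out.append((f"in {sorted(map(str, left))}", np.isin(values, list(left))))
    return out


def best_split(
    response: pd.DataFrame,
    predictors: pd.DataFrame,
    ordered: set[str],
) -> tuple[str, str, np.ndarray, float] | None:
    """Exhaustive best single split: (var, rule, left mask, child SS sum)."""
    y = np.asarray(response, dtype=float)
    best = None
    for var in predictors.columns:
        for rule, mask in candidate_splits(predictors[var], var in ordered):
            if mask.all() or not mask.any():
                continue
            ss = _node_ss(y[mask]) + _node_ss(y[~mask])
            if best is None or ss < best[3] - 1e-12:
                best = (var, rule, mask, ss)
    return best


def mrt(
    response: pd.DataFrame,
    predictors: pd.DataFrame,
    ordered: tuple[str, ...] = ("decay_class",),
    min_node_size: int = 5,
    max_depth: int = 4,
    min_rel_improvement: float = 0.01,
) -> MrtNode:
    """Multivariate regression tree by greedy Euclidean SS splitting.

    Each split minimizes the summed within-child sum of squared Euclidean
    distances.  Ordered predictors use threshold splits, categorical ones
    all level bipartitions.  A node becomes a leaf when it is smaller than
    ``min_node_size``, at ``max_depth``, or when the best split improves SS
    by less than ``min_rel_improvement`` of the root SS.
    """
    if len(response) != len(predictors):
        raise ValueError("response and predictors must have equal row counts")
    y = np.asarray(response, dtype=float)
    root_ss = _node_ss(y)
    ordered_set = set(ordered)

    def grow(idx: np.ndarray, depth: int) -> MrtNode:
        node = MrtNode(
            samples=list(response.index[idx]),
            ss=_node_ss(y[idx]),
            depth=depth,
        )
        if len(idx) < max(2, min_node_size) or depth >= max_depth:
            return node
        found = best_split(response.iloc[idx], predictors.iloc[idx], ordered_set)
        if found is None:
            return node
        var, rule, mask, child_ss = found
        if root_ss > 0 and (node.ss - child_ss) < min_rel_improvement * root_ss:
            return node
        node.split_var, node.split_rule = var, rule
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    root = grow(np.arange(len(response)), 0)
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.leaf_id = i
    return root


# --------------------------------------------------------------------------
# PCA of group means

def pca_group_means(
    matrix: pd.DataFrame,
    groups: pd.Series,
    correlation_threshold: float = 0.8,
) -> dict:
    """PCA of the group-mean vectors with samples projected onto the axes.

    Axes are eigenvectors of the covariance of the group means (unweighted).
    The per-axis "intersect correlation" is the Pearson correlation between
    sample scores and the scores of their group means; axes exceeding the
    threshold are flagged as carrying significant between-group variation.
    """
    groups = pd.Series(groups, index=matrix.index)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("PCA of group means requires at least two groups")
    means = np.vstack([matrix[groups == g].mean(axis=0).to_numpy() for g in labels])
    center = means.mean(axis=0)
    cov = np.cov(means - center, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(eigval)[::-1]
    n_axes = min(len(labels) - 1, matrix.shape[1])
    eigval = np.clip(eigval[order][:n_axes], 0, None)
    axes = eigvec[:, order][:, :n_axes]

    group_scores = (means - center) @ axes
    sample_scores = (np.asarray(matrix, dtype=float) - center) @ axes
    group_of = np.array([labels.index(g) for g in groups])
    mean_scores = group_scores[group_of]

    correlations = []
    for ax in range(n_axes):
        a, b = sample_scores[:, ax], mean_scores[:, ax]
        if a.std() == 0 or b.std() == 0:
            correlations.append(0.0)
        else:
            correlations.append(float(np.corrcoef(a, b)[0, 1]))
    total = eigval.sum()
    explained = eigval / total if total > 0 else np.zeros_like(eigval)
    return {
        "groups": labels,
        "group_scores": pd.DataFrame(
            group_scores, index=labels,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        ),
        "sample_scores": pd.DataFrame(
            sample_scores, index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        ),
        "explained_variance": explained,
        "eigenvalues": eigval,
        "intersect_correlations": np.asarray(correlations),
        "significant_axes": [
            i + 1 for i, c in enumerate(correlations) if c > correlation_threshold
        ],
    }


# --------------------------------------------------------------------------
# Richness regressions

def richness_models(
    table: pd.DataFrame,
    response: str = "sporocarp_richness",
    predictors: tuple[str, ...] = (
        "species",
        "log_n_per_density",
        "log_c_per_density",
        "decay_class",
        "nifh_richness",
    ),
    alpha: float = 0.05,
) -> dict:
    """OLS of sporocarp richness with a sequential ANOVA and backward selection.

    Columns named ``log_<x>`` are computed as ``log(x)`` from the raw column
    (raising on non-positive values).  The full-model ANOVA assigns each
    predictor one df in order of entry (Type I); backward selection then
    drops the largest-p predictor until all retained coefficients have
    p < ``alpha``.
    """
    data = table.copy()
    for name in predictors:
        if name.startswith("log_"):
            raw = name[4:]
            if raw not in data.columns:
                raise ValueError(f"column {raw!r} required for {name!r}")
            if (data[raw] <= 0).any():
                raise ValueError(f"non-positive values in {raw!r} cannot be log-transformed")
            data[name] = np.log(data[raw])
        elif name not in data.columns:
            raise ValueError(f"unknown predictor {name!r}")

    def design(cols: tuple[str, ...] | list[str]) -> pd.DataFrame:
        blocks = []
        for c in cols:
            col = data[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                blocks.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
            else:
                blocks.append(col.astype(float).rename(c).to_frame())
        x = pd.concat(blocks, axis=1)
        return sm.add_constant(x)

    y = data[response].astype(float)
    full = sm.OLS(y, design(predictors)).fit()

    # Sequential (Type I) ANOVA: SS drop when each term is added in order.
    rows = []
    prev_rss = float(((y - y.mean()) ** 2).sum())
    prev_df = len(y) - 1
    for i, name in enumerate(predictors):
        fit = sm.OLS(y, design(predictors[: i + 1])).fit()
        rss = float(fit.ssr)
        df = prev_df - int(fit.df_resid)
        rows.append((name, df, prev_rss - rss))
        prev_rss, prev_df = rss, int(fit.df_resid)
    resid_df = int(full.df_resid)
    ms_resid = full.ssr / resid_df
    anova = pd.DataFrame(
        [
            (name, df, ss, ss / df, (ss / df) / ms_resid)
            for name, df, ss in rows
        ],
        columns=["term", "Df", "SS", "MS", "F"],
    ).set_index("term")
    from scipy import stats as _st

    anova["p"] = _st.f.sf(anova["F"], anova["Df"], resid_df)
    anova.loc["Residual"] = [resid_df, full.ssr, ms_resid, np.nan, np.nan]

    # Backward elimination on coefficient p-values.
    kept = list(predictors)
    while kept:
        fit = sm.OLS(y, design(kept)).fit()
        pvals = {}
        for name in kept:
            cols = [c for c in fit.params.index if c == name or c.startswith(f"{name}_")]
            pvals[name] = min(fit.pvalues[c] for c in cols)
        worst = max(kept, key=lambda nm: pvals[nm])
        if pvals[worst] < alpha:
            break
        kept.remove(worst)
    selected = sm.OLS(y, design(kept)).fit() if kept else sm.OLS(y, sm.add_constant(
        pd.DataFrame(index=data.index))).fit()

    return {
        "full_model": full,
        "anova": anova,
        "selected_predictors": kept,
        "selected_model": selected,
        "residual_df": resid_df,
    }


def polynomial_fit(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray, degree: int = 2) -> dict:
    """Least-squares polynomial fit with R2, F-test p and coefficients.

    Coefficients are returned highest order first (``coef[0]`` is the
    leading term), so a hump-shaped response yields ``coef[0] < 0`` at
    degree 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.vander(x, degree + 1)  # columns: x^degree ... 1
    fit = sm.OLS(y, design).fit()
    return {
        "coefficients": fit.params,
        "r_squared": float(fit.rsquared),
        "p_value": float(fit.f_pvalue) if fit.df_model > 0 else np.nan,
        "model": fit,
    }
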