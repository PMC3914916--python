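"""Presence-absence null models: C-score, checkerboards and pairwise Z-scores.

The observed fungal and nifH occurrence tables are stacked into one binary
species x sites matrix.  Segregation is quantified by the C-score (the mean
over species pairs of the checkerboard units ``CU = (r_i - S)(r_j - S)``,
with ``r`` the row totals and ``S`` the number of shared sites) and by the
checkerboard index (the number of species pairs that never co-occur; the
summed checkerboard units are reported alongside).  Significance comes from
a fixed-fixed null model: sequential checkerboard swaps that preserve both
row and column totals exactly, sampled into an ensemble of randomized
matrices.  Pairwise non-random associations are scored as
``Z = (CU_obs - mean(CU_null)) / sd(CU_null)``; Z below -1.96 marks
co-occurrence (aggregation), above +1.96 avoidance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "BinaryMatrix",
    "PairScore",
    "NullEnsemble",
    "binarize_and_filter",
    "cscore",
    "checkerboard_stats",
    "swap_randomize",
    "null_ensemble",
    "matrix_test",
    "pairwise_z",
    "Z_THRESHOLD",
]

#: Two-sided normal critical value used to flag non-random pairs.
Z_THRESHOLD = 1.96


@dataclass
class BinaryMatrix:
    """Species x sites presence-absence matrix with kingdom labels."""

    data: np.ndarray  # shape (n_species, n_sites), dtype int8, values {0,1}
    taxa: list[str]
    kingdoms: list[str]  # per taxon: "fungus" or "nifH"
    sites: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")
        if len(self.taxa) != self.data.shape[0] or len(self.sites) != self.data.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
        if len(self.kingdoms) != len(self.taxa):
            raise ValueError("one kingdom label per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")

    @property
    def row_margins(self) -> np.ndarray:
        return self.data.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.data.sum(axis=0)

    @property
    def n_species(self) -> int:
        return self.data.shape[0]


def binarize_and_filter(
    fungal: pd.DataFrame,
    motus: pd.DataFrame,
    min_occurrence: int = 3,
    apply_filter: bool = True,
) -> BinaryMatrix:
    """Stack abundance tables (rows = sites) into one binary species matrix.

    Cells become presence (abundance > 0).  With ``apply_filter`` species
    occupying fewer than ``min_occurrence`` sites are dropped, as done for
    the pairwise analysis; the matrix-level test keeps every species
    (``apply_filter=False``).
    """
    if set(fungal.index) != set(motus.index):
        raise ValueError("fungal and nifH tables must share an identical site set")
    motus = motus.loc[fungal.index]
    if (fungal.values < 0).any() or (motus.values < 0).any():
        raise ValueError("abundances must be non-negative")
    blocks, taxa, kingdoms = [], [], []
    for df, kingdom in ((fungal, "fungus"), (motus, "nifH")):
        presence = (df.values > 0).astype(np.int8).T  # species x sites
        keep = np.ones(presence.shape[0], dtype=bool)
        if apply_filter:
            keep = presence.sum(axis=1) >= min_occurrence
        blocks.append(presence[keep])
        taxa.extend(np.asarray(df.columns)[keep])
        kingdoms.extend([kingdom] * int(keep.sum()))
    return BinaryMatrix(
        data=np.vstack(blocks),
        taxa=list(taxa),
        kingdoms=kingdoms,
        sites=list(fungal.index),
    )


def _pair_cu(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle arrays of shared-site counts S and checkerboard units CU."""
    a = data.astype(np.int64)
    shared = a @ a.T
    r = a.sum(axis=1)
    cu = np.multiply.outer(r, np.ones_like(r)) - shared
    cu = cu * cu.T  # (r_i - S)(r_j - S)
    iu = np.triu_indices(len(r), k=1)
    return shared[iu], cu[iu]


def cscore(matrix: BinaryMatrix | np.ndarray) -> float:
    """Mean checkerboard units over all species pairs."""
    data = matrix.data if isinstance(matrix, BinaryMatrix) else np.asarray(matrix)
    if data.shape[0] < 2:
        raise ValueError("C-score requires at least two species")
    _, cu = _pair_cu(data)
    return float(cu.mean())


def checkerboard_stats(matrix: BinaryMatrix | np.ndarray) -> tuple[int, int]:
    """(number of species pairs that never co-occur, total checkerboard units)."""
    data = matrix.data if isinstance(matrix, BinaryMatrix) else np.asarray(matrix)
    if data.shape[0] < 2:
        raise ValueError("checkerboard statistics require at least two species")
    shared, cu = _pair_cu(data)
    return int((shared == 0).sum()), int(cu.sum())


@njit(cache=False)
def _swap_kernel(m, r1, r2, c1, c2):  # pragma: no cover - jitted
    accepted = 0
    for t in range(r1.size):
        i, j, k, l = r1[t], r2[t], c1[t], c2[t]
        a = m[i, k]
        b = m[i, l]
        c = m[j, k]
        d = m[j, l]
        if a == d and b == c and a != b:
            m[i, k] = b
            m[i, l] = a
            m[j, k] = c ^ 1
            m[j, l] = c
            accepted += 1
    return accepted


def _attempt_swaps(data: np.ndarray, n_attempts: int, rng: np.random.Generator) -> int:
    """Run ``n_attempts`` sequential swap attempts in place; return successes."""
    if n_attempts <= 0:
        return 0
    nr, nc = data.shape
    r1 = rng.integers(0, nr, size=n_attempts)
    r2 = rng.integers(0, nr - 1, size=n_attempts)
    r2 = r2 + (r2 >= r1)
    c1 = rng.integers(0, nc, size=n_attempts)
    c2 = rng.integers(0, nc - 1, size=n_attempts)
    c2 = c2 + (c2 >= c1)
    return int(_swap_kernel(data, r1, r2, c1, c2))


def swap_randomize(
    matrix: BinaryMatrix | np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return a copy randomized by ``n_swaps`` checkerboard swap attempts.

    Each attempt draws a random 2x2 submatrix and flips it iff it is a
    checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]); attempts on other
    submatrices are no-ops.  Row and column margins are preserved exactly.
    """
    data = matrix.data if isinstance(matrix, BinaryMatrix) else np.asarray(matrix)
    out = np.ascontiguousarray(data.astype(np.int8).copy())
    _attempt_swaps(out, int(n_swaps), rng)
    return out


@dataclass
class NullEnsemble:
    """Margin-preserving randomized matrices summarized by their statistics."""

    n: int
    cscores: np.ndarray  # (n,)
    checkerboard_pairs: np.ndarray  # (n,)
    checkerboard_units: np.ndarray  # (n,)
    pair_cu: np.ndarray  # (n, n_pairs) null CU samples, upper-triangle order
    burn_in: int
    spacing: int
    seed: int | None
    acceptance_rate: float


def null_ensemble(
    matrix: BinaryMatrix | np.ndarray,
    n: int = 100,
    burn_in: int | None = None,
    spacing: int | None = None,
    seed: int | None = 0,
) -> NullEnsemble:
    """Sample ``n`` fixed-fixed randomized matrices by sequential swapping.

    Defaults: ``burn_in`` = 10x and ``spacing`` = 5x the number of occupied
    cells.  Every sampled matrix has exactly the observed margins.  A matrix
    admitting no checkerboard submatrix (e.g. perfectly nested) cannot move,
    so a degenerate-null warning is emitted.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    data = matrix.data if isinstance(matrix, BinaryMatrix) else np.asarray(matrix)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    fill = int(data.sum())
    burn_in = 10 * fill if burn_in is None else int(burn_in)
    spacing = max(1, 5 * fill if spacing is None else int(spacing))
    rng = np.random.default_rng(seed)
    work = np.ascontiguousarray(data.astype(np.int8).copy())

    _, cu_obs = _pair_cu(data)
    accepted = _attempt_swaps(work, burn_in, rng)
    cs = np.empty(n)
    cb_pairs = np.empty(n, dtype=np.int64)
    cb_units = np.empty(n, dtype=np.int64)
    pair_cu = np.empty((n, cu_obs.size), dtype=np.int64)
    attempts = burn_in
    for i in range(n):
        accepted += _attempt_swaps(work, spacing, rng)
        attempts += spacing
        shared, cu = _pair_cu(work)
        cs[i] = cu.mean()
        cb_pairs[i] = (shared == 0).sum()
        cb_units[i] = cu.sum()
        pair_cu[i] = cu
    if accepted == 0:
        warnings.warn(
            "no checkerboard swap was possible: the null distribution is "
            "degenerate (matrix is likely nested)",
            stacklevel=2,
        )
    return NullEnsemble(
        n=n,
        cscores=cs,
        checkerboard_pairs=cb_pairs,
        checkerboard_units=cb_units,
        pair_cu=pair_cu,
        burn_in=burn_in,
        spacing=spacing,
        seed=seed,
        acceptance_rate=accepted / max(attempts, 1),
    )


def matrix_test(observed: float, null_values: np.ndarray, tail: str = "greater") -> float:
    """Monte-Carlo p-value of an observed matrix-level statistic.

    ``p = (#{null >= observed} + 1) / (N + 1)`` for ``tail='greater'``
    (``<=`` for ``'lesser'``), so p never reaches zero.
    """
    null_values = np.asarray(null_values)
    if null_values.size == 0:
        raise ValueError("ensemble is empty")
    if tail == "greater":
        count = int((null_values >= observed).sum())
    elif tail == "lesser":
        count = int((null_values <= observed).sum())
    else:
        raise ValueError(f"tail must be 'greater' or 'lesser', got {tail!r}")
    return (count + 1) / (null_values.size + 1)


@dataclass
class PairScore:
    """Null-model score of one species pair."""

    taxon_a: str
    taxon_b: str
    kingdom_a: str
    kingdom_b: str
    shared_sites: int
    cu_obs: int
    null_mean: float
    null_sd: float
    z: float
    p_two_sided: float
    classification: str  # "co-occurrence" | "avoidance" | "none" | "indeterminate"


def pairwise_z(
    matrix: BinaryMatrix,
    ensemble: NullEnsemble,
    z_threshold: float = Z_THRESHOLD,
) -> list[PairScore]:
    """Z-transformed pair scores against the null ensemble.

    A zero null standard deviation gives Z = 0 when the observed units equal
    the null mean and is otherwise flagged indeterminate.  Classification:
    co-occurrence for Z < -1.96, avoidance for Z > +1.96, none otherwise.
    The two-sided p is the doubled smaller empirical tail probability with
    the (count+1)/(N+1) convention.
    """
    shared, cu_obs = _pair_cu(matrix.data)
    means = ensemble.pair_cu.mean(axis=0)
    sds = ensemble.pair_cu.std(axis=0, ddof=0)
    iu = np.triu_indices(matrix.n_species, k=1)
    n = ensemble.n
    scores: list[PairScore] = []
    for k, (i, j) in enumerate(zip(*iu)):
        sd = float(sds[k])
        obs = int(cu_obs[k])
        if sd == 0.0:
            if obs == means[k]:
                z, cls = 0.0, "none"
            else:
                z = float("inf") if obs > means[k] else float("-inf")
                cls = "indeterminate"
        else:
            z = (obs - float(means[k])) / sd
            if z < -z_threshold:
                cls = "co-occurrence"
            elif z > z_threshold:
                cls = "avoidance"
            else:
                cls = "none"
        null = ensemble.pair_cu[:, k]
        p_ge = (int((null >= obs).sum()) + 1) / (n + 1)
        p_le = (int((null <= obs).sum()) + 1) / (n + 1)
        p_two = min(1.0, 2.0 * min(p_ge, p_le))
        scores.append(
            PairScore(
                taxon_a=matrix.taxa[i],
                taxon_b=matrix.taxa[j],
                kingdom_a=matrix.kingdoms[i],
                kingdom_b=matrix.kingdoms[j],
                shared_sites=int(shared[k]),
                cu_obs=obs,
                null_mean=float(means[k]),
                null_sd=sd,
                z=float(z),
                p_two_sided=p_two,
                classification=cls,
            )
        )
    return scores
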