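"""Two-way orthogonal PLS (O2PLS) with a permutation null for variable
selection.

O2PLS decomposes a coupled pair of sample-matched matrices X (samples x
taxa) and Y (samples x HAs) into three parts per block:

    X = T W' + T_o P_ox' + E_x
    Y = U C' + U_o P_oy' + E_y

where the n joint components (scores T, U; unit-norm loadings W, C)
capture the covariation shared between blocks, the nx / ny orthogonal
components capture structured within-block variation uncorrelated with
the joint scores, and E is residual noise.  Joint loadings are seeded by
the leading singular triplets of X'Y; orthogonal components are extracted
one at a time from the part of each block predicted by the joint scores
but orthogonal to the joint loadings, deflating the block after each, and
the joint parts are recomputed on the deflated data.  The inner relation
B is the least-squares regression of U on T.

Variable selection uses an empirical permutation null: the rows of Y are
reshuffled ``n_perm`` times (breaking the X–Y sample linkage while
preserving each block's internal structure), the model is refit, and the
permuted joint loadings of each component are pooled — after aligning
each permuted loading vector's sign with the observed one — into a null
distribution.  A variable is significant when its observed loading falls
below the α/2 or above the 1 − α/2 empirical quantile of that null in any
joint component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DataError

__all__ = [
    "ScalingSpec",
    "O2PLSModel",
    "PermutationResult",
    "normalize",
    "fit",
    "permutation_test",
]


@dataclass(frozen=True)
class ScalingSpec:
    """Block scaling applied before the decomposition.

    Default mode mirrors the reference preprocessing: mean-center both
    blocks by column, scale the (metabolite) Y columns to unit variance,
    then scale each whole block to a total sum of squares of 1.  The
    alternative ``zscore_columns`` mode centers and unit-variance scales
    every column of the block it is applied to.
    """

    center: bool = True
    unit_variance_y: bool = True
    equal_total_ssq: bool = True
    zscore_columns: bool = False

    def __post_init__(self) -> None:
        if self.zscore_columns and (self.unit_variance_y or self.equal_total_ssq):
            raise ConfigurationError(
                "zscore_columns mode excludes unit_variance_y/equal_total_ssq; "
                "construct ScalingSpec(center=True, unit_variance_y=False, "
                "equal_total_ssq=False, zscore_columns=True)"
            )


def _column_names(M) -> list:
    if isinstance(M, pd.DataFrame):
        return list(M.columns)
    return list(range(np.asarray(M).shape[1]))


def normalize(M, spec: ScalingSpec, *, block: str = "x"):
    """Scale a samples x features block according to ``spec``.

    ``block`` selects whether the matrix is treated as the X (taxa) or Y
    (HA) block; unit-variance column scaling applies to Y only in the
    default mode.  Returns the same container type as the input.
    """
    if block not in ("x", "y"):
        raise ConfigurationError(f"block must be 'x' or 'y', got {block!r}")
    names = _column_names(M)
    A = np.array(M, dtype=float, copy=True)
    if A.ndim != 2 or A.shape[0] < 2:
        raise DataError("normalize requires a 2-D matrix with >= 2 samples")

    def _check_variance(sd: np.ndarray) -> None:
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise DataError(
                "zero-variance columns cannot be variance-scaled: "
                f"{[names[i] for i in dead[:5]]}"
            )

    if spec.zscore_columns:
        A -= A.mean(axis=0)
        sd = A.std(axis=0, ddof=1)
        _check_variance(sd)
        A /= sd
    else:
        if spec.center:
            A -= A.mean(axis=0)
        if block == "y" and spec.unit_variance_y:
            sd = A.std(axis=0, ddof=1)
            _check_variance(sd)
            A /= sd
        if spec.equal_total_ssq:
            norm = np.sqrt((A**2).sum())
            if norm == 0:
                raise DataError("all-zero block cannot be scaled to unit ssq")
            A /= norm
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(A, index=M.index, columns=M.columns)
    return A


@dataclass
class O2PLSModel:
    """Fitted O2PLS decomposition.

    Joint loadings ``W`` (p x n) and ``C`` (q x n) have unit-norm columns;
    ``T``/``U`` are the joint scores, ``*_orth`` the orthogonal
    scores/loadings, ``B`` the inner-relation matrix (U ≈ T B) and
    ``variance_explained`` the joint/orthogonal/residual sum-of-squares
    fractions per block.
    """

    W: np.ndarray
    C: np.ndarray
    T: np.ndarray
    U: np.ndarray
    W_orth: np.ndarray
    P_orth_x: np.ndarray
    T_orth: np.ndarray
    C_orth: np.ndarray
    P_orth_y: np.ndarray
    U_orth: np.ndarray
    B: np.ndarray
    variance_explained: dict
    n: int = 1
    nx: int = 0
    ny: int = 0
    x_names: list = field(default_factory=list)
    y_names: list = field(default_factory=list)

    def reconstruct_x(self) -> np.ndarray:
        return self.T @ self.W.T + self.T_orth @ self.P_orth_x.T

    def reconstruct_y(self) -> np.ndarray:
        return self.U @ self.C.T + self.U_orth @ self.P_orth_y.T


def _joint_loadings(X: np.ndarray, Y: np.ndarray, n: int):
    """Leading n singular triplets of the cross-covariance X'Y."""
    u, s, vt = np.linalg.svd(X.T @ Y, full_matrices=False)
    return u[:, :n].copy(), vt[:n].T.copy()


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Per-column sign flips making the max-|value| element positive."""
    flips = np.ones(L.shape[1])
    for k in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, k])))
        if L[i, k] < 0:
            flips[k] = -1.0
    return flips


def _deflate_orthogonal(block: np.ndarray, scores: np.ndarray,
                        loadings: np.ndarray, n_orth: int):
    """Extract ``n_orth`` orthogonal components from one block.

    ``scores`` are the current joint scores of the block and ``loadings``
    its joint loadings.  Returns the deflated block and the orthogonal
    weights / scores / loadings.
    """
    n_samples, n_feat = block.shape
    w_o = np.zeros((n_feat, n_orth))
    t_o = np.zeros((n_samples, n_orth))
    p_o = np.zeros((n_feat, n_orth))
    deflated = block.copy()
    scores = scores.copy()
    for k in range(n_orth):
        resid = deflated - scores @ loadings.T
        u, _, _ = np.linalg.svd(resid.T @ scores, full_matrices=False)
        w = u[:, 0]
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = deflated @ w
        denom = float(t @ t)
        if denom == 0:
            raise DataError(
                f"orthogonal component {k + 1} degenerate (zero score norm)"
            )
        p = deflated.T @ t / denom
        deflated = deflated - np.outer(t, p)
        w_o[:, k], t_o[:, k], p_o[:, k] = w, t, p
        scores = deflated @ loadings
    return deflated, w_o, t_o, p_o


def fit(X, Y, n: int, nx: int = 0, ny: int = 0) -> O2PLSModel:
    """Fit the O2PLS decomposition with n joint and nx/ny orthogonal components.

    ``X`` and ``Y`` are sample-matched (samples x features) matrices,
    already normalized (see :func:`normalize`).
    """
    x_names = _column_names(X)
    y_names = _column_names(Y)
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.ndim != 2 or Ya.ndim != 2:
        raise DataError("X and Y must be 2-D (samples x features)")
    if Xa.shape[0] != Ya.shape[0]:
        raise AlignmentError(
            f"sample counts differ: X has {Xa.shape[0]}, Y has {Ya.shape[0]}"
        )
    if n < 1:
        raise ConfigurationError("need at least one joint component")
    if nx < 0 or ny < 0:
        raise ConfigurationError("orthogonal component counts must be >= 0")
    limit = min(Xa.shape[0], Xa.shape[1], Ya.shape[1])
    if n + max(nx, ny) > limit:
        raise ConfigurationError(
            f"n + max(nx, ny) = {n + max(nx, ny)} exceeds the smallest "
            f"dimension {limit}"
        )

    Xd, Yd = Xa.copy(), Ya.copy()
    W, C = _joint_loadings(Xd, Yd, n)
    T, U = Xd @ W, Yd @ C

    if nx > 0:
        Xd, W_o, T_o, P_ox = _deflate_orthogonal(Xd, T, W, nx)
    else:
        W_o = np.zeros((Xa.shape[1], 0))
        T_o = np.zeros((Xa.shape[0], 0))
        P_ox = np.zeros((Xa.shape[1], 0))
    if ny > 0:
        Yd, C_o, U_o, P_oy = _deflate_orthogonal(Yd, U, C, ny)
    else:
        C_o = np.zeros((Ya.shape[1], 0))
        U_o = np.zeros((Ya.shape[0], 0))
        P_oy = np.zeros((Ya.shape[1], 0))

    # joint parts recomputed on the deflated blocks
    W, C = _joint_loadings(Xd, Yd, n)
    W *= _fix_signs(W)
    C *= _fix_signs(C)
    T, U = Xd @ W, Yd @ C
    B = np.linalg.lstsq(T, U, rcond=None)[0]

    def _fractions(block: np.ndarray, joint: np.ndarray, scores_o: np.ndarray,
                   loadings_o: np.ndarray) -> dict:
        total = float((block**2).sum())
        ss_joint = float((joint**2).sum())
        ss_orth = float(((scores_o @ loadings_o.T) ** 2).sum())
        resid = max(total - ss_joint - ss_orth, 0.0)
        return {"joint": ss_joint / total, "orthogonal": ss_orth / total,
                "residual": resid / total}

    variance = {
        "x": _fractions(Xa, T @ W.T, T_o, P_ox),
        "y": _fractions(Ya, U @ C.T, U_o, P_oy),
    }
    return O2PLSModel(W=W, C=C, T=T, U=U, W_orth=W_o, P_orth_x=P_ox, T_orth=T_o,
                      C_orth=C_o, P_orth_y=P_oy, U_orth=U_o, B=B,
                      variance_explained=variance, n=n, nx=nx, ny=ny,
                      x_names=x_names, y_names=y_names)


@dataclass
class PermutationResult:
    """Permutation-null quantiles and the selected variable sets.

    ``null_loadings`` maps (side, component) to the pooled permuted
    loading values; ``lower_q``/``upper_q`` hold the α/2 and 1 − α/2
    empirical quantiles (inclusive, type-7).  ``significant_x`` /
    ``significant_y`` are the variables whose observed loading escapes the
    null band in at least one joint component.
    """

    n_perm: int
    alpha: float
    seed: int | None
    null_loadings: dict
    lower_q: dict
    upper_q: dict
    significant_x: set
    significant_y: set
    observed: O2PLSModel


def permutation_test(X, Y, n: int, nx: int = 0, ny: int = 0,
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int | None = None) -> PermutationResult:
    """Permutation significance test for O2PLS joint loadings.

    Each permutation reshuffles the rows of Y with a seeded RNG and refits
    the model; permuted loading vectors are sign-aligned to the observed
    ones (sign of the dot product) and pooled per component and side into
    an empirical null.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse alpha/2 quantiles; use >= 100",
            stacklevel=2,
        )
    observed = fit(X, Y, n, nx, ny)
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)

    null_w: dict[int, list[np.ndarray]] = {k: [] for k in range(n)}
    null_c: dict[int, list[np.ndarray]] = {k: [] for k in range(n)}
    for _ in range(n_perm):
        perm = rng.permutation(Ya.shape[0])
        m = fit(Xa, Ya[perm], n, nx, ny)
        for k in range(n):
            sw = 1.0 if m.W[:, k] @ observed.W[:, k] >= 0 else -1.0
            null_w[k].append(sw * m.W[:, k])
            sc = 1.0 if m.C[:, k] @ observed.C[:, k] >= 0 else -1.0
            null_c[k].append(sc * m.C[:, k])

    null_loadings, lower_q, upper_q = {}, {}, {}
    for side, null, loadings in (("x", null_w, observed.W),
                                 ("y", null_c, observed.C)):
        for k in range(n):
            pooled = np.concatenate(null[k])
            null_loadings[(side, k)] = pooled
            lower_q[(side, k)] = float(np.quantile(pooled, alpha / 2))
            upper_q[(side, k)] = float(np.quantile(pooled, 1 - alpha / 2))

    def _significant(loadings: np.ndarray, side: str, names: list) -> set:
        hits = set()
        for k in range(n):
            lo, hi = lower_q[(side, k)], upper_q[(side, k)]
            outside = (loadings[:, k] < lo) | (loadings[:, k] > hi)
            hits.update(names[i] for i in np.flatnonzero(outside))
        return hits

    return PermutationResult(
        n_perm=n_perm, alpha=alpha, seed=seed, null_loadings=null_loadings,
        lower_q=lower_q, upper_q=upper_q,
        significant_x=_significant(observed.W, "x", observed.x_names),
        significant_y=_significant(observed.C, "y", observed.y_names),
        observed=observed,
    )
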