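"""Taxon–HA and taxon–taxon Pearson correlation with BH-FDR control.

Edges carry the sample Pearson coefficient r, a two-sided p-value from
the t distribution with n − 2 degrees of freedom, the Benjamini–Hochberg
adjusted q-value, a sign, and a "robust" flag for |r| above a threshold
(0.95 by default).  The robust flag annotates rather than filters:
significance gating is by p (and q when FDR is enabled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import AbundanceTable, to_relative
from .errors import AlignmentError, DataError
from .ha_quant import HATable

logger = logging.getLogger(__name__)

__all__ = [
    "AssocConfig",
    "AssocResult",
    "pearson_pairwise",
    "bh_adjust",
    "filter_edges",
    "cooccurrence_network",
    "ha_sample_matrix",
]


@dataclass(frozen=True)
class AssocConfig:
    """Thresholds and data-handling policy for the correlation stage.

    ``nd_policy`` decides how ND concentrations enter the correlation:
    ``"zero"`` treats absence as a true 0 (default), ``"drop-pairwise"``
    excludes ND samples pair by pair.  ``sample_matching`` selects whether
    taxa and HAs are paired at replicate level (n = 18) or on timepoint
    means (n = 6).
    """

    p_cutoff: float = 0.05
    use_fdr: bool = True
    robust_r: float = 0.95
    nd_policy: str = "zero"
    sample_matching: str = "replicate-level"

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise DataError(f"p_cutoff must be in (0,1), got {self.p_cutoff}")
        if not 0 < self.robust_r <= 1:
            raise DataError(f"robust_r must be in (0,1], got {self.robust_r}")
        if self.nd_policy not in ("zero", "drop-pairwise"):
            raise DataError(f"unknown nd_policy {self.nd_policy!r}")
        if self.sample_matching not in ("replicate-level", "timepoint-means"):
            raise DataError(f"unknown sample_matching {self.sample_matching!r}")


@dataclass
class AssocResult:
    """Correlation edge set plus node metadata.

    ``edges`` columns: source, target, r, p, q, robust, sign.
    ``nodes`` columns: id, type (taxon | ha), mean_value.
    """

    edges: pd.DataFrame
    nodes: pd.DataFrame

    EDGE_COLUMNS = ("source", "target", "r", "p", "q", "robust", "sign")

    def __len__(self) -> int:
        return len(self.edges)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _corr_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r for every (row of x, row of y) pair over shared samples."""
    xz = x - x.mean(axis=1, keepdims=True)
    yz = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xz**2).sum(axis=1))
    yn = np.sqrt((yz**2).sum(axis=1))
    r = (xz @ yz.T) / np.outer(xn, yn)
    return np.clip(r, -1.0, 1.0)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pearson_pairwise(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    config: AssocConfig | None = None,
    *,
    x_type: str = "taxon",
    y_type: str = "ha",
) -> AssocResult:
    """All-pairs Pearson correlation between the rows of two feature tables.

    ``X`` and ``Y`` are features x samples with an identical ordered sample
    axis.  Zero-variance features yield no edges (logged); NaN cells
    trigger pairwise-complete computation per pair.
    """
    config = config or AssocConfig()
    if list(X.columns) != list(Y.columns):
        raise AlignmentError(
            "sample axes differ between the two tables: "
            f"{list(X.columns)[:4]}... vs {list(Y.columns)[:4]}..."
        )
    n = X.shape[1]
    if n < 3:
        raise DataError(f"need at least 3 shared samples, got {n}")

    x = X.to_numpy(dtype=float)
    y = Y.to_numpy(dtype=float)
    x_ok = np.nanstd(x, axis=1) > 0
    y_ok = np.nanstd(y, axis=1) > 0
    for name in X.index[~x_ok]:
        logger.warning("feature %s has zero variance; skipped", name)
    for name in Y.index[~y_ok]:
        logger.warning("feature %s has zero variance; skipped", name)
    xi = np.flatnonzero(x_ok)
    yi = np.flatnonzero(y_ok)

    rows: list[dict] = []
    if xi.size and yi.size:
        if np.isnan(x).any() or np.isnan(y).any():
            for i in xi:
                for j in yi:
                    mask = np.isfinite(x[i]) & np.isfinite(y[j])
                    if mask.sum() < 3:
                        continue
                    xv, yv = x[i, mask], y[j, mask]
                    if xv.std() == 0 or yv.std() == 0:
                        continue
                    r = float(_corr_matrix(xv[None, :], yv[None, :])[0, 0])
                    p = float(_p_from_r(np.array(r), int(mask.sum())))
                    rows.append({"source": X.index[i], "target": Y.index[j],
                                 "r": r, "p": p})
        else:
            r_mat = _corr_matrix(x[xi], y[yi])
            p_mat = _p_from_r(r_mat, n)
            for a, i in enumerate(xi):
                for b, j in enumerate(yi):
                    rows.append({"source": X.index[i], "target": Y.index[j],
                                 "r": float(r_mat[a, b]), "p": float(p_mat[a, b])})

    edges = pd.DataFrame(rows, columns=["source", "target", "r", "p"])
    edges["q"] = bh_adjust(edges["p"].to_numpy()) if len(edges) else np.nan
    edges["robust"] = edges["r"].abs() > config.robust_r if len(edges) else []
    edges["sign"] = np.where(edges["r"] >= 0, "+", "-") if len(edges) else []

    nodes = pd.concat([
        pd.DataFrame({"id": X.index, "type": x_type,
                      "mean_value": np.nanmean(x, axis=1)}),
        pd.DataFrame({"id": Y.index, "type": y_type,
                      "mean_value": np.nanmean(y, axis=1)}),
    ], ignore_index=True)
    return AssocResult(edges=edges, nodes=nodes)


def filter_edges(result: AssocResult, config: AssocConfig) -> AssocResult:
    """Keep edges passing the p (and, with FDR, q) cutoff; re-flag robustness."""
    edges = result.edges
    keep = edges["p"] <= config.p_cutoff
    if config.use_fdr:
        if edges["q"].isna().any() and len(edges):
            raise DataError("use_fdr requires q-values on every edge")
        keep &= edges["q"] <= config.p_cutoff
    out = edges.loc[keep].copy().reset_index(drop=True)
    out["robust"] = out["r"].abs() > config.robust_r
    return AssocResult(edges=out, nodes=result.nodes.copy())


def cooccurrence_network(table: AbundanceTable,
                         config: AssocConfig | None = None) -> AssocResult:
    """Taxon–taxon co-occurrence edges (undirected, unique pairs).

    Isolated taxa stay present in the node metadata so the full community
    graph can be reconstructed after filtering.
    """
    config = config or AssocConfig()
    rel = to_relative(table)
    res = pearson_pairwise(rel.data, rel.data, config,
                           x_type="taxon", y_type="taxon")
    order = {t: i for i, t in enumerate(rel.data.index)}
    edges = res.edges
    upper = edges[[order[s] < order[t]
                   for s, t in zip(edges["source"], edges["target"])]]
    edges = upper.copy().reset_index(drop=True)
    edges["q"] = bh_adjust(edges["p"].to_numpy()) if len(edges) else np.nan
    nodes = res.nodes.drop_duplicates(subset="id").reset_index(drop=True)
    return AssocResult(edges=edges, nodes=nodes)


def ha_sample_matrix(ha: HATable, config: AssocConfig) -> pd.DataFrame:
    """HA concentrations as a compound x sample matrix per the assoc policy.

    Replicate-level matching uses the replicate columns (n = 18);
    timepoint-means uses the summarized means (n = 6, column per
    timepoint).  ND cells become 0 under the ``zero`` policy and NaN under
    ``drop-pairwise``.
    """
    if config.sample_matching == "replicate-level":
        if ha.replicate_values is None:
            raise DataError("replicate-level matching needs replicate values")
        values = ha.replicate_values.copy()
        nd = ha.replicate_nd.astype(bool)
    else:
        values = ha.mean.copy()
        nd = ha.nd_mask.astype(bool)
    fill = 0.0 if config.nd_policy == "zero" else np.nan
    return values.mask(nd, fill)
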