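"""Abundance-table handling and alpha diversity.

The community side of the analysis works on a taxa x samples abundance
matrix (counts or relative abundances) with samples labelled
``D{day}R{rep}``.  Diversity is summarized per sample by the Simpson
dominance index (sum of squared proportions — larger means less diverse)
and by the bias-corrected Chao1 richness estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AbundanceTable",
    "DiversityResult",
    "to_relative",
    "simpson_index",
    "chao1",
    "alpha_diversity",
    "aggregate_to_rank",
    "top_fraction",
]

RANK_PREFIXES = {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
                 "family": "f", "genus": "g", "species": "s"}
RANK_ORDER = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    ``data`` is indexed by taxon id with sample-id columns; entries are
    non-negative counts or relative abundances.  ``lineage`` optionally
    maps each taxon id to a rank-prefixed lineage string such as
    ``k__Bacteria;p__Firmicutes;...;g__Lactococcus``.
    """

    data: pd.DataFrame
    lineage: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon ids: {dupes}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise DataError("abundances must be non-negative")
        if self.lineage is not None:
            self.lineage = self.lineage.reindex(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_days(self) -> pd.Series:
        """Day of each sample, parsed from the ``D{day}R{rep}`` label."""
        from .ha_quant import parse_sample_id

        return pd.Series({s: parse_sample_id(s)[0] for s in self.samples})


@dataclass
class DiversityResult:
    """Per-sample alpha-diversity summaries."""

    simpson: pd.Series
    chao1: pd.Series | None
    observed_otus: pd.Series


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize every sample column to sum to one."""
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DataError(f"all-zero samples cannot be normalized: {list(zero.index)}")
    return AbundanceTable(data=table.data.div(sums, axis=1), lineage=table.lineage)


def simpson_index(p, *, complement: bool = False, tol: float = 1e-6) -> float:
    """Simpson index of one sample's relative abundances.

    Returns the dominance form Σ p_i² by default (larger = less diverse);
    ``complement=True`` returns 1 − Σ p_i².
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise DataError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise DataError(f"relative abundances sum to {p.sum():.6g}, not 1")
    d = float(np.sum(p**2))
    return 1.0 - d if complement else d


def chao1(counts, *, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from one sample's integer counts.

    Bias-corrected form: S_obs + F1(F1−1)/(2(F2+1)), with F1/F2 the
    singleton/doubleton counts; the classical form F1²/(2 F2) is available
    with ``bias_corrected=False`` (undefined at F2 = 0).
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DataError("counts must be non-negative")
    if not np.allclose(c, np.round(c)):
        raise DataError("Chao1 requires integer counts")
    c = np.round(c).astype(int)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise DataError("classical Chao1 is undefined when there are no doubletons")
    return s_obs + f1**2 / (2.0 * f2)


def alpha_diversity(table: AbundanceTable) -> DiversityResult:
    """Simpson (always) and Chao1 (integer count tables only), per sample."""
    rel = to_relative(table)
    simpson = pd.Series(
        {s: simpson_index(rel.data[s].to_numpy()) for s in table.samples},
        name="simpson",
    )
    observed = (table.data > 0).sum(axis=0).astype(int)
    observed.name = "observed_otus"
    vals = table.data.to_numpy(dtype=float)
    is_counts = np.allclose(vals, np.round(vals)) and vals.max() > 1
    chao = None
    if is_counts:
        chao = pd.Series(
            {s: chao1(table.data[s].to_numpy()) for s in table.samples},
            name="chao1",
        )
    return DiversityResult(simpson=simpson, chao1=chao, observed_otus=observed)


def _rank_label(lineage: str, rank: str) -> str:
    """Extract the label at ``rank``; pool unclassified under ``norank_``."""
    prefix = RANK_PREFIXES[rank]
    fields = {}
    for part in str(lineage).split(";"):
        part = part.strip()
        if "__" in part:
            pfx, _, name = part.partition("__")
            fields[pfx.strip()] = name.strip()
    label = fields.get(prefix, "")
    if label:
        return label
    # fall back to the deepest classified ancestor, norank_-prefixed
    for r in reversed(RANK_ORDER[: RANK_ORDER.index(rank)]):
        pfx = RANK_PREFIXES[r]
        if fields.get(pfx):
            return f"norank_{pfx}_{fields[pfx]}"
    return "norank_unclassified"


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum rows sharing the same label at a taxonomy rank.

    Taxa whose lineage is unclassified at ``rank`` are pooled into a
    ``norank_``-prefixed label derived from the deepest classified
    ancestor (e.g. ``norank_f_Erysipelotrichaceae``).
    """
    if rank not in RANK_PREFIXES:
        raise DataError(f"unknown rank {rank!r}; expected one of {RANK_ORDER}")
    if table.lineage is None or table.lineage.isna().any():
        missing = (
            list(table.data.index) if table.lineage is None
            else list(table.lineage.index[table.lineage.isna()])
        )
        raise DataError(f"lineage missing for taxa: {missing[:5]}...")
    labels = table.lineage.map(lambda lin: _rank_label(lin, rank))
    grouped = table.data.groupby(labels, sort=False).sum()
    return AbundanceTable(data=grouped, lineage=None)


def top_fraction(table: AbundanceTable, fraction: float = 0.20) -> set[str]:
    """Taxa in the top ``fraction`` by mean relative abundance.

    Taxa are ranked by their mean relative abundance across all samples
    (descending, ties broken lexicographically by id) and the first
    ``ceil(fraction * n_taxa)`` are returned.
    """
    if not 0 < fraction <= 1:
        raise DataError(f"fraction must be in (0, 1], got {fraction}")
    if table.data.empty:
        raise DataError("cannot rank an empty abundance table")
    rel = to_relative(table)
    means = rel.data.mean(axis=1)
    order = sorted(means.index, key=lambda t: (-means[t], str(t)))
    k = math.ceil(fraction * len(order))
    return set(order[:k])
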