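"""Internal-standard semiquantification of higher alcohols (HAs) and
summary statistics over the compound x timepoint concentration table.

Concentrations follow the single-point internal-standard relation

    C = dilution_factor * (A_c / A_is) * C_is        [µg/L]

where ``A_c`` and ``A_is`` are the GC-MS peak areas of the analyte and of
the spiked internal standard (2-octanol), ``C_is`` is the in-vial
internal-standard concentration and ``dilution_factor`` accounts for the
dilution of the sample into the extraction vial.  The method is
semiquantitative: one internal standard, no per-compound calibration
curve.

"Not detected" (ND) is an explicit mask throughout — a cell below the
method's detection capability is distinct from a measured zero, and the
decision to treat ND as 0 belongs to downstream consumers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    ConfigurationError,
    DataError,
    QuantificationError,
)

__all__ = [
    "QuantConfig",
    "PeakTable",
    "HATable",
    "CompoundAnnotation",
    "DetectionStats",
    "quantify",
    "summarize_replicates",
    "total_concentration",
    "detection_stats",
    "high_content_filter",
    "classify_alkanols",
    "load_table1",
    "load_annotation",
    "parse_sample_id",
]

_SAMPLE_ID_RE = re.compile(r"^D(\d+)R(\d+)$")


def parse_sample_id(sample_id: str) -> tuple[int, int]:
    """Parse a ``D{day}R{rep}`` sample label into ``(day, replicate)``."""
    m = _SAMPLE_ID_RE.match(str(sample_id))
    if m is None:
        raise DataError(f"sample id {sample_id!r} is not of the form D<day>R<rep>")
    return int(m.group(1)), int(m.group(2))


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of the internal-standard quantification.

    Parameters
    ----------
    c_is
        In-vial internal-standard concentration, µg/L.  For the reference
        protocol (60 µL of 8800 µg/L 2-octanol in a 6.0 mL vial) this is
        88 µg/L.
    dilution_factor
        Unitless vial dilution factor multiplying the area ratio
        (default 12, i.e. 6.0 mL vial volume / 0.5 mL sample).
    detection_limit
        Concentration in µg/L below which a quantified value is reported
        ND.  0 means "report as measured".
    """

    c_is: float
    dilution_factor: float = 12.0
    detection_limit: float = 0.0

    def __post_init__(self) -> None:
        if not self.c_is > 0:
            raise ConfigurationError(f"c_is must be positive, got {self.c_is}")
        if not self.dilution_factor > 0:
            raise ConfigurationError(
                f"dilution_factor must be positive, got {self.dilution_factor}"
            )
        if self.detection_limit < 0:
            raise ConfigurationError("detection_limit must be >= 0")


@dataclass
class PeakTable:
    """Long-format GC-MS peak areas.

    ``records`` has columns ``compound``, ``sample_id``, ``area`` (analyte
    peak area, arbitrary units, >= 0) and ``is_area`` (internal-standard
    peak area, > 0).
    """

    records: pd.DataFrame

    REQUIRED_COLUMNS = ("compound", "sample_id", "area", "is_area")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"PeakTable is missing columns: {missing}")
        if (self.records["area"] < 0).any():
            bad = self.records.loc[self.records["area"] < 0].iloc[0]
            raise DataError(
                f"negative peak area for {bad['compound']!r} in {bad['sample_id']!r}"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HATable:
    """Higher-alcohol concentration table (compound x timepoint), µg/L.

    ``mean`` holds NaN wherever ``nd_mask`` is True; ``se`` is the standard
    error over replicates where at least two replicates were detected.
    ``replicate_values``/``replicate_nd`` (compound x sample id, samples
    labelled ``D{day}R{rep}``) are retained when the table was built from
    replicate-level measurements.
    """

    mean: pd.DataFrame
    nd_mask: pd.DataFrame
    se: pd.DataFrame | None = None
    replicate_values: pd.DataFrame | None = None
    replicate_nd: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mean.shape != self.nd_mask.shape:
            raise DataError("mean and nd_mask shapes differ")
        detected = ~self.nd_mask.to_numpy(dtype=bool)
        vals = self.mean.to_numpy(dtype=float)
        if np.any(detected & ~np.isfinite(vals)):
            raise DataError("detected cells must carry finite concentrations")
        if np.any(vals[detected] < 0):
            raise DataError("concentrations must be non-negative")

    @property
    def compounds(self) -> list[str]:
        return list(self.mean.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.mean.columns)


@dataclass
class CompoundAnnotation:
    """Compound -> chemistry flags, keyed case-insensitively.

    ``table`` is indexed by compound name with boolean column
    ``is_straight_chain_saturated_alkan1ol`` and integer ``carbon_count``.
    """

    table: pd.DataFrame
    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {_normalize_name(name): name for name in self.table.index}

    def lookup(self, compound: str) -> pd.Series:
        key = _normalize_name(compound)
        if key not in self._index:
            raise AnnotationError(f"compound {compound!r} is not annotated")
        return self.table.loc[self._index[key]]

    def __contains__(self, compound: str) -> bool:
        return _normalize_name(compound) in self._index


def _normalize_name(name: str) -> str:
    s = str(name).strip().lower()
    s = s.replace("–", "-").replace("—", "-")
    s = re.sub(r"\s*-\s*", "-", s)
    s = re.sub(r"\s*,\s*", ",", s)
    s = re.sub(r"\s+", " ", s)
    return s.rstrip(".")


@dataclass
class DetectionStats:
    """Detection counts derived from an HATable's ND mask."""

    per_compound: pd.Series  # timepoints detected, per compound
    per_timepoint: pd.Series  # compounds detected, per timepoint
    stable: pd.Series  # per compound: detected >= min_detections times
    min_detections: int

    @property
    def n_compounds_detected(self) -> int:
        return int((self.per_compound > 0).sum())

    @property
    def stable_compounds(self) -> set[str]:
        return set(self.stable.index[self.stable])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def quantify(peaks: PeakTable, quant: QuantConfig) -> HATable:
    """Convert peak areas to a replicate-level concentration table.

    Returns an :class:`HATable` whose columns are the individual sample
    ids; pass the result to :func:`summarize_replicates` for the
    timepoint-level mean ± SE table.
    """
    rec = peaks.records
    bad = rec["is_area"] <= 0
    if bad.any():
        r = rec.loc[bad].iloc[0]
        raise QuantificationError(
            f"non-positive internal-standard area for compound "
            f"{r['compound']!r} in sample {r['sample_id']!r}"
        )
    conc = quant.dilution_factor * (rec["area"] / rec["is_area"]) * quant.c_is
    wide = (
        rec.assign(concentration=conc)
        .pivot_table(index="compound", columns="sample_id", values="concentration",
                     aggfunc="first", sort=False)
    )
    wide = wide.loc[pd.unique(rec["compound"])]
    nd = wide.isna()
    if quant.detection_limit > 0:
        nd = nd | (wide < quant.detection_limit)
    mean = wide.mask(nd)
    return HATable(mean=mean, nd_mask=nd, replicate_values=wide.copy(),
                   replicate_nd=nd.copy())


def summarize_replicates(ha: HATable) -> HATable:
    """Collapse replicate columns to per-timepoint mean ± SE.

    The mean is taken over detected replicates only; SE = sample SD / √n
    (defined where at least two replicates were detected).  A timepoint is
    ND only when every replicate is ND.
    """
    if ha.replicate_values is None or ha.replicate_nd is None:
        raise DataError("HATable carries no replicate-level values to summarize")
    values = ha.replicate_values
    nd = ha.replicate_nd.astype(bool)
    days = sorted({parse_sample_id(s)[0] for s in values.columns})
    labels = [f"D{d}" for d in days]
    mean = pd.DataFrame(index=values.index, columns=labels, dtype=float)
    se = pd.DataFrame(index=values.index, columns=labels, dtype=float)
    nd_out = pd.DataFrame(True, index=values.index, columns=labels)
    for day, label in zip(days, labels):
        cols = [c for c in values.columns if parse_sample_id(c)[0] == day]
        if not cols:
            raise DataError(f"timepoint day {day} has no replicates")
        detected = ~nd[cols]
        vals = values[cols].where(detected)
        n = detected.sum(axis=1)
        mean[label] = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        se[label] = (sd / np.sqrt(n)).where(n >= 2)
        nd_out[label] = n == 0
    mean = mean.mask(nd_out)
    se = se.mask(nd_out)
    return HATable(mean=mean, nd_mask=nd_out, se=se,
                   replicate_values=ha.replicate_values,
                   replicate_nd=ha.replicate_nd)


def total_concentration(ha: HATable, timepoint: str | int) -> float:
    """Total detected HA concentration (µg/L) at one timepoint."""
    label = f"D{timepoint}" if not str(timepoint).startswith("D") else str(timepoint)
    if label not in ha.mean.columns:
        raise DataError(
            f"unknown timepoint {timepoint!r}; table has {list(ha.mean.columns)}"
        )
    col = ha.mean[label].where(~ha.nd_mask[label])
    return float(col.fillna(0.0).sum())


def detection_stats(ha: HATable, min_detections: int = 5) -> DetectionStats:
    """Per-compound and per-timepoint detection counts and the stable flag.

    A compound is "stable" when it was detected in at least
    ``min_detections`` timepoints (default 5 of the 6 sampling days).
    """
    detected = ~ha.nd_mask.astype(bool)
    per_compound = detected.sum(axis=1).astype(int)
    per_timepoint = detected.sum(axis=0).astype(int)
    stable = per_compound >= min_detections
    return DetectionStats(per_compound=per_compound, per_timepoint=per_timepoint,
                          stable=stable, min_detections=min_detections)


def high_content_filter(ha: HATable, threshold: float = 1000.0) -> set[str]:
    """Compounds whose maximum timepoint mean strictly exceeds ``threshold`` µg/L."""
    detected = ha.mean.where(~ha.nd_mask.astype(bool))
    maxima = detected.max(axis=1)
    return set(maxima.index[maxima > threshold])


def classify_alkanols(ha: HATable, ann: CompoundAnnotation) -> set[str]:
    """Compounds flagged as straight-chain saturated alkan-1-ols."""
    missing = [c for c in ha.compounds if c not in ann]
    if missing:
        raise AnnotationError(f"unannotated compounds: {missing}")
    return {
        c for c in ha.compounds
        if bool(ann.lookup(c)["is_straight_chain_saturated_alkan1ol"])
    }


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

def load_table1() -> HATable:
    """The packaged 23-compound x 6-timepoint HA concentration table."""
    from .io import read_ha_csv  # local import to avoid a cycle

    with resources.as_file(
        resources.files("huangjiu_core.data") / "table1_mean_se.csv"
    ) as path:
        return read_ha_csv(path)


def load_annotation() -> CompoundAnnotation:
    """The packaged compound annotation (alkan-1-ol flags, carbon counts)."""
    with resources.as_file(
        resources.files("huangjiu_core.data") / "compound_annotation.csv"
    ) as path:
        table = pd.read_csv(path, index_col="compound")
    table["is_straight_chain_saturated_alkan1ol"] = (
        table["is_straight_chain_saturated_alkan1ol"]
        .astype(str).str.strip().str.lower().map({"true": True, "false": False})
    )
    table["carbon_count"] = table["carbon_count"].astype(int)
    return CompoundAnnotation(table=table)
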