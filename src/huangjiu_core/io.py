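"""File formats, pipeline configuration and provenance.

Formats are plain text throughout: abundance tables as TSV (taxa rows,
``D{day}R{rep}`` sample columns, optional trailing ``lineage`` column),
HA concentration tables as wide CSV (``D{day}_mean`` / ``D{day}_se``
columns with the literal token ``ND`` for non-detects), peak tables as
long CSV, edge lists as TSV, networks as GraphML.  Readers reject rather
than coerce: a malformed cell raises a :class:`~.errors.FormatError`
naming its coordinates.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .assoc import AssocConfig, AssocResult
from .community import AbundanceTable
from .errors import ConfigurationError, FormatError
from .ha_quant import HATable, PeakTable, QuantConfig
from .o2pls import ScalingSpec

__all__ = [
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_ha_csv",
    "write_ha_csv",
    "read_peak_csv",
    "write_peak_csv",
    "write_edges_tsv",
    "write_graphml",
    "PipelineConfig",
    "load_config",
    "provenance_record",
]

ND_TOKEN = "ND"
#: thousands separators tolerated in printed concentration tables
_SEPARATORS = str.maketrans("", "", ",\u2009\u00a0 ")


def _parse_number(cell: str, *, where: str) -> float:
    s = str(cell).strip().translate(_SEPARATORS)
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"malformed numeric cell {cell!r} at {where}") from None


def _format_number(v: float) -> str:
    return format(float(v), ".12g")


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def read_abundance_tsv(path: str | Path) -> AbundanceTable:
    """Read a taxa x samples TSV (first column taxon id, optional ``lineage``)."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must carry at least one sample id")
    has_lineage = header[-1] == "lineage"
    sample_ids = header[1:-1] if has_lineage else header[1:]
    taxa, rows, lineages = [], [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: row {ln_no} has {len(fields)} fields, "
                f"expected {len(header)}"
            )
        taxa.append(fields[0])
        numeric = fields[1:-1] if has_lineage else fields[1:]
        rows.append([
            _parse_number(c, where=f"{path} row {ln_no} column {header[j + 1]!r}")
            for j, c in enumerate(numeric)
        ])
        if has_lineage:
            lineages.append(fields[-1])
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise FormatError(f"{path}: duplicate taxon ids {dupes}")
    data = pd.DataFrame(rows, index=taxa, columns=sample_ids, dtype=float)
    lineage = pd.Series(lineages, index=taxa) if has_lineage else None
    return AbundanceTable(data=data, lineage=lineage)


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    header = ["taxon"] + list(table.data.columns)
    if table.lineage is not None:
        header.append("lineage")
    lines = ["\t".join(header)]
    for taxon in table.data.index:
        fields = [str(taxon)] + [_format_number(v) for v in table.data.loc[taxon]]
        if table.lineage is not None:
            fields.append(str(table.lineage[taxon]))
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# HA concentration tables
# ---------------------------------------------------------------------------

_MEAN_COL_RE = re.compile(r"^D(\d+)(R\d+)?(_mean)?$")
_SE_COL_RE = re.compile(r"^D(\d+)_se$")


def read_ha_csv(path: str | Path) -> HATable:
    """Read a wide compound x timepoint CSV with ``ND`` tokens.

    Columns are ``compound`` then ``D{day}_mean`` (or bare ``D{day}`` /
    ``D{day}R{rep}`` for replicate-level tables) with optional
    ``D{day}_se`` columns.  Thousands separators in printed tables
    ("16,280.09") are stripped; the token ``ND`` maps to the ND mask,
    never to 0.
    """
    path = Path(path)
    if not path.read_text().strip():
        raise FormatError(f"{path}: empty file")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "compound" not in raw.columns:
        raise FormatError(f"{path}: missing 'compound' column")
    mean_cols, se_cols = [], {}
    for col in raw.columns:
        if col == "compound":
            continue
        if _SE_COL_RE.match(col):
            se_cols[col] = f"D{_SE_COL_RE.match(col).group(1)}"
        elif _MEAN_COL_RE.match(col):
            mean_cols.append(col)
        else:
            raise FormatError(f"{path}: unknown column {col!r}")
    if not mean_cols:
        raise FormatError(f"{path}: no concentration columns found")
    compounds = list(raw["compound"])

    def _label(col: str) -> str:
        return col[:-5] if col.endswith("_mean") else col

    def _parse_block(cols: list[str], labels: list[str]):
        values = pd.DataFrame(np.nan, index=compounds, columns=labels)
        nd = pd.DataFrame(True, index=compounds, columns=labels)
        for col, label in zip(cols, labels):
            j = values.columns.get_loc(label)
            for i, cell in enumerate(raw[col]):
                cell = str(cell).strip()
                if cell == ND_TOKEN or cell == "":
                    continue
                values.iloc[i, j] = _parse_number(
                    cell, where=f"{path} compound {compounds[i]!r} column {col!r}"
                )
                nd.iloc[i, j] = False
        return values, nd

    mean, nd = _parse_block(mean_cols, [_label(c) for c in mean_cols])
    se = None
    if se_cols:
        se, _ = _parse_block(list(se_cols), [se_cols[c] for c in se_cols])
    replicate_like = any("R" in _label(c) for c in mean_cols)
    return HATable(
        mean=mean, nd_mask=nd, se=se,
        replicate_values=mean.copy() if replicate_like else None,
        replicate_nd=nd.copy() if replicate_like else None,
    )


def write_ha_csv(ha: HATable, path: str | Path) -> None:
    path = Path(path)
    columns = ["compound"]
    for tp in ha.timepoints:
        columns.append(f"{tp}_mean" if not re.search(r"R\d+$", tp) else tp)
        if ha.se is not None and tp in ha.se.columns:
            columns.append(f"{tp}_se")
    rows = [",".join(columns)]
    for compound in ha.compounds:
        fields = [f'"{compound}"' if "," in str(compound) else str(compound)]
        for tp in ha.timepoints:
            if bool(ha.nd_mask.loc[compound, tp]):
                fields.append(ND_TOKEN)
                if ha.se is not None and tp in ha.se.columns:
                    fields.append(ND_TOKEN)
            else:
                fields.append(_format_number(ha.mean.loc[compound, tp]))
                if ha.se is not None and tp in ha.se.columns:
                    sv = ha.se.loc[compound, tp]
                    fields.append(ND_TOKEN if pd.isna(sv) else _format_number(sv))
        rows.append(",".join(fields))
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def read_peak_csv(path: str | Path) -> PeakTable:
    """Read a long-format peak-area CSV (compound, sample_id, area, is_area)."""
    path = Path(path)
    if not path.read_text().strip():
        raise FormatError(f"{path}: empty file")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = list(PeakTable.REQUIRED_COLUMNS)
    unknown = [c for c in raw.columns if c not in expected]
    if unknown:
        raise FormatError(f"{path}: unknown columns {unknown}")
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = raw.copy()
    for col in ("area", "is_area"):
        records[col] = [
            _parse_number(c, where=f"{path} row {i + 2} column {col!r}")
            for i, c in enumerate(raw[col])
        ]
    return PeakTable(records=records)


def write_peak_csv(peaks: PeakTable, path: str | Path) -> None:
    peaks.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_edges_tsv(result: AssocResult, path: str | Path) -> None:
    result.edges.to_csv(path, sep="\t", index=False)


def write_graphml(result: AssocResult, path: str | Path) -> None:
    """Export the edge set (plus isolated nodes) as GraphML."""
    g = nx.Graph()
    for _, node in result.nodes.iterrows():
        g.add_node(str(node["id"]), type=str(node["type"]),
                   mean_value=float(node["mean_value"]))
    for _, e in result.edges.iterrows():
        g.add_edge(str(e["source"]), str(e["target"]), r=float(e["r"]),
                   p=float(e["p"]),
                   q=float(e["q"]) if pd.notna(e["q"]) else float("nan"),
                   robust=bool(e["robust"]), sign=str(e["sign"]))
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# pipeline configuration & provenance
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One document controlling every pipeline stage.

    Exactly one of ``inputs`` (paths to abundance / HA / peak files) and
    ``sim`` (synthetic-generation parameters) must be set.  The global
    ``seed`` is propagated to every stochastic stage.
    """

    outdir: str | Path = "results"
    seed: int = 0
    sim: dict | None = None
    inputs: dict | None = None
    quant: dict = field(default_factory=dict)
    # pipeline default: correlate on timepoint means — the three parallel
    # mashes are technical replicates sharing a timepoint mean, so
    # replicate-level correlation would overstate the degrees of freedom
    assoc: dict = field(default_factory=lambda: {
        "sample_matching": "timepoint-means",
    })
    scaling: dict = field(default_factory=dict)
    o2pls: dict = field(default_factory=lambda: {"n": 2, "nx": 1, "ny": 1,
                                                 "n_perm": 1000, "alpha": 0.05})
    criteria: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'sim' and 'inputs' must be configured"
            )

    def quant_config(self) -> QuantConfig:
        return QuantConfig(**{"c_is": 88.0, **self.quant})

    def assoc_config(self) -> AssocConfig:
        return AssocConfig(**self.assoc)

    def scaling_spec(self) -> ScalingSpec:
        return ScalingSpec(**self.scaling)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    merged = dict(doc)
    if "o2pls" in merged:
        defaults = {"n": 2, "nx": 1, "ny": 1, "n_perm": 1000, "alpha": 0.05}
        merged["o2pls"] = {**defaults, **merged["o2pls"]}
    return PipelineConfig(**merged)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def provenance_record(config: PipelineConfig,
                      input_paths: dict[str, str | Path] | None = None) -> dict:
    """Config echo, seed, package version and input content hashes."""
    from . import __version__

    record = {
        "package": "huangjiu-core",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "inputs": {},
    }
    for name, p in (input_paths or {}).items():
        p = Path(p)
        record["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    return record


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
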