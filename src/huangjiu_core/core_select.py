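"""Functional-core HA-producing bacteria: combine the evidence gates.

A genus is called core when it (i) carries a permutation-significant
O2PLS joint loading (optional gate, on by default), (ii) sits in the top
abundance stratum (top 20% by mean relative abundance), and (iii) is
significantly correlated with at least one stable HA — an alcohol
detected in at least 5 of the 6 fermentation timepoints.  The report
keeps the full evidence trail per genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assoc as assoc_mod
from . import community, ha_quant, o2pls, synthetic
from .errors import AlignmentError, DataError, PipelineError
from .ha_quant import DetectionStats

logger = logging.getLogger(__name__)

__all__ = ["CoreCriteria", "CoreTaxaReport", "select_core", "run_pipeline"]


@dataclass(frozen=True)
class CoreCriteria:
    """Thresholds of the core-taxon call."""

    top_fraction: float = 0.20
    min_detections: int = 5
    p_cutoff: float = 0.05
    require_significant: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise DataError(f"top_fraction must be in (0,1], got {self.top_fraction}")
        if self.min_detections < 1:
            raise DataError("min_detections must be >= 1")
        if not 0 < self.p_cutoff < 1:
            raise DataError(f"p_cutoff must be in (0,1), got {self.p_cutoff}")


@dataclass
class CoreTaxaReport:
    """Selected core genera plus the per-genus evidence trail."""

    core_taxa: list[str]
    evidence: dict[str, dict]
    criteria: CoreCriteria
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "core_taxa": self.core_taxa,
            "evidence": self.evidence,
            "criteria": vars(self.criteria).copy(),
            "provenance": self.provenance,
        }

    def to_markdown(self) -> str:
        lines = ["# Core HA-producing taxa", ""]
        if not self.core_taxa:
            lines.append("No taxon passed all criteria.")
        for taxon in self.core_taxa:
            ev = self.evidence[taxon]
            lines.append(
                f"- **{taxon}** — abundance rank {ev['abundance_rank']}, "
                f"mean relative abundance {ev['mean_relative_abundance']:.4f}, "
                f"O2PLS-significant: {ev['significant']}"
            )
            for e in ev["stable_ha_links"]:
                lines.append(
                    f"    - {e['target']}: r = {e['r']:.3f}, p = {e['p']:.3g}, "
                    f"q = {e['q']:.3g}"
                )
        return "\n".join(lines) + "\n"


def select_core(significant_taxa: set[str],
                assoc_result: assoc_mod.AssocResult,
                abundance: community.AbundanceTable,
                ha_stats: DetectionStats,
                criteria: CoreCriteria | None = None,
                provenance: dict | None = None) -> CoreTaxaReport:
    """Apply the core-taxon criteria and assemble the evidence report.

    ``assoc_result`` should already be filtered to significant edges; the
    stability gate uses adjusted p-values when they are present (i.e. the
    correlation stage ran with FDR), raw p otherwise.
    """
    criteria = criteria or CoreCriteria()
    taxa = set(abundance.taxa)
    edge_taxa = set(assoc_result.edges["source"]) if len(assoc_result.edges) else set()
    stray = edge_taxa - taxa
    if stray:
        raise AlignmentError(
            f"edge sources missing from the abundance table: {sorted(stray)[:5]}"
        )
    if criteria.require_significant and (significant_taxa - taxa):
        raise AlignmentError(
            "significant taxa missing from the abundance table: "
            f"{sorted(significant_taxa - taxa)[:5]}"
        )

    rel = community.to_relative(abundance)
    mean_rel = rel.data.mean(axis=1)
    ranks = mean_rel.rank(ascending=False, method="min").astype(int)
    top = community.top_fraction(abundance, criteria.top_fraction)
    stable = ha_stats.stable_compounds

    edges = assoc_result.edges
    use_q = len(edges) > 0 and edges["q"].notna().all()
    sig_col = "q" if use_q else "p"

    candidates = top if not criteria.require_significant else top & significant_taxa
    evidence: dict[str, dict] = {}
    core: list[str] = []
    for taxon in candidates:
        if len(edges):
            mine = edges[(edges["source"] == taxon)
                         & edges["target"].isin(stable)
                         & (edges[sig_col] <= criteria.p_cutoff)]
        else:
            mine = edges
        links = [
            {"target": e["target"], "r": float(e["r"]), "p": float(e["p"]),
             "q": float(e["q"]) if pd.notna(e["q"]) else None}
            for _, e in mine.iterrows()
        ]
        if not links:
            continue
        core.append(taxon)
        evidence[taxon] = {
            "significant": taxon in significant_taxa,
            "abundance_rank": int(ranks[taxon]),
            "mean_relative_abundance": float(mean_rel[taxon]),
            "stable_ha_links": links,
        }
    core.sort(key=lambda t: (-mean_rel[t], str(t)))
    return CoreTaxaReport(core_taxa=core, evidence=evidence, criteria=criteria,
                          provenance=provenance or {})


def run_pipeline(config) -> CoreTaxaReport:
    """Run every stage end to end and write all intermediate artifacts.

    ``config`` is an :class:`~huangjiu_core.io.PipelineConfig`.  Synthetic
    mode generates the paired datasets from the configured SimConfig;
    file mode reads the configured abundance / HA (or peak) tables.
    Identical config + seed give an identical report.
    """
    from . import io as io_mod

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quant = config.quant_config()
    assoc_cfg = config.assoc_config()
    scaling = config.scaling_spec()
    criteria = CoreCriteria(**config.criteria)
    truth = None
    input_paths: dict[str, str] = {}

    stage = "inputs"
    try:
        if config.sim is not None:
            stage = "simulate"
            sim = synthetic.SimConfig(**{**config.sim, "seed": config.seed})
            abundance, truth = synthetic.generate_community(sim)
            ha_replicate = synthetic.generate_ha(abundance, truth, sim)
            peaks = synthetic.generate_peak_table(ha_replicate, quant)
            io_mod.write_abundance_tsv(abundance, outdir / "abundance.tsv")
            io_mod.write_peak_csv(peaks, outdir / "peaks.csv")
        else:
            stage = "read-inputs"
            paths = dict(config.inputs)
            input_paths = {k: str(v) for k, v in paths.items()}
            abundance = io_mod.read_abundance_tsv(paths["abundance"])
            if "peaks" in paths:
                peaks = io_mod.read_peak_csv(paths["peaks"])
            elif "ha" in paths:
                peaks = None
                ha_replicate = io_mod.read_ha_csv(paths["ha"])
            else:
                raise PipelineError("inputs must name 'peaks' or 'ha'")

        stage = "quantify"
        if peaks is not None:
            ha_replicate = ha_quant.quantify(peaks, quant)
        if ha_replicate.replicate_values is not None:
            ha_summary = ha_quant.summarize_replicates(ha_replicate)
        else:
            ha_summary = ha_replicate
        io_mod.write_ha_csv(ha_summary, outdir / "ha_summary.csv")

        stage = "diversity"
        diversity = community.alpha_diversity(abundance)
        div = pd.DataFrame({"simpson": diversity.simpson,
                            "observed_otus": diversity.observed_otus})
        if diversity.chao1 is not None:
            div["chao1"] = diversity.chao1
        div.index.name = "sample_id"
        div.to_csv(outdir / "diversity.csv")

        stage = "correlate"
        rel = community.to_relative(abundance)

        def _taxa_matrix(matching: str) -> pd.DataFrame:
            if matching == "timepoint-means":
                day_means = {
                    f"D{day}": rel.data.loc[
                        :, [s for s in rel.data.columns
                            if s.startswith(f"D{day}R")]].mean(axis=1)
                    for day in sorted({ha_quant.parse_sample_id(s)[0]
                                       for s in rel.data.columns})
                }
                return pd.DataFrame(day_means)
            return rel.data

        ha_matrix = assoc_mod.ha_sample_matrix(ha_summary, assoc_cfg)
        taxa_matrix = _taxa_matrix(assoc_cfg.sample_matching)
        correlations = assoc_mod.pearson_pairwise(taxa_matrix, ha_matrix, assoc_cfg)
        filtered = assoc_mod.filter_edges(correlations, assoc_cfg)
        io_mod.write_edges_tsv(correlations, outdir / "correlations_all.tsv")
        io_mod.write_edges_tsv(filtered, outdir / "correlations_significant.tsv")
        io_mod.write_graphml(filtered, outdir / "network.graphml")

        stage = "o2pls"
        dims = dict(config.o2pls)
        # the permutation null benefits from every sample: O2PLS runs at
        # replicate level unless configured otherwise
        o2pls_matching = dims.pop("sample_matching", "replicate-level")
        o2pls_assoc = assoc_mod.AssocConfig(nd_policy=assoc_cfg.nd_policy,
                                            sample_matching=o2pls_matching)
        X = o2pls.normalize(_taxa_matrix(o2pls_matching).T, scaling, block="x")
        Y = o2pls.normalize(assoc_mod.ha_sample_matrix(ha_summary, o2pls_assoc).T,
                            scaling, block="y")
        perm = o2pls.permutation_test(
            X, Y, n=dims["n"], nx=dims["nx"], ny=dims["ny"],
            n_perm=dims["n_perm"], alpha=dims["alpha"],
            seed=config.seed,
        )
        io_mod.write_json(
            {
                "significant_x": perm.significant_x,
                "significant_y": perm.significant_y,
                "lower_q": {f"{s}_{k}": v for (s, k), v in perm.lower_q.items()},
                "upper_q": {f"{s}_{k}": v for (s, k), v in perm.upper_q.items()},
                "n_perm": perm.n_perm,
                "alpha": perm.alpha,
                "seed": perm.seed,
                "variance_explained": perm.observed.variance_explained,
            },
            outdir / "o2pls.json",
        )
        pd.DataFrame(perm.observed.W, index=perm.observed.x_names,
                     columns=[f"joint_{k + 1}" for k in range(dims["n"])]
                     ).to_csv(outdir / "o2pls_x_loadings.csv")
        pd.DataFrame(perm.observed.C, index=perm.observed.y_names,
                     columns=[f"joint_{k + 1}" for k in range(dims["n"])]
                     ).to_csv(outdir / "o2pls_y_loadings.csv")

        stage = "select-core"
        stats = ha_quant.detection_stats(ha_summary,
                                         min_detections=criteria.min_detections)
        prov = io_mod.provenance_record(config, input_paths or None)
        if truth is not None:
            prov["ground_truth"] = {
                "producers": truth.producer_ids,
                "dominant_taxon": truth.dominant_taxon,
                "planted_stable_has": sorted(truth.planted_stable_has),
            }
        report = select_core(perm.significant_x, filtered, abundance, stats,
                             criteria, provenance=prov)
        io_mod.write_json(report.to_dict(), outdir / "core_taxa.json")
        (outdir / "core_taxa.md").write_text(report.to_markdown())
        io_mod.write_json(prov, outdir / "provenance.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline finished: %d core taxa", len(report.core_taxa))
    return report
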