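"""Fermentation-like synthetic paired datasets with known ground truth.

The generator emulates the study design of a 10-day semisolid Huangjiu
fermentation sampled every two days in triplicate (6 timepoints x 3
replicates): a compositional bacterial community with one dominant genus
and many low-abundance background genera, plus a set of planted
"producer" genera whose relative abundances linearly drive a subset of
higher-alcohol (HA) concentrations.

Structure of a generated dataset:

* producers follow smooth temporal templates (logistic growth or a
  Gaussian bump, chosen per taxon by the seeded RNG) at high baseline
  abundance, so that they land in the top stratum of mean relative
  abundance;
* background taxa draw i.i.d. log-normal timepoint means around a
  constant low baseline;
* the dominant taxon occupies a target share of the community with
  log-normal jitter on its odds, which — through compositional closure —
  suppresses every other taxon when it fluctuates upward;
* replicates share the timepoint mean and differ only by multiplicative
  log-normal noise of relative SD ``noise_sd``;
* driven HA concentrations are an exact linear map of producer relative
  abundances times multiplicative log-normal noise; undriven HAs are pure
  log-normal noise around a small baseline;
* concentrations below ``detection_limit`` are recorded ND (masked, never
  zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .errors import AlignmentError, ConfigurationError
from .ha_quant import HATable, PeakTable, QuantConfig, summarize_replicates

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_community",
    "generate_ha",
    "generate_peak_table",
]

#: µg/L of HA produced per unit producer relative abundance at effect_size 1
CONC_SCALE = 20_000.0
#: baseline µg/L scale of undriven (pure-noise) HAs
BACKGROUND_HA_SCALE = 200.0
#: fixed internal-standard peak area used when synthesizing peak tables
IS_AREA = 1.0e6


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic fermentation.

    Defaults mirror the emulated design: 50 genera over 6 timepoints
    (days 0–10, every 2 days) x 3 replicate mashes, 5 producer genera
    driving 5 of 10 HAs, 10% multiplicative noise and a dominant genus
    holding at least half of the community.
    """

    n_taxa: int = 50
    n_timepoints: int = 6
    n_replicates: int = 3
    n_producers: int = 5
    n_has: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.1
    dominant_taxon_fraction: float = 0.5
    detection_limit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ConfigurationError("need at least 2 taxa")
        if self.n_producers > self.n_taxa - 1:
            raise ConfigurationError(
                "n_producers must leave room for the dominant taxon "
                f"(got {self.n_producers} producers among {self.n_taxa} taxa)"
            )
        if self.n_timepoints < 2:
            raise ConfigurationError("need at least 2 timepoints")
        if self.n_replicates < 1 or self.n_has < 1:
            raise ConfigurationError("n_replicates and n_has must be >= 1")
        if not 0 <= self.dominant_taxon_fraction < 1:
            raise ConfigurationError("dominant_taxon_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.detection_limit < 0:
            raise ConfigurationError("detection_limit must be >= 0")

    @property
    def days(self) -> list[int]:
        return [2 * t for t in range(self.n_timepoints)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"D{d}R{r}" for d in self.days
                for r in range(1, self.n_replicates + 1)]


@dataclass
class GroundTruth:
    """What was planted: producers, their effect slopes, stable HAs."""

    producer_ids: list[str]
    effect_matrix: pd.DataFrame  # producers x HAs, µg/L per unit rel. abundance
    dominant_taxon: str
    planted_stable_has: set[str] = field(default_factory=set)

    @property
    def driven_has(self) -> set[str]:
        nonzero = (self.effect_matrix != 0).any(axis=0)
        return set(self.effect_matrix.columns[nonzero])


def _producer_template(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """A smooth per-taxon trajectory: logistic rise or Gaussian bump."""
    if rng.random() < 0.5:
        mid = rng.uniform(0.3, 0.7)
        shape = 1.0 / (1.0 + np.exp(-8.0 * (t - mid)))
    else:
        mid = rng.uniform(0.2, 0.8)
        shape = np.exp(-((t - mid) ** 2) / (2 * 0.15**2))
    template = 0.1 + 0.9 * shape  # keep trajectories strictly positive
    # unit mean, so a producer's baseline is its mean abundance and the
    # planted producers land in the top abundance stratum by construction
    return template / template.mean()


def generate_community(config: SimConfig) -> tuple[AbundanceTable, GroundTruth]:
    """Generate the taxa x samples relative-abundance table and its truth.

    Column sums are exactly 1; the dominant taxon's mean relative
    abundance is at least ``dominant_taxon_fraction`` (the generator
    targets a slightly higher share so the floor survives noise).
    """
    rng = np.random.default_rng(config.seed)
    T, R = config.n_timepoints, config.n_replicates
    taxa = [f"taxon_{i:03d}" for i in range(config.n_taxa)]
    dominant = taxa[0]
    producer_idx = 1 + rng.choice(config.n_taxa - 1, size=config.n_producers,
                                  replace=False)
    producer_idx = np.sort(producer_idx)
    producers = [taxa[i] for i in producer_idx]

    t = np.linspace(0.0, 1.0, T)
    means = np.zeros((config.n_taxa, T))
    for i in range(1, config.n_taxa):
        if i in producer_idx:
            base = np.exp(rng.uniform(np.log(0.02), np.log(0.05)))
            means[i] = base * _producer_template(rng, t)
        else:
            base = np.exp(rng.uniform(np.log(1e-4), np.log(1e-2)))
            means[i] = base * np.exp(rng.normal(0.0, 0.5, size=T))

    # dominant taxon: jittered odds around a target slightly above the floor,
    # so its mean share stays >= dominant_taxon_fraction under noise
    f = config.dominant_taxon_fraction
    f_eff = f + 0.15 * (1.0 - f)
    odds = f_eff / (1.0 - f_eff) * np.exp(rng.normal(0.0, 0.2, size=T))
    rest = means[1:].sum(axis=0)
    means[0] = odds * rest

    noise = np.exp(rng.normal(0.0, config.noise_sd,
                              size=(config.n_taxa, T, R)))
    values = means[:, :, None] * noise
    flat = values.reshape(config.n_taxa, T * R)
    flat = flat / flat.sum(axis=0, keepdims=True)
    data = pd.DataFrame(flat, index=taxa, columns=config.sample_ids)

    effect = pd.DataFrame(
        0.0, index=producers, columns=[f"ha_{j:02d}" for j in range(config.n_has)]
    )
    for j, producer in enumerate(producers):
        effect.iloc[j, j % config.n_has] = config.effect_size * CONC_SCALE
    truth = GroundTruth(producer_ids=producers, effect_matrix=effect,
                        dominant_taxon=dominant)
    return AbundanceTable(data=data), truth


def generate_ha(abundance: AbundanceTable, truth: GroundTruth,
                config: SimConfig) -> HATable:
    """Generate the HA concentration table driven by the planted producers.

    Driven HAs are Σ_producers (effect x producer relative abundance) x
    exp(noise); undriven HAs are pure log-normal noise around a small
    baseline.  Cells below ``detection_limit`` are masked ND.  Updates
    ``truth.planted_stable_has`` with the HAs detected in at least 5
    timepoints of the summarized table.
    """
    missing = [p for p in truth.producer_ids if p not in abundance.data.index]
    if missing:
        raise AlignmentError(f"producers absent from abundance table: {missing}")
    samples = abundance.samples
    if len(samples) != config.n_timepoints * config.n_replicates:
        raise AlignmentError(
            "abundance table sample count does not match the SimConfig design"
        )
    # independent noise stream, decoupled from the community draw
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ha_names = list(truth.effect_matrix.columns)
    prod = abundance.data.loc[truth.producer_ids].to_numpy(dtype=float)
    signal = truth.effect_matrix.to_numpy(dtype=float).T @ prod  # HAs x samples

    values = np.empty_like(signal)
    driven = (truth.effect_matrix != 0).any(axis=0).to_numpy()
    noise = np.exp(rng.normal(0.0, config.noise_sd, size=signal.shape))
    baselines = BACKGROUND_HA_SCALE * np.exp(
        rng.uniform(np.log(0.25), np.log(2.5), size=len(ha_names))
    )
    for h in range(len(ha_names)):
        if driven[h]:
            values[h] = signal[h] * noise[h]
        else:
            values[h] = baselines[h] * noise[h]

    replicate_values = pd.DataFrame(values, index=ha_names, columns=samples)
    replicate_nd = replicate_values < config.detection_limit
    table = HATable(
        mean=replicate_values.mask(replicate_nd),
        nd_mask=replicate_nd.copy(),
        replicate_values=replicate_values,
        replicate_nd=replicate_nd,
    )
    summary = summarize_replicates(table)
    detected = (~summary.nd_mask).sum(axis=1)
    truth.planted_stable_has = set(detected.index[detected >= 5])
    return table


def generate_peak_table(ha: HATable, quant: QuantConfig) -> PeakTable:
    """Invert the internal-standard relation to synthesize peak areas.

    Uses a fixed internal-standard area, so that quantification recovers
    the input concentrations exactly (C = d * A_c / A_is * C_is inverted
    as A_c = C * A_is / (d * C_is)).
    """
    values = ha.replicate_values if ha.replicate_values is not None else ha.mean
    if (values.to_numpy(dtype=float) < 0).any():
        raise ConfigurationError("concentrations must be non-negative")
    records = []
    for compound in values.index:
        for sample in values.columns:
            c = float(values.loc[compound, sample])
            a_c = c * IS_AREA / (quant.dilution_factor * quant.c_is)
            records.append({"compound": compound, "sample_id": sample,
                            "area": a_c, "is_area": IS_AREA})
    return PeakTable(records=pd.DataFrame(records))
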