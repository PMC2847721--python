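"""Seeded generators of Cq experiments with known ground truth.

The simulator encodes the error structure RT-qPCR assumes: biology and
sample loading act multiplicatively on template quantity (modelled as
Gaussian noise on the log2 quantity scale), while technical replicate error
is additive on the cycle scale.  For sample s and gene g,

    expression_{s,g} = 2 ** (mu_g + bio_noise_{s,g} + dysregulation_g)
    quantity_{s,g}   = expression_{s,g} * loading_s
    Cq_{s,g,rep}     = baseline - log(quantity) / log(factor) + tech_noise

Candidate reference genes differ only in their biological noise sd, which
defines a known stability ordering for testing stability analysis.  The
expressed-Alu-repeat (EAR) signal is not one transcript: it is emitted as
the sum of many independent Alu-bearing transcript quantities, each with
its own biological noise, so its pooled log2 variance shrinks roughly as
1/n_components — the quantitative form of the argument that dysregulation
of individual genes cannot move the aggregate Alu signal.

Everything is a pure function of (config, seed): the same inputs always
reproduce the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .qpcr_data import CqTable, MeltCurve, ReplicateDesign

EAR_GENE_ID = "EAR"


@dataclass(frozen=True)
class GeneSpec:
    """True behaviour of one simulated gene."""

    gene_id: str
    true_log2_expression: float = 8.0
    biological_sd_log2: float = 0.0
    dysregulated: bool = False
    effect_log2: float = 0.0

    def __post_init__(self) -> None:
        if self.biological_sd_log2 < 0:
            raise ValidationError(f"{self.gene_id}: biological sd must be >= 0")


def default_blood_panel() -> list[GeneSpec]:
    """Six candidate references in three stability classes plus one target.

    The three low-noise genes play the stable trio; the three noisier ones
    the unstable tail of a typical blood panel.  BDNF stands in for a
    biologically variable (but not dysregulated) target transcript.
    """
    return [
        GeneSpec("GNB2L1", 8.0, 0.05),
        GeneSpec("HPRT1", 7.0, 0.05),
        GeneSpec("YWHAZ", 7.5, 0.05),
        GeneSpec("B2M", 10.0, 0.3),
        GeneSpec("GAPDH", 9.0, 0.4),
        GeneSpec("ACTB", 10.5, 0.5),
        GeneSpec("BDNF", 4.0, 0.5),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated Cq experiment.

    Defaults model a small human cohort profiled in the standard
    2 RT x 3 PCR design: ten subjects, per-sample loading sd of 0.5 log2
    units (about 1.4-fold cDNA input spread), technical Cq noise of 0.1
    cycles per well, and an EAR signal pooled over 500 Alu-bearing
    transcripts whose individual biological sds match a mid-range gene.
    """

    n_samples: int = 10
    genes: tuple[GeneSpec, ...] = field(
        default_factory=lambda: tuple(default_blood_panel()))
    loading_sd_log2: float = 0.5
    technical_sd_cq: float = 0.1
    rt_replicates: int = 2
    pcr_replicates: int = 3
    ear_components: int = 500
    ear_component_mean_log2: float = 3.0
    ear_component_spread_log2: float = 1.0
    ear_component_sd_log2: float = 0.3
    amplification_factor: float = 2.0
    baseline_cq: float = 34.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.rt_replicates < 1 or self.pcr_replicates < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.ear_components < 1:
            raise ValidationError("ear_components must be >= 1")
        for sd in (self.loading_sd_log2, self.technical_sd_cq,
                   self.ear_component_sd_log2):
            if sd < 0:
                raise ValidationError("noise sds must be >= 0")
        if self.amplification_factor <= 1:
            raise ValidationError("amplification factor must exceed 1")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene ids in config")
        if EAR_GENE_ID in ids:
            raise ValidationError(f"{EAR_GENE_ID} is generated by pooling; "
                                  "do not list it as a gene")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated experiment.

    ``expression`` holds biological quantities with loading excluded;
    multiply by ``loading`` (linear per-sample factors) to get the template
    quantity a well actually saw.
    """

    loading: pd.Series                 # per-sample linear loading factor
    expression: pd.DataFrame           # samples x genes (incl. EAR), loading-free
    stability_order: list[str]         # gene ids sorted by biological sd
    config: SimulationConfig
    seed: int


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:02d}" for i in range(1, n + 1)]


def simulate_experiment(config: SimulationConfig,
                        seed: Optional[int] = None) -> tuple[CqTable, SimulationTruth]:
    """Generate a full Cq plate plus its ground truth.

    The EAR row of the output is the Cq of the *summed* quantity of
    ``config.ear_components`` independent transcripts; every other gene is a
    single transcript with its configured mean and biological sd.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    samples = _sample_ids(config.n_samples)
    n = config.n_samples

    loading = 2.0 ** rng.normal(0.0, config.loading_sd_log2, size=n)
    loading_s = pd.Series(loading, index=samples, name="loading")

    expr = {}
    for g in config.genes:
        eps = rng.normal(0.0, g.biological_sd_log2, size=n) if g.biological_sd_log2 else np.zeros(n)
        shift = g.effect_log2 if g.dysregulated else 0.0
        expr[g.gene_id] = 2.0 ** (g.true_log2_expression + eps + shift)

    # EAR: pooled quantity over many Alu-bearing transcripts.  Component
    # baseline abundances are drawn once (they are properties of the
    # transcriptome), per-sample noise independently per component.
    comp_base = rng.normal(config.ear_component_mean_log2,
                           config.ear_component_spread_log2,
                           size=config.ear_components)
    comp_noise = rng.normal(0.0, config.ear_component_sd_log2,
                            size=(n, config.ear_components))
    expr[EAR_GENE_ID] = (2.0 ** (comp_base[None, :] + comp_noise)).sum(axis=1)

    expression = pd.DataFrame(expr, index=samples)

    ln_factor = np.log(config.amplification_factor)
    rows = []
    for gene_id in expression.columns:
        quantity = expression[gene_id].to_numpy() * loading
        true_cq = config.baseline_cq - np.log(quantity) / ln_factor
        for si, sample in enumerate(samples):
            for rt in range(1, config.rt_replicates + 1):
                for pcr in range(1, config.pcr_replicates + 1):
                    noise = rng.normal(0.0, config.technical_sd_cq) \
                        if config.technical_sd_cq else 0.0
                    rows.append({"sample": sample, "gene": gene_id,
                                 "rt_rep": rt, "pcr_rep": pcr,
                                 "cq": true_cq[si] + noise})
    table = CqTable(pd.DataFrame(rows),
                    ReplicateDesign(config.rt_replicates, config.pcr_replicates))

    order = [g.gene_id for g in
             sorted(config.genes, key=lambda g: (g.biological_sd_log2, g.gene_id))]
    truth = SimulationTruth(loading=loading_s, expression=expression,
                            stability_order=order, config=config, seed=seed)
    return table, truth


def simulate_dilution_series(true_slope: float, intercept: float,
                             amounts: Sequence[float], noise_sd: float,
                             seed: int, replicates: int = 1
                             ) -> list[tuple[float, float]]:
    """Dilution-series points: Cq = intercept + slope*log10(amount) + noise."""
    amounts = np.asarray(amounts, dtype=float)
    if np.any(amounts <= 0):
        raise ValidationError("dilution amounts must be positive")
    if noise_sd < 0:
        raise ValidationError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for amount in amounts:
        for _ in range(replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
            points.append((float(amount),
                           float(intercept + true_slope * np.log10(amount) + noise)))
    return points


@dataclass(frozen=True)
class MeltComponent:
    """One melting product: centre temperature, transition width, weight."""

    tm_c: float
    width_c: float = 0.5
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError("melt component weight must be positive")
        if self.width_c <= 0:
            raise ValidationError("melt component width must be positive")


def simulate_melt(components: Sequence[MeltComponent],
                  grid: Optional[np.ndarray] = None,
                  noise_sd: float = 0.0,
                  seed: int = 0,
                  well_id: str = "W1", sample_id: str = "S01",
                  gene_id: str = EAR_GENE_ID) -> MeltCurve:
    """Fluorescence trace: sum of sigmoidal melt transitions plus noise.

    Each component contributes weight / (1 + exp((T - Tm)/width)); its
    -dF/dT peaks exactly at Tm with height weight/(4*width).  The default
    grid is 55-94 degC at 0.5 degC, the usual post-amplification ramp.
    """
    comps = [c if isinstance(c, MeltComponent) else MeltComponent(*c)
             for c in components]
    if not comps:
        raise ValidationError("need >= 1 melt component")
    if grid is None:
        grid = np.arange(55.0, 94.0 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    f = np.zeros_like(grid)
    for c in comps:
        f += c.weight / (1.0 + np.exp((grid - c.tm_c) / c.width_c))
    if noise_sd:
        f = f + rng.normal(0.0, noise_sd, size=grid.size)
    return MeltCurve(well_id=well_id, sample_id=sample_id, gene_id=gene_id,
                     temperatures=grid, fluorescence=f)
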