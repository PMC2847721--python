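"""End-to-end workflow: ingest/simulate -> calibrate -> quantify ->
stability -> normalize -> melt QC -> stats, with a provenance manifest.

Every stage communicates through written artifacts only, so any stage can
be re-run from the previous stage's files, and a rerun with the same
inputs, configuration and seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .calibration import StandardCurve, fit_standard_curve
from .errors import EarnormError, ValidationError
from .genorm import (DEFAULT_M_THRESHOLD, normalization_factor,
                     stepwise_ranking)
from .melt_qc import (DEFAULT_PROMINENCE_FRACTION, DEFAULT_TOLERANCE_C,
                      curve_peaks, replicate_concordance)
from .normalization import compare_strategies, normalize
from .qpcr_data import ReplicateDesign, read_cq_table, read_melt_curves, \
    write_cq_table, write_melt_curves
from .quantification import quantities_wide, quantity_table
from .synthetic import EAR_GENE_ID, SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Union[str, Path]
    cq_path: Optional[Union[str, Path]] = None     # None -> simulate
    melt_path: Optional[Union[str, Path]] = None
    dilution_path: Optional[Union[str, Path]] = None  # columns amount,cq
    calibrated_gene: str = EAR_GENE_ID             # gene the curve applies to
    target: str = "BDNF"
    strategy: str = "ear"                          # ear | single | nf
    reference_genes: tuple[str, ...] = ()
    candidate_genes: tuple[str, ...] = ()          # genorm panel; () = all but target/EAR
    m_threshold: float = DEFAULT_M_THRESHOLD
    melt_tolerance_c: float = DEFAULT_TOLERANCE_C
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
    rt_replicates: int = 2
    pcr_replicates: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.strategy not in {"ear", "single", "nf"}:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        for name, value in (("m_threshold", self.m_threshold),
                            ("melt_tolerance_c", self.melt_tolerance_c),
                            ("prominence_fraction", self.prominence_fraction)):
            if value <= 0:
                raise ValidationError(f"{name} must be positive")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps({k: str(v) for k, v in asdict(config).items()},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the staged workflow; returns the manifest dictionary.

    Stage outputs land in ``config.out_dir``: cq.csv (when simulated),
    curve.json (when a dilution series is given), quantities.csv,
    stability.json, normalized.csv, meltqc.json and manifest.json.
    Any stage failure aborts with the stage name in the error message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "earnorm_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except EarnormError as exc:
                raise EarnormError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = result
            return result
        return wrap

    design = ReplicateDesign(config.rt_replicates, config.pcr_replicates)

    @stage("ingest")
    def _ingest():
        if config.cq_path is not None:
            table = read_cq_table(config.cq_path, design)
            return {"source": str(config.cq_path), "rows": len(table)}
        sim_cfg = SimulationConfig(rt_replicates=config.rt_replicates,
                                   pcr_replicates=config.pcr_replicates,
                                   seed=config.seed)
        table, _truth = simulate_experiment(sim_cfg)
        write_cq_table(table, out / "cq.csv")
        return {"source": "simulated", "rows": len(table),
                "written": str(out / "cq.csv")}

    cq_source = config.cq_path if config.cq_path is not None else out / "cq.csv"
    table = read_cq_table(cq_source, design)

    factors = {}

    @stage("calibrate")
    def _calibrate():
        if config.dilution_path is None:
            return {"skipped": True, "default_factor": 2.0}
        frame = pd.read_csv(config.dilution_path)
        curve = fit_standard_curve(
            list(zip(frame["amount"], frame["cq"])))
        curve.to_json(out / "curve.json")
        factors[config.calibrated_gene] = curve
        return {"slope": curve.slope,
                "efficiency_percent": curve.efficiency_percent,
                "r_squared": curve.r_squared,
                "applies_to": config.calibrated_gene,
                "written": str(out / "curve.json")}

    @stage("quantify")
    def _quantify():
        quantities = quantity_table(table, factors)
        quantities.to_csv(out / "quantities.csv", index=False)
        return {"pairs": len(quantities), "written": str(out / "quantities.csv")}

    wide = quantities_wide(pd.read_csv(out / "quantities.csv"))

    @stage("stability")
    def _stability():
        panel = list(config.candidate_genes) or [
            g for g in wide.columns if g not in (config.target, EAR_GENE_ID)]
        report = stepwise_ranking(wide, panel, threshold=config.m_threshold)
        report.to_json(out / "stability.json")
        manifest["warnings"].extend(report.warnings)
        return {"ranking": report.ranking,
                "selected_references": report.selected_references,
                "written": str(out / "stability.json")}

    stability = manifest["stages"]["stability"]

    @stage("normalize")
    def _normalize():
        refs = list(config.reference_genes)
        if config.strategy == "nf" and not refs:
            refs = stability["selected_references"]
        if config.strategy == "nf":
            unstable = [g for g in refs
                        if g not in stability["selected_references"]]
            for g in unstable:
                manifest["warnings"].append(
                    f"reference gene {g} did not pass the stability "
                    f"threshold (M < {config.m_threshold})")
        result = normalize(wide, config.target, config.strategy,
                           reference_genes=refs, ear_gene=EAR_GENE_ID)
        result.to_frame().to_csv(out / "normalized.csv", index=False)
        return {"strategy": config.strategy,
                "references": list(result.reference_detail),
                "n_samples": len(result.values),
                "median": float(result.values.median()),
                "written": str(out / "normalized.csv")}

    @stage("melt_qc")
    def _melt_qc():
        if config.melt_path is None:
            return {"skipped": True}
        curves = read_melt_curves(config.melt_path)
        peaks = [curve_peaks(c, config.prominence_fraction) for c in curves]
        by_sample: dict[str, list] = {}
        for c, p in zip(curves, peaks):
            by_sample.setdefault(c.sample_id, []).append(p)
        verdicts = {
            s: asdict(replicate_concordance(ps, config.melt_tolerance_c))
            for s, ps in sorted(by_sample.items())}
        payload = {"per_sample": verdicts,
                   "peaks": {p.well_id: list(p.peak_temperatures) for p in peaks}}
        (out / "meltqc.json").write_text(json.dumps(payload, indent=2) + "\n")
        n_fail = sum(v["status"] == "fail" for v in verdicts.values())
        return {"samples": len(verdicts), "failed": n_fail,
                "written": str(out / "meltqc.json")}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
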