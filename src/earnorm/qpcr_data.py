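"""Domain types and I/O for Cq plate tables, melt curves, primers and sequences.

The quantification cycle (Cq) is the PCR cycle at which a well's fluorescence
crosses the detection threshold; lower Cq means more starting template.  A
plate table records one Cq per (sample, gene, RT replicate, PCR replicate),
where RT replicates are independent reverse-transcription reactions and PCR
replicates are repeated amplifications of the same cDNA.  The standard design
here is 2 RT x 3 PCR, i.e. six independent measurements per sample and gene.

File formats are deliberately plain: Cq tables and melt traces are UTF-8 CSV
with dot decimal separators, sequences are FASTA, and primer panels are a
small YAML list.  Vendor-proprietary thermocycler exports are out of scope;
CSV is the ingestion boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted in primers and template sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

CQ_COLUMNS = ["sample", "gene", "rt_rep", "pcr_rep", "cq"]
MELT_COLUMNS = ["well", "sample", "gene", "temperature_c", "fluorescence"]


@dataclass(frozen=True)
class ReplicateDesign:
    """Expected replicate structure of a plate: RT reactions x PCR repeats."""

    rt_replicates: int = 2
    pcr_replicates: int = 3

    def __post_init__(self) -> None:
        if self.rt_replicates < 1 or self.pcr_replicates < 1:
            raise ValidationError("replicate design counts must be >= 1")

    @property
    def n_measurements(self) -> int:
        return self.rt_replicates * self.pcr_replicates


@dataclass(frozen=True)
class CqMeasurement:
    """One well: a Cq value (or missing) for a sample/gene/replicate key."""

    sample_id: str
    gene_id: str
    rt_replicate: int
    pcr_replicate: int
    cq: Optional[float]

    def __post_init__(self) -> None:
        if self.rt_replicate < 1 or self.pcr_replicate < 1:
            raise ValidationError("replicate indices are 1-based, got "
                                  f"({self.rt_replicate}, {self.pcr_replicate})")
        if self.cq is not None and not np.isnan(self.cq):
            if not 0.0 < self.cq < 60.0:
                raise ValidationError(
                    f"cq {self.cq} outside (0, 60) for "
                    f"({self.sample_id}, {self.gene_id})")


class CqTable:
    """Validated collection of Cq measurements plus the replicate design.

    Internally a pandas DataFrame with columns sample, gene, rt_rep,
    pcr_rep, cq (float64; NaN encodes a missing Cq, never a sentinel).
    Sample and gene identifiers are case-sensitive throughout: B2M and
    b2m are different genes.
    """

    def __init__(self, data: pd.DataFrame, design: ReplicateDesign = ReplicateDesign()):
        missing = [c for c in CQ_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"Cq table missing columns: {missing}")
        frame = data.loc[:, CQ_COLUMNS].copy()
        frame["sample"] = frame["sample"].astype(str)
        frame["gene"] = frame["gene"].astype(str)
        frame["rt_rep"] = frame["rt_rep"].astype(int)
        frame["pcr_rep"] = frame["pcr_rep"].astype(int)
        frame["cq"] = pd.to_numeric(frame["cq"], errors="raise").astype(float)

        if (frame["rt_rep"] < 1).any() or (frame["pcr_rep"] < 1).any():
            raise ValidationError("replicate indices must be >= 1 (1-based)")
        bad = frame["cq"].notna() & ~frame["cq"].between(0, 60, inclusive="neither")
        if bad.any():
            row = frame.loc[bad].iloc[0]
            raise ValidationError(
                f"cq {row['cq']} outside (0, 60) for ({row['sample']}, {row['gene']})")
        dup = frame.duplicated(subset=["sample", "gene", "rt_rep", "pcr_rep"])
        if dup.any():
            key = frame.loc[dup, ["sample", "gene", "rt_rep", "pcr_rep"]].iloc[0]
            raise ValidationError(
                "duplicate measurement key "
                f"({key['sample']}, {key['gene']}, rt={key['rt_rep']}, pcr={key['pcr_rep']})")

        self.data = frame.reset_index(drop=True)
        self.design = design

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def measurements(self) -> list[CqMeasurement]:
        return [
            CqMeasurement(r.sample, r.gene, int(r.rt_rep), int(r.pcr_rep),
                          None if pd.isna(r.cq) else float(r.cq))
            for r in self.data.itertuples(index=False)
        ]

    @classmethod
    def from_measurements(cls, measurements: Iterable[CqMeasurement],
                          design: ReplicateDesign = ReplicateDesign()) -> "CqTable":
        rows = [
            {"sample": m.sample_id, "gene": m.gene_id, "rt_rep": m.rt_replicate,
             "pcr_rep": m.pcr_replicate,
             "cq": np.nan if m.cq is None else float(m.cq)}
            for m in measurements
        ]
        frame = pd.DataFrame(rows, columns=CQ_COLUMNS)
        return cls(frame, design)


@dataclass(frozen=True)
class PrimerPair:
    """A named forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str
    expected_product_bp: Optional[int] = None

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            seq_u = seq.upper().replace("U", "T")
            if len(seq_u) < 10:
                raise ValidationError(
                    f"{self.name}: {label} primer shorter than 10 nt")
            bad = set(seq_u) - IUPAC_DNA
            if bad:
                raise ValidationError(
                    f"{self.name}: {label} primer has non-IUPAC characters {sorted(bad)}")
            object.__setattr__(self, label, seq_u)
        if self.expected_product_bp is not None and self.expected_product_bp < 1:
            raise ValidationError(f"{self.name}: expected_product_bp must be positive")


@dataclass
class MeltCurve:
    """Post-amplification dissociation trace: fluorescence vs temperature.

    Temperatures must be strictly increasing, on a grid inside [50, 100] degC
    (instruments typically ramp 55-94 degC), with at least two points.
    """

    well_id: str
    sample_id: str
    gene_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValidationError(f"well {self.well_id}: series length mismatch")
        if self.temperatures.size < 2:
            raise ValidationError(
                f"well {self.well_id}: needs >= 2 temperature points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError(
                f"well {self.well_id}: temperatures not strictly increasing")
        if self.temperatures[0] < 50.0 or self.temperatures[-1] > 100.0:
            raise ValidationError(
                f"well {self.well_id}: temperature grid outside [50, 100] degC")

    def __len__(self) -> int:
        return int(self.temperatures.size)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cq_table(path: Union[str, Path],
                  design: ReplicateDesign = ReplicateDesign()) -> CqTable:
    """Read a Cq plate CSV (columns sample,gene,rt_rep,pcr_rep,cq).

    An empty cq field is preserved as missing (NaN); no row is ever silently
    dropped — the parsed row count always equals the file's data-row count.
    """
    try:
        frame = pd.read_csv(path, dtype={"sample": str, "gene": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse Cq CSV {path}: {exc}") from exc
    missing = [c for c in CQ_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: malformed header, missing columns {missing}")
    table = CqTable(frame, design)
    logger.info("read %d Cq rows from %s (%d samples, %d genes)",
                len(table), path, len(table.samples), len(table.genes))
    return table


def write_cq_table(table: CqTable, path: Union[str, Path]) -> None:
    """Write a Cq table back to CSV; missing Cq becomes an empty field."""
    table.data.to_csv(path, index=False, na_rep="")
    logger.info("wrote %d Cq rows to %s", len(table), path)


def read_melt_curves(path: Union[str, Path]) -> list[MeltCurve]:
    """Read long-format melt CSV, one curve per well, temperature-sorted."""
    try:
        frame = pd.read_csv(path, dtype={"well": str, "sample": str, "gene": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse melt CSV {path}: {exc}") from exc
    missing = [c for c in MELT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: malformed header, missing columns {missing}")

    curves: list[MeltCurve] = []
    for well, grp in frame.groupby("well", sort=True):
        grp = grp.sort_values("temperature_c")
        temps = grp["temperature_c"].to_numpy(dtype=float)
        if np.any(np.diff(temps) <= 0):
            raise ValidationError(f"well {well}: duplicate temperature in trace")
        sample_ids = grp["sample"].unique()
        gene_ids = grp["gene"].unique()
        if len(sample_ids) != 1 or len(gene_ids) != 1:
            raise ValidationError(f"well {well}: inconsistent sample/gene labels")
        curves.append(MeltCurve(
            well_id=str(well), sample_id=str(sample_ids[0]), gene_id=str(gene_ids[0]),
            temperatures=temps,
            fluorescence=grp["fluorescence"].to_numpy(dtype=float)))
    logger.info("read %d melt curves from %s", len(curves), path)
    return curves


def write_melt_curves(curves: Sequence[MeltCurve], path: Union[str, Path]) -> None:
    rows = []
    for c in curves:
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append({"well": c.well_id, "sample": c.sample_id, "gene": c.gene_id,
                         "temperature_c": t, "fluorescence": f})
    pd.DataFrame(rows, columns=MELT_COLUMNS).to_csv(path, index=False)


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence); uppercase, RNA U mapped to T."""
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValidationError(f"FASTA record {rec.id!r} is empty")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"FASTA record {rec.id!r} has non-IUPAC characters {sorted(bad)}")
        records.append((rec.id, seq))
    logger.info("read %d FASTA records from %s", len(records), path)
    return records


def read_primer_config(path: Union[str, Path]) -> list[PrimerPair]:
    """Read a primer panel from YAML: a list of name/forward/reverse entries.

    Each entry may carry expected_product_bp for in-silico validation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise FormatError(f"{path}: primer config must be a YAML list of pairs")
    pairs = []
    for entry in raw:
        try:
            pairs.append(PrimerPair(
                name=str(entry["name"]),
                forward=str(entry["forward"]),
                reverse=str(entry["reverse"]),
                expected_product_bp=(int(entry["expected_product_bp"])
                                     if entry.get("expected_product_bp") is not None
                                     else None)))
        except KeyError as exc:
            raise FormatError(f"{path}: primer entry missing field {exc}") from exc
    return pairs
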