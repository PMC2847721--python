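"""Normalization of target quantities to a reference signal.

Three strategies produce the dimensionless per-sample expression values
used for between-sample comparison:

* ``single`` — divide by one reference gene's relative quantity (the
  classical, and error-prone, housekeeping-gene normalization);
* ``nf`` — divide by the GeNorm normalization factor, the geometric mean of
  several validated stable references;
* ``ear`` — divide by the pooled expressed-Alu-repeat (EAR) quantity, a
  single universal reference whose stability comes from averaging over
  thousands of Alu-bearing transcripts rather than from gene selection.

Computationally ``ear`` is single-gene normalization with the EAR assay as
the reference; the distinction is scientific (what the signal measures),
so the strategy and reference genes are recorded with every output value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .stats import TestResult, pearson_r

logger = logging.getLogger(__name__)


@dataclass
class NormalizedExpressionTable:
    """Per-sample normalized values of one target plus full provenance."""

    target: str
    values: pd.Series                 # index: sample ids; values > 0
    strategy: str                     # "single" | "nf" | "ear"
    reference_detail: tuple[str, ...]  # the reference gene(s) used

    def __post_init__(self) -> None:
        if self.strategy not in {"single", "nf", "ear"}:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if (self.values <= 0).any():
            raise ValidationError("normalized values must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.values.index,
            "target": self.target,
            "normalized_value": self.values.to_numpy(),
            "strategy": self.strategy,
            "references": ",".join(self.reference_detail),
        })


def _align(q_target: pd.Series, q_reference: pd.Series) -> tuple[pd.Series, pd.Series]:
    shared = q_target.index.intersection(q_reference.index)
    dropped = q_target.index.difference(shared)
    for s in dropped:
        logger.warning("sample %s lacks a reference value; omitted", s)
    if len(shared) == 0:
        raise InsufficientDataError("no shared samples between target and reference")
    return q_target.loc[shared], q_reference.loc[shared]


def normalize_to_single(q_target: pd.Series, q_reference: pd.Series) -> pd.Series:
    """value_s = Q_target,s / Q_ref,s; samples without a reference are omitted."""
    t, r = _align(pd.Series(q_target, dtype=float), pd.Series(q_reference, dtype=float))
    if (r <= 0).any():
        raise ValidationError("reference quantities must be positive")
    return t / r


def normalize_to_nf(q_target: pd.Series, nf: pd.Series) -> pd.Series:
    """value_s = Q_target,s / NF_s (NF: geometric mean of the references)."""
    return normalize_to_single(q_target, nf)


def normalize(quantities: pd.DataFrame, target: str, strategy: str,
              reference_genes: Sequence[str] = (),
              ear_gene: str = "EAR",
              rescale_to_median: bool = False) -> NormalizedExpressionTable:
    """Normalize one target column of a samples x genes quantity matrix.

    ``strategy`` is "single" (reference_genes = one gene), "nf"
    (reference_genes = the stable set; geometric mean) or "ear" (the
    ``ear_gene`` column is the reference).  ``rescale_to_median`` divides the
    result by its cohort median, a display convention that centres the
    distribution at 1 without changing any ratio between samples.
    """
    from .genorm import normalization_factor  # local import avoids a cycle

    if target not in quantities.columns:
        raise ValidationError(f"target {target!r} absent from quantities")
    q_target = quantities[target]
    if strategy == "single":
        if len(reference_genes) != 1:
            raise ValidationError("strategy 'single' needs exactly one reference gene")
        refs = tuple(reference_genes)
        values = normalize_to_single(q_target, quantities[refs[0]])
    elif strategy == "nf":
        refs = tuple(reference_genes)
        values = normalize_to_nf(q_target, normalization_factor(quantities, refs))
    elif strategy == "ear":
        if ear_gene not in quantities.columns:
            raise ValidationError(f"EAR column {ear_gene!r} absent from quantities")
        refs = (ear_gene,)
        values = normalize_to_single(q_target, quantities[ear_gene])
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")

    if rescale_to_median:
        values = values / values.median()
    return NormalizedExpressionTable(target=target, values=values,
                                     strategy=strategy, reference_detail=refs)


@dataclass
class StrategyComparison:
    """Agreement between two normalization strategies on shared samples."""

    pearson: TestResult
    median_a: float
    median_b: float
    ratio: pd.Series          # per-sample values_a / values_b
    paired: pd.DataFrame      # columns a, b for plotting
    n: int


def compare_strategies(values_a: pd.Series, values_b: pd.Series) -> StrategyComparison:
    """Compare two normalized series: Pearson r, medians, per-sample ratios."""
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise InsufficientDataError("strategy comparison needs >= 3 shared samples")
    a, b = a.loc[shared], b.loc[shared]
    return StrategyComparison(
        pearson=pearson_r(a.to_numpy(), b.to_numpy()),
        median_a=float(a.median()), median_b=float(b.median()),
        ratio=a / b,
        paired=pd.DataFrame({"a": a, "b": b}),
        n=int(len(shared)))
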