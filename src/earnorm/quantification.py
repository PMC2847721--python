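"""Replicate aggregation and efficiency-corrected relative quantification.

Technical replicates are averaged on the Cq (cycle) scale, where qPCR noise
is approximately additive, and the mean Cq is then transformed to a relative
quantity

    Q_s = factor ** (Cq_min - Cq_s)

where ``factor`` is the per-cycle amplification factor (2.0 for a perfectly
efficient assay, or the factor derived from a standard curve) and Cq_min is
the gene's minimum mean Cq across samples.  The sample with the most
template therefore gets Q = 1 and every other sample a value in (0, 1] —
the max-expression scaling used by GeNorm.  The absolute anchor cancels in
every downstream ratio, so this choice of scale is purely conventional.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .calibration import StandardCurve
from .errors import DomainError, InsufficientDataError
from .qpcr_data import CqTable

logger = logging.getLogger(__name__)

DEFAULT_AMPLIFICATION_FACTOR = 2.0


def aggregate_replicates(table: CqTable) -> pd.DataFrame:
    """Collapse technical replicates to per-(sample, gene) summary rows.

    Returns a DataFrame with columns sample, gene, mean_cq, cq_sd, n where
    mean and sd (n-1 denominator) cover the non-missing Cq values only.
    Pairs with zero non-missing measurements are unquantifiable: they are
    excluded from the output with a warning rather than propagated as NaN.
    """
    grouped = table.data.groupby(["sample", "gene"], sort=True)["cq"]
    out = grouped.agg(mean_cq="mean", cq_sd=lambda s: s.std(ddof=1),
                      n="count").reset_index()
    dropped = out[out["n"] == 0]
    for row in dropped.itertuples(index=False):
        logger.warning("(%s, %s): no non-missing Cq; pair excluded as "
                       "unquantifiable", row.sample, row.gene)
    out = out[out["n"] > 0].reset_index(drop=True)
    out["n"] = out["n"].astype(int)
    return out


def relative_quantity(mean_cq_by_sample: pd.Series,
                      amplification_factor: float = DEFAULT_AMPLIFICATION_FACTOR
                      ) -> pd.Series:
    """Transform one gene's per-sample mean Cq into relative quantities.

    Q_s = factor ** (cq_min - cq_s); the sample attaining the minimum mean
    Cq gets Q = 1.  Shifting every Cq by a constant leaves Q unchanged.
    """
    if amplification_factor <= 1:
        raise DomainError(
            f"amplification factor must exceed 1, got {amplification_factor}")
    cq = pd.Series(mean_cq_by_sample, dtype=float)
    if cq.empty:
        raise InsufficientDataError("need >= 1 sample to compute quantities")
    return amplification_factor ** (cq.min() - cq)


def quantity_table(table: CqTable,
                   factors: Optional[Mapping[str, Union[float, StandardCurve]]] = None,
                   default_factor: float = DEFAULT_AMPLIFICATION_FACTOR
                   ) -> pd.DataFrame:
    """Aggregate a plate and attach efficiency-corrected quantities.

    ``factors`` maps gene id to an amplification factor or a fitted
    StandardCurve; genes without an entry use ``default_factor`` (2.0, i.e.
    100% efficiency — the conventional assumption when only some assays have
    been calibrated).
    """
    agg = aggregate_replicates(table)
    factors = factors or {}
    q = np.empty(len(agg))
    for gene, idx in agg.groupby("gene").groups.items():
        f = factors.get(gene, default_factor)
        if isinstance(f, StandardCurve):
            f = f.amplification_factor
        q[np.asarray(idx)] = relative_quantity(
            agg.loc[idx].set_index("sample")["mean_cq"], float(f)).to_numpy()
    agg = agg.assign(q=q)
    return agg


def quantities_wide(quantities: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long quantity table to a samples x genes matrix of Q."""
    return quantities.pivot(index="sample", columns="gene", values="q")
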