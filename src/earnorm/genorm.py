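"""GeNorm reference-gene stability analysis.

For candidate reference genes j and k with per-sample relative quantities
Q_j and Q_k, the pairwise variation

    V_jk = sd over samples of log2(Q_j,s / Q_k,s)        (n-1 denominator)

is zero when the two genes are perfectly co-regulated (any proportional
pair) and grows with independent biological noise in either gene.  A gene's
stability measure is the average of its pairwise variations,

    M_j = mean over k != j of V_jk,

so lower M means more stable.  Stepwise exclusion repeatedly removes the
current highest-M gene and recomputes M, until two genes remain; at n = 2
the two survivors share a single V and cannot be mutually ranked.  Genes
with M >= 0.5 in the round where they were last evaluated are conventionally
considered unstable; a small set (three by default) of the most stable genes
passing that threshold forms the reference set, and the per-sample
normalization factor is the geometric mean of their quantities:

    NF_s = (prod over reference genes g of Q_g,s) ** (1/n_refs)

Sample loading differences multiply every gene's Q equally and cancel in
each Q_j/Q_k ratio, which is why V and M measure biological stability, not
pipetting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_M_THRESHOLD = 0.5
DEFAULT_N_REFERENCES = 3


def pairwise_variation(q_j: pd.Series, q_k: pd.Series) -> float:
    """V_jk: sd (n-1) of the per-sample log2 ratio of two genes' quantities."""
    q_j, q_k = pd.Series(q_j, dtype=float), pd.Series(q_k, dtype=float)
    if set(q_j.index) != set(q_k.index):
        raise ValidationError("pairwise variation requires identical sample sets")
    q_k = q_k.reindex(q_j.index)
    if len(q_j) < 2:
        raise InsufficientDataError("pairwise variation needs >= 2 samples")
    if (q_j <= 0).any() or (q_k <= 0).any():
        raise ValidationError("all quantities must be positive")
    ratios = np.log2(q_j.to_numpy() / q_k.to_numpy())
    return float(np.std(ratios, ddof=1))


def stability_m(quantities: pd.DataFrame,
                genes: Optional[Sequence[str]] = None) -> pd.Series:
    """Stability M per gene: mean pairwise variation against all other genes.

    ``quantities`` is a samples x genes matrix of positive relative
    quantities.  Needs >= 3 genes (with 2 genes the single shared V cannot
    rank them) and >= 2 samples.
    """
    genes = list(genes) if genes is not None else list(quantities.columns)
    if len(genes) < 3:
        raise InsufficientDataError(
            "stability M needs >= 3 genes; with 2 genes the ranking is "
            "unresolvable (single shared pairwise variation)")
    sub = quantities.loc[:, genes]
    if len(sub) < 2:
        raise InsufficientDataError("stability M needs >= 2 samples")
    if (sub <= 0).to_numpy().any() or sub.isna().to_numpy().any():
        raise ValidationError("all quantities must be positive and present")

    # sd of log2(Qj/Qk) for all pairs at once via the log-matrix covariance
    logq = np.log2(sub.to_numpy())
    cov = np.cov(logq, rowvar=False, ddof=1)          # genes x genes
    var = np.diag(cov)
    # Var(Lj - Lk) = Var(Lj) + Var(Lk) - 2 Cov(Lj, Lk)
    v_matrix = np.sqrt(np.maximum(var[:, None] + var[None, :] - 2 * cov, 0.0))
    m = (v_matrix.sum(axis=1)) / (len(genes) - 1)     # diagonal is zero
    return pd.Series(m, index=genes, name="M")


@dataclass
class StabilityRound:
    """M values for the genes remaining in one stepwise-exclusion round."""

    remaining_genes: list[str]
    m_by_gene: dict[str, float]
    excluded: Optional[str] = None     # gene removed at the end of this round


@dataclass
class GeneStabilityReport:
    """Full stepwise GeNorm analysis of a candidate reference panel."""

    genes: list[str]
    rounds: list[StabilityRound]
    exclusion_order: list[str]          # least stable exits first
    final_pair: tuple[str, str]         # rank-tied; lexicographic display order
    ranking: list[str]                  # most stable first (final pair leads)
    last_evaluated_m: dict[str, float]  # each gene's M in its last round
    selected_references: list[str]
    threshold: float
    n_select: int
    log_base: int = 2
    tie_notes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["final_pair"] = list(self.final_pair)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def stepwise_ranking(quantities: pd.DataFrame,
                     genes: Optional[Sequence[str]] = None,
                     threshold: float = DEFAULT_M_THRESHOLD,
                     n_select: int = DEFAULT_N_REFERENCES) -> GeneStabilityReport:
    """Rank genes by stepwise exclusion of the least stable gene.

    Each round computes M for the remaining genes and removes the argmax-M
    gene (ties broken by lexicographic gene id and recorded), until two
    genes remain.  The final two cannot be mutually ranked by M and are
    reported as rank-tied.  The reference set is the ``n_select`` most
    stable genes whose M in their last evaluated round is below
    ``threshold``; genes at or above it are dropped with a warning.
    """
    genes = list(genes) if genes is not None else list(quantities.columns)
    if len(genes) < 3:
        raise InsufficientDataError("stepwise ranking needs >= 3 genes")

    remaining = list(genes)
    rounds: list[StabilityRound] = []
    exclusion_order: list[str] = []
    last_evaluated: dict[str, float] = {}
    tie_notes: list[str] = []

    while len(remaining) > 2:
        m = stability_m(quantities, remaining)
        last_evaluated.update(m.to_dict())
        max_m = m.max()
        at_max = sorted(m.index[m == max_m])
        if len(at_max) > 1:
            tie_notes.append(
                f"argmax-M tie at M={max_m:.6g} among {at_max}; "
                f"excluded {at_max[0]} (lexicographic)")
        worst = at_max[0]
        rounds.append(StabilityRound(
            remaining_genes=list(remaining),
            m_by_gene={g: float(m[g]) for g in remaining},
            excluded=worst))
        exclusion_order.append(worst)
        remaining.remove(worst)

    final_pair = tuple(sorted(remaining))
    # the survivors' last-evaluated M comes from the last 3-gene round
    ranking = list(final_pair) + list(reversed(exclusion_order))

    selected: list[str] = []
    warnings: list[str] = []
    for gene in ranking[:n_select]:
        m_last = last_evaluated[gene]
        if m_last < threshold:
            selected.append(gene)
        else:
            warnings.append(
                f"{gene}: last-evaluated M={m_last:.3f} >= {threshold} — "
                "excluded from the reference set as unstable")
    for w in warnings:
        logger.warning("%s", w)

    return GeneStabilityReport(
        genes=list(genes), rounds=rounds, exclusion_order=exclusion_order,
        final_pair=final_pair, ranking=ranking,
        last_evaluated_m=last_evaluated, selected_references=selected,
        threshold=threshold, n_select=n_select,
        tie_notes=tie_notes, warnings=warnings)


def normalization_factor(quantities: pd.DataFrame,
                         reference_genes: Iterable[str]) -> pd.Series:
    """Per-sample NF: geometric mean of the reference genes' quantities.

    Three or more stable references are recommended; a smaller set is
    accepted (a single gene reduces NF to that gene's Q) with a warning
    below two genes, an empty set is an error.
    """
    refs = list(reference_genes)
    if not refs:
        raise ValidationError("reference gene set is empty")
    missing = [g for g in refs if g not in quantities.columns]
    if missing:
        raise ValidationError(f"reference genes absent from quantities: {missing}")
    if len(refs) < 2:
        logger.warning("normalization factor from a single reference gene "
                       "(%s); geometric-mean averaging is inactive", refs[0])
    sub = quantities.loc[:, refs]
    if (sub <= 0).to_numpy().any() or sub.isna().to_numpy().any():
        raise ValidationError("all reference quantities must be positive")
    nf = np.exp(np.log(sub.to_numpy()).mean(axis=1))
    return pd.Series(nf, index=quantities.index, name="NF")
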