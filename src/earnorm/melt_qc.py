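"""Melt-curve quality control: -dF/dT peaks and replicate concordance.

After amplification the instrument ramps temperature while recording SYBR
fluorescence; double-stranded product dissociates around its melting
temperature, producing a drop in fluorescence whose negative derivative
-dF/dT peaks at the product's Tm.  A clean single-product assay shows one
peak.  Pooled-repeat assays such as expressed-Alu-repeat (EAR)
amplification legitimately show several peaks — polymorphic repeat
subfamilies melt at different temperatures — so the QC rule is not "one
peak" but replicate concordance: technical replicates of the same sample
must share their melting-peak pattern, while different samples may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, ValidationError
from .qpcr_data import MeltCurve

DEFAULT_PROMINENCE_FRACTION = 0.2
DEFAULT_TOLERANCE_C = 0.5
#: default expected EAR product peak (degC), editable per assay
DEFAULT_EAR_PEAK_C = 88.69


@dataclass(frozen=True)
class DerivativeSeries:
    """-dF/dT evaluated on the interior points of a melt curve's grid."""

    well_id: str
    temperatures: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class MeltPeaks:
    """Called melting peaks for one well, sorted by temperature."""

    well_id: str
    peak_temperatures: tuple[float, ...]
    peak_heights: tuple[float, ...]

    @property
    def n_peaks(self) -> int:
        return len(self.peak_temperatures)


@dataclass
class ConcordanceReport:
    """Outcome of comparing melting-peak patterns across replicates."""

    status: str                    # "pass" | "fail" | "indeterminate"
    n_replicates: int
    tolerance_c: float
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def negative_derivative(curve: MeltCurve,
                        smooth_window: Optional[int] = None) -> DerivativeSeries:
    """Central-difference -dF/dT on the interior temperature points.

    ``smooth_window`` optionally applies a centred moving average (odd
    width) to the fluorescence before differencing; by default the raw
    trace is differenced, keeping the transform transparent.
    """
    if len(curve) < 3:
        raise InsufficientDataError(
            f"well {curve.well_id}: derivative needs >= 3 points")
    f = curve.fluorescence
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        f = np.convolve(np.pad(f, pad, mode="edge"), kernel, mode="valid")
    t = curve.temperatures
    deriv = -(f[2:] - f[:-2]) / (t[2:] - t[:-2])
    return DerivativeSeries(well_id=curve.well_id,
                            temperatures=t[1:-1], values=deriv)


def call_peaks(deriv: DerivativeSeries,
               min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
               ) -> MeltPeaks:
    """Local maxima of -dF/dT with prominence >= fraction of the global max.

    Prominence is measured relative to the well's own maximum so the call is
    invariant to uniform fluorescence scaling (plate-level gain differences).
    A flat or non-positive series yields zero peaks, which is legal.
    """
    values = deriv.values
    global_max = float(values.max(initial=0.0))
    if global_max <= 0:
        return MeltPeaks(well_id=deriv.well_id, peak_temperatures=(), peak_heights=())
    idx, _ = find_peaks(values, prominence=min_prominence_fraction * global_max)
    idx = idx[values[idx] > 0]
    return MeltPeaks(
        well_id=deriv.well_id,
        peak_temperatures=tuple(float(x) for x in deriv.temperatures[idx]),
        peak_heights=tuple(float(x) for x in values[idx]))


def curve_peaks(curve: MeltCurve,
                min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                smooth_window: Optional[int] = None) -> MeltPeaks:
    """Convenience: negative_derivative followed by call_peaks."""
    return call_peaks(negative_derivative(curve, smooth_window),
                      min_prominence_fraction)


def _matched_within(p: Sequence[float], q: Sequence[float], tol: float) -> bool:
    # equal counts assumed; peaks are temperature-sorted, so greedy nearest
    # pairing reduces to positional pairing
    return all(abs(a - b) <= tol for a, b in zip(sorted(p), sorted(q)))


def replicate_concordance(peaks_by_replicate: Sequence[MeltPeaks],
                          tolerance_c: float = DEFAULT_TOLERANCE_C
                          ) -> ConcordanceReport:
    """Check that replicates of one sample share their melting-peak pattern.

    Pass requires every replicate pair to have the same peak count and
    matched peaks within ``tolerance_c``.  A single replicate cannot be
    checked and yields status "indeterminate".  The check is symmetric in
    replicate order.
    """
    reps = list(peaks_by_replicate)
    if len(reps) < 2:
        return ConcordanceReport(status="indeterminate", n_replicates=len(reps),
                                 tolerance_c=tolerance_c,
                                 reasons=["single replicate: concordance undefined"])
    reasons: list[str] = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = reps[i], reps[j]
            if a.n_peaks != b.n_peaks:
                reasons.append(f"{a.well_id} vs {b.well_id}: peak count "
                               f"{a.n_peaks} != {b.n_peaks}")
            elif not _matched_within(a.peak_temperatures, b.peak_temperatures,
                                     tolerance_c):
                reasons.append(f"{a.well_id} vs {b.well_id}: matched peaks "
                               f"differ by more than {tolerance_c} degC")
    status = "fail" if reasons else "pass"
    return ConcordanceReport(status=status, n_replicates=len(reps),
                             tolerance_c=tolerance_c, reasons=reasons)
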