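"""LOT histograms, the planned-vs-measured difference histogram, and the
leaf-open-time attainment rate.

The attainment rate eta is the fraction of planned leaf openings whose
measured-minus-planned LOT difference falls in the zero bin of the
difference histogram:

    eta = DeltaLOT(0) / sum_t DeltaLOT(t)

where DeltaLOT(t) counts events by their LOT difference, the zero bin
collects |Delta| <= bin_width/2, and the denominator is the total number of
planned openings — including those the MLC failed to execute (measured
LOT 0).  Zero-LOT plan entries are never events: a leaf that was never
meant to open contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShapeMismatchError, UndefinedStatisticError
from .simulate import MeasuredSinogram, PlannedSinogram

DEFAULT_BIN_WIDTH_MS = 5.0
DEFAULT_MAX_OFFSET_BINS = 20


@dataclass(frozen=True)
class LOTHistogram:
    """Histogram of nonzero LOTs over [0, projection duration), right-open bins."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    total_events: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.total_events:
            raise ValueError("histogram counts do not sum to total_events")


@dataclass(frozen=True)
class DifferenceHistogram:
    """Binned measured-minus-planned LOT differences for one fraction.

    ``bin_centers_ms`` is a symmetric grid k*w for k in -K..K; differences
    beyond the grid land in the two overflow bins.  ``extra_measured_events``
    counts openings observed where none was planned; they are reported but
    excluded from the histogram and from eta.
    """

    bin_width_ms: float
    bin_centers_ms: np.ndarray
    counts: np.ndarray
    underflow_count: int
    overflow_count: int
    total_planned_events: int
    extra_measured_events: int = 0

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers_ms, dtype=float)
        if len(centers) % 2 == 0 or not np.isclose(centers[len(centers) // 2], 0.0):
            raise ValueError("bin grid must be symmetric with a bin centered at 0")
        total = int(self.counts.sum()) + self.underflow_count + self.overflow_count
        if total != self.total_planned_events:
            raise ValueError("difference-histogram counts do not sum to the "
                             "planned event count")

    @property
    def zero_count(self) -> int:
        """Events in the bin centered at 0 (|Delta| <= bin_width/2)."""
        return int(self.counts[len(self.counts) // 2])


@dataclass(frozen=True)
class AttainmentResult:
    """The attainment rate with its audit counts.

    ``eta_percent`` is reported rounded to 3 decimal places, the precision
    at which the statistic is conventionally quoted (e.g. 96.513%).
    """

    eta: float
    eta_percent: float
    zero_count: int
    total_planned_events: int


def build_lot_histogram(sinogram: PlannedSinogram | MeasuredSinogram,
                        bin_width_ms: float = DEFAULT_BIN_WIDTH_MS) -> LOTHistogram:
    """Histogram the nonzero LOTs of a sinogram.

    Bins are right-open [k*w, (k+1)*w) covering [0, projection duration];
    zero-LOT entries are excluded (a closed leaf is not a leaf movement).
    An all-zero sinogram yields an empty histogram, not an error.
    """
    if bin_width_ms <= 0:
        raise ParameterError(f"bin_width_ms must be > 0, got {bin_width_ms}")
    w = float(bin_width_ms)
    n_bins = int(np.floor(sinogram.projection_duration_ms / w)) + 1
    edges = np.arange(n_bins + 1) * w
    values = sinogram.lot_ms[sinogram.lot_ms > 0]
    idx = np.floor(values / w).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    return LOTHistogram(edges, counts, int(values.size))


def difference_histogram(planned: PlannedSinogram, measured: MeasuredSinogram,
                         bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
                         max_offset_bins: int = DEFAULT_MAX_OFFSET_BINS,
                         absolute: bool = False) -> DifferenceHistogram:
    """Bin per-event LOT differences, paired by (projection, leaf).

    For every planned-nonzero event, Delta = measured - planned; the event
    goes to the bin whose center k*w is nearest, with boundary ties resolved
    toward zero (so the zero bin is exactly |Delta| <= w/2).  A planned
    opening the MLC never executed contributes Delta = -planned.  Measured
    openings with no planned counterpart are tallied separately as extras.
    With ``absolute=True`` differences are binned by magnitude (all mass at
    k >= 0); signed is the default since latency may run early or late.
    """
    if bin_width_ms <= 0:
        raise ParameterError(f"bin_width_ms must be > 0, got {bin_width_ms}")
    if planned.lot_ms.shape != measured.lot_ms.shape:
        raise ShapeMismatchError(
            f"planned sinogram shape {planned.lot_ms.shape} != measured "
            f"sinogram shape {measured.lot_ms.shape}")
    w = float(bin_width_ms)
    K = int(max_offset_bins)
    nz = planned.lot_ms > 0
    delta = measured.lot_ms[nz] - planned.lot_ms[nz]
    if absolute:
        delta = np.abs(delta)

    # nearest-center index with ties toward zero: k = ceil(|d|/w - 1/2), signed
    k = np.sign(delta) * np.ceil(np.abs(delta) / w - 0.5)
    k = k.astype(int)
    underflow = int(np.count_nonzero(k < -K))
    overflow = int(np.count_nonzero(k > K))
    counts = np.bincount(k[(k >= -K) & (k <= K)] + K, minlength=2 * K + 1).astype(np.int64)
    centers = np.arange(-K, K + 1) * w
    extras = int(np.count_nonzero((measured.lot_ms > 0) & ~nz))
    return DifferenceHistogram(w, centers, counts, underflow, overflow,
                               int(nz.sum()), extras)


def attainment_rate(diff: DifferenceHistogram) -> AttainmentResult:
    """eta = zero-bin count / total planned openings.

    Raises :class:`UndefinedStatisticError` when the plan contains no
    openings (an empty or all-zero plan has no defined attainment).
    """
    total = diff.total_planned_events
    if total == 0:
        raise UndefinedStatisticError(
            "attainment rate undefined: plan contains no leaf openings")
    eta = diff.zero_count / total
    return AttainmentResult(eta=eta, eta_percent=round(100.0 * eta, 3),
                            zero_count=diff.zero_count,
                            total_planned_events=total)


def compute_attainment(planned: PlannedSinogram, measured: MeasuredSinogram,
                       bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
                       absolute: bool = False) -> AttainmentResult:
    """Difference histogram + attainment rate in one step."""
    return attainment_rate(difference_histogram(planned, measured,
                                                bin_width_ms, absolute=absolute))
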