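"""Ploidy determination from chromosome counts and flow-cytometry histograms.

Two independent routes to a cytotype call:

* **Counting** — the modal metaphase chromosome count of a plant (at least
  ten well-spread cells are expected) is divided by the basic chromosome
  number (x = 11 in Musa, so 2n = 2x = 22 and 2n = 3x = 33). Counts that do
  not land within a tolerance of an integer multiple of x are refused as
  aneuploid-or-miscount rather than rounded to the nearest cytotype.

* **Flow cytometry** — relative nuclear DNA content histograms are measured
  with a co-chopped internal standard of known ploidy (the triploid
  single-bunching cultivar). Peaks are found on a moving-average-smoothed
  histogram via a prominence threshold; the dominant peak outside the
  control's channel band is converted to a ploidy by the ratio of its
  channel to the control channel, scaled by the control's ploidy. A peak
  too far from any integer-ploidy position is refused as unresolved.

Refusals are first-class results: cohort summaries tally calls by ploidy
and list every refusal with its reason, never dropping them silently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    AneuploidCountError,
    InvalidArgumentError,
    MusavarError,
    NoPeaksError,
    UnresolvedPloidyError,
)
from .profiles import BASIC_CHROMOSOME_NUMBER


@dataclass(frozen=True)
class CytologyObservation:
    """Per-metaphase chromosome counts for one plant."""

    plant_id: str
    cell_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.cell_counts:
            raise InvalidArgumentError("at least one metaphase count required")
        if any(c <= 0 for c in self.cell_counts):
            raise InvalidArgumentError("chromosome counts must be positive")


@dataclass(frozen=True)
class FlowHistogram:
    """DNA-content fluorescence histogram: nucleus counts per channel."""

    plant_id: str
    channels: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.counts) or not self.channels:
            raise InvalidArgumentError(
                "channels and counts must be equal-length and non-empty"
            )
        if any(c <= 0 for c in self.channels) or any(
            a >= b for a, b in zip(self.channels, self.channels[1:])
        ):
            raise InvalidArgumentError(
                "channels must be strictly increasing positive integers"
            )
        if any(c < 0 for c in self.counts):
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class PloidyCall:
    plant_id: str
    method: str  # "counting" | "flow"
    ploidy: int
    chromosome_number: int | None = None
    peak_channel: float | None = None
    ratio_to_control: float | None = None


@dataclass(frozen=True)
class CohortSummary:
    tally: dict[int, int]
    refused: tuple[tuple[str, str], ...]  # (plant_id, reason)


def modal_count(counts: Sequence[int]) -> int:
    """Most frequent value; ties resolved to the lower count (a slide more
    often loses a chromosome to squash damage than gains one)."""
    tallied = Counter(counts)
    best = max(tallied.values())
    return min(c for c, k in tallied.items() if k == best)


def count_to_ploidy(
    observation: CytologyObservation,
    basic_number: int = BASIC_CHROMOSOME_NUMBER,
    tolerance: int = 1,
) -> PloidyCall:
    """Ploidy from the modal metaphase chromosome count.

    Raises AneuploidCountError when the modal count is farther than
    ``tolerance`` chromosomes from every multiple of ``basic_number``.
    """
    if basic_number < 1:
        raise InvalidArgumentError("basic_number must be >= 1")
    if tolerance < 0:
        raise InvalidArgumentError("tolerance must be >= 0")
    m = modal_count(observation.cell_counts)
    ploidy = round(m / basic_number)
    if ploidy < 1 or abs(m - ploidy * basic_number) > tolerance:
        raise AneuploidCountError(
            f"{observation.plant_id}: modal count {m} is not within "
            f"{tolerance} of a multiple of x={basic_number}"
        )
    return PloidyCall(
        plant_id=observation.plant_id,
        method="counting",
        ploidy=ploidy,
        chromosome_number=m,
    )


def _smoothed(histogram: FlowHistogram, smooth_window: int) -> np.ndarray:
    counts = np.asarray(histogram.counts, dtype=float)
    kernel = np.ones(smooth_window)
    # normalize by actual kernel coverage so the edges are not damped,
    # which would turn a flat histogram into a phantom interior plateau
    coverage = np.convolve(np.ones_like(counts), kernel, mode="same")
    return np.convolve(counts, kernel, mode="same") / coverage


def detect_peaks(
    histogram: FlowHistogram,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.05,
) -> list[int]:
    """Channels of local maxima on the smoothed histogram.

    A maximum counts as a peak when its prominence reaches
    ``min_prominence_frac`` of the largest smoothed count. Returned in
    ascending channel order.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise InvalidArgumentError("smooth_window must be a positive odd int")
    if not 0 < min_prominence_frac <= 1:
        raise InvalidArgumentError("min_prominence_frac must be in (0, 1]")
    smoothed = _smoothed(histogram, smooth_window)
    if smoothed.max() <= 0:
        raise NoPeaksError(f"{histogram.plant_id}: histogram is all zeros")
    idx, _ = find_peaks(smoothed, prominence=min_prominence_frac * smoothed.max())
    if idx.size == 0:
        raise NoPeaksError(
            f"{histogram.plant_id}: no peak above the prominence floor"
        )
    return [histogram.channels[i] for i in idx]


def call_ploidy_flow(
    histogram: FlowHistogram,
    control_channel: float,
    control_ploidy: int = 3,
    max_rel_deviation: float = 0.2,
    control_band_frac: float = 0.1,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.05,
    min_channel_frac: float = 0.25,
) -> PloidyCall:
    """Ploidy from the dominant sample peak relative to the internal control.

    Channels below ``min_channel_frac`` x control_channel are treated as
    debris and never yield a sample peak (chopped-tissue preparations carry
    a strong low-fluorescence fragment tail). Peaks within
    ``control_band_frac`` (relative) of ``control_channel`` are attributed
    to the internal standard. The highest remaining peak p gives
    ploidy = round(control_ploidy * p / control_channel); the call is
    refused (UnresolvedPloidyError) when p deviates from the implied
    integer-ploidy channel by more than ``max_rel_deviation`` relative. When
    only the control-band peak exists the sample is indistinguishable from
    the control and is called at the control's ploidy.
    """
    if control_channel <= 0:
        raise InvalidArgumentError("control_channel must be positive")
    if control_ploidy < 1:
        raise InvalidArgumentError("control_ploidy must be >= 1")
    peaks = detect_peaks(histogram, smooth_window, min_prominence_frac)
    smoothed = _smoothed(histogram, smooth_window)
    height = {
        ch: smoothed[histogram.channels.index(ch)] for ch in peaks
    }
    peaks = [
        ch for ch in peaks if ch >= min_channel_frac * control_channel
    ]
    if not peaks:
        raise NoPeaksError(
            f"{histogram.plant_id}: every peak lies in the debris region"
        )
    sample_peaks = [
        ch
        for ch in peaks
        if abs(ch - control_channel) / control_channel > control_band_frac
    ]
    if sample_peaks:
        p = max(sample_peaks, key=lambda ch: height[ch])
    else:
        p = max(peaks, key=lambda ch: height[ch])  # merged with control
    ploidy = round(control_ploidy * p / control_channel)
    if ploidy < 1:
        raise UnresolvedPloidyError(
            f"{histogram.plant_id}: peak at channel {p} implies ploidy < 1"
        )
    expected = ploidy * control_channel / control_ploidy
    if abs(p - expected) / expected > max_rel_deviation:
        raise UnresolvedPloidyError(
            f"{histogram.plant_id}: peak at channel {p} deviates "
            f"{abs(p - expected) / expected:.2f} from the nearest "
            f"integer-ploidy position {expected:.1f}"
        )
    return PloidyCall(
        plant_id=histogram.plant_id,
        method="flow",
        ploidy=ploidy,
        peak_channel=float(p),
        ratio_to_control=p / control_channel,
    )


def call_cohort_flow(
    histograms: Iterable[FlowHistogram],
    control_channel: float,
    control_ploidy: int = 3,
    **kwargs,
) -> tuple[list[PloidyCall], list[tuple[str, str]]]:
    """Call every histogram, collecting refusals instead of raising."""
    calls: list[PloidyCall] = []
    refused: list[tuple[str, str]] = []
    for h in histograms:
        try:
            calls.append(
                call_ploidy_flow(h, control_channel, control_ploidy, **kwargs)
            )
        except MusavarError as exc:
            refused.append((h.plant_id, str(exc)))
    return calls, refused


def summarize_cohort(
    calls: Iterable[PloidyCall],
    refused: Iterable[tuple[str, str]] = (),
) -> CohortSummary:
    """Tally successful calls by ploidy; carry refusals alongside."""
    tally: Counter[int] = Counter(c.ploidy for c in calls)
    return CohortSummary(tally=dict(sorted(tally.items())), refused=tuple(refused))
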