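"""Preprocessing of labeled multichannel time series.

Turns per-paradigm recordings into the (time x channels) analysis matrix
consumed by the Mapper stage: anti-aliased downsampling, stimulus-only
row selection, channel intersection and pairwise paradigm concatenation.

Storage is time-major (time x channels) throughout the package; a single
convention avoids a transpose bug class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly

from .exceptions import (
    DataError,
    EmptyOutputError,
    IncompatibleInputsError,
    UnsupportedOperationError,
)

logger = logging.getLogger(__name__)

#: Recognised phase labels for a time point.
PHASES = ("stimulus", "fixation", "baseline", "missing")


@dataclass
class LabeledTimeSeries:
    """A (time x channels) recording with per-time-point labels.

    Parameters
    ----------
    data
        Real matrix, one row per time point, one column per channel.
    channel_ids
        Unique channel names, one per column.
    sampling_rate
        Sampling rate in Hz.
    paradigm
        Per-row experimental paradigm label (e.g. ``"Wrkmem"``).
    phase
        Per-row phase label, one of :data:`PHASES`.
    subject_id
        Identifier of the recorded subject.
    """

    data: np.ndarray
    channel_ids: list[str]
    sampling_rate: float
    paradigm: np.ndarray
    phase: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D (time x channels) matrix")
        self.paradigm = np.asarray(self.paradigm, dtype=object)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.data.shape[0]
        if len(self.paradigm) != n or len(self.phase) != n:
            raise DataError("label tracks must have exactly one entry per time row")
        if len(self.channel_ids) != self.data.shape[1]:
            raise DataError("channel_ids must have one entry per column")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise DataError("channel ids must be unique")
        if self.sampling_rate <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class AnalysisMatrix:
    """Concatenated two-paradigm matrix ready for Mapper.

    ``boundary`` marks where the first paradigm's rows end: rows
    ``[0, boundary)`` belong to the first-named paradigm, rows
    ``[boundary, n)`` to the second.
    """

    data: np.ndarray
    paradigm: np.ndarray
    boundary: int
    channel_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.paradigm = np.asarray(self.paradigm, dtype=object)
        if len(self.paradigm) != self.data.shape[0]:
            raise DataError("paradigm track must have one entry per row")
        if not 0 <= self.boundary <= self.data.shape[0]:
            raise DataError("boundary index outside the row range")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


def resample(ts: LabeledTimeSeries, target_rate: float) -> LabeledTimeSeries:
    """Downsample to ``target_rate`` Hz with polyphase anti-alias filtering.

    Labels are decimated consistently: each output row takes the labels of
    the nearest original time point. Upsampling is not supported.
    """
    if target_rate <= 0:
        raise UnsupportedOperationError("target rate must be positive")
    if target_rate > ts.sampling_rate:
        raise UnsupportedOperationError(
            f"upsampling {ts.sampling_rate} Hz -> {target_rate} Hz is not supported"
        )
    if target_rate == ts.sampling_rate:
        return replace(ts)

    ratio = Fraction(target_rate / ts.sampling_rate).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    new_data = resample_poly(ts.data, up, down, axis=0)
    n_new = new_data.shape[0]
    # output sample i sits at original index i * down / up
    src = np.clip(np.rint(np.arange(n_new) * down / up).astype(int), 0, ts.n_timepoints - 1)
    return LabeledTimeSeries(
        data=new_data,
        channel_ids=list(ts.channel_ids),
        sampling_rate=float(target_rate),
        paradigm=ts.paradigm[src],
        phase=ts.phase[src],
        subject_id=ts.subject_id,
    )


def select_stimulus_timepoints(ts: LabeledTimeSeries) -> LabeledTimeSeries:
    """Keep only stimulus-phase rows whose values are all finite.

    Fixation and baseline periods are discarded, as are rows containing
    missing (non-finite) values; temporal order is preserved.
    """
    finite = np.isfinite(ts.data).all(axis=1)
    keep = (ts.phase == "stimulus") & finite
    if not keep.any():
        raise EmptyOutputError("no stimulus rows with fully finite values survive")
    return LabeledTimeSeries(
        data=ts.data[keep],
        channel_ids=list(ts.channel_ids),
        sampling_rate=ts.sampling_rate,
        paradigm=ts.paradigm[keep],
        phase=ts.phase[keep],
        subject_id=ts.subject_id,
    )


def intersect_and_concatenate(
    a: LabeledTimeSeries,
    b: LabeledTimeSeries,
    order: tuple[str, str] | None = None,
) -> AnalysisMatrix:
    """Concatenate two paradigm recordings across their common channels.

    Columns are restricted to the channel-id intersection in lexicographic
    order; the first-named paradigm's rows precede the second's, and the
    boundary index records where they meet.
    """
    if order is None:
        order = (str(a.paradigm[0]), str(b.paradigm[0]))
    by_name = {}
    for ts in (a, b):
        for name in np.unique(ts.paradigm):
            by_name[str(name)] = ts
    try:
        first, second = by_name[order[0]], by_name[order[1]]
    except KeyError as exc:
        raise IncompatibleInputsError(f"paradigm {exc} not present in the inputs") from exc

    common = sorted(set(first.channel_ids) & set(second.channel_ids))
    if not common:
        raise IncompatibleInputsError("the two paradigms share no channels")
    cols_first = [first.channel_ids.index(c) for c in common]
    cols_second = [second.channel_ids.index(c) for c in common]

    data = np.vstack([first.data[:, cols_first], second.data[:, cols_second]])
    paradigm = np.concatenate([first.paradigm, second.paradigm])
    subject = first.subject_id or second.subject_id
    return AnalysisMatrix(
        data=data,
        paradigm=paradigm,
        boundary=first.n_timepoints,
        channel_ids=common,
        subject_id=subject,
    )


def split_paradigms(ts: LabeledTimeSeries) -> dict[str, LabeledTimeSeries]:
    """Split a multi-paradigm series into one series per paradigm label."""
    out: dict[str, LabeledTimeSeries] = {}
    for name in np.unique(ts.paradigm):
        mask = ts.paradigm == name
        out[str(name)] = LabeledTimeSeries(
            data=ts.data[mask],
            channel_ids=list(ts.channel_ids),
            sampling_rate=ts.sampling_rate,
            paradigm=ts.paradigm[mask],
            phase=ts.phase[mask],
            subject_id=ts.subject_id,
        )
    return out


def to_analysis_matrix(ts: LabeledTimeSeries, order: tuple[str, str]) -> AnalysisMatrix:
    """Build the two-paradigm analysis matrix from one concatenated series."""
    parts = split_paradigms(ts)
    try:
        a, b = parts[order[0]], parts[order[1]]
    except KeyError as exc:
        raise IncompatibleInputsError(f"paradigm {exc} not present") from exc
    return intersect_and_concatenate(a, b, order=order)
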