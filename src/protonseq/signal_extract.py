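"""Reduce a raw trace to per-chunk on-fractions and their median.

The trace is cut into non-overlapping chunks of fixed duration (1 ms by
default; a trailing partial chunk is dropped).  Each chunk is median-filtered
(size 3 by default, edges handled by shrinking the window) to remove
single-sample outliers, thresholded at the midpoint between its filtered
minimum and maximum, and the fraction of samples strictly above the threshold
is the chunk's on-fraction.  The per-residue summary statistic is the median
over the chunk on-fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_sim import Trace

__all__ = ["Measurement", "median_filter", "chunk_on_fraction", "summarize"]


@dataclass(frozen=True)
class Measurement:
    """Per-residue summary of one measurement window."""

    chunk_on_fractions: np.ndarray
    median_on_fraction: float
    chunk_duration: float = 1e-3
    filter_size: int = 3


def median_filter(window: np.ndarray, size: int = 3) -> np.ndarray:
    """Running median with window shrinkage at the edges.

    At the boundaries the window is truncated to the available samples, so a
    size-3 filter takes the 2-element median (their midpoint) at each end.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("filter size must be a positive odd integer")
    window = np.asarray(window, dtype=float)
    n = len(window)
    if n < size:
        raise ValueError("window shorter than the filter size")
    if size == 1:
        return window.copy()
    if size == 3:
        a, b, c = window[:-2], window[1:-1], window[2:]
        out = np.empty(n)
        # median of three via min/max identities (no sort)
        out[1:-1] = np.maximum(np.minimum(a, b), np.minimum(np.maximum(a, b), c))
        out[0] = 0.5 * (window[0] + window[1])
        out[-1] = 0.5 * (window[-2] + window[-1])
        return out
    half = size // 2
    padded = np.full(n + 2 * half, np.nan)
    padded[half : half + n] = window
    from numpy.lib.stride_tricks import sliding_window_view

    return np.nanmedian(sliding_window_view(padded, size), axis=1)


def chunk_on_fraction(window: np.ndarray, filter_size: int = 3) -> float:
    """On-fraction of one chunk: the fraction of median-filtered samples
    strictly above the midpoint of the filtered extrema.

    A constant (degenerate) chunk yields 0 — no sample is strictly above a
    threshold equal to the constant itself.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    filtered = median_filter(window, filter_size)
    threshold = 0.5 * (filtered.max() + filtered.min())
    return float(np.count_nonzero(filtered > threshold) / len(filtered))


def _chunk_fractions_fast(values: np.ndarray, chunk_len: int) -> np.ndarray:
    """Vectorised size-3 filtering + thresholding of all complete chunks."""
    n_chunks = len(values) // chunk_len
    x = values[: n_chunks * chunk_len].reshape(n_chunks, chunk_len)
    a, b, c = x[:, :-2], x[:, 1:-1], x[:, 2:]
    filt = np.empty_like(x)
    filt[:, 1:-1] = np.maximum(np.minimum(a, b), np.minimum(np.maximum(a, b), c))
    filt[:, 0] = 0.5 * (x[:, 0] + x[:, 1])
    filt[:, -1] = 0.5 * (x[:, -2] + x[:, -1])
    thr = 0.5 * (filt.max(axis=1) + filt.min(axis=1))
    return np.count_nonzero(filt > thr[:, None], axis=1) / chunk_len


def summarize(
    trace: Trace,
    chunk_duration: float = 1e-3,
    filter_size: int = 3,
) -> Measurement:
    """Chunk a trace and aggregate per-chunk on-fractions by their median.

    The trailing partial chunk (if any) is dropped so that all chunk
    statistics are identically distributed; an even chunk count takes the
    midpoint of the central order statistics.
    """
    chunk_len = int(round(chunk_duration * trace.sample_rate))
    if chunk_len < 1 or len(trace.values) < chunk_len:
        raise ValueError("trace shorter than one chunk")
    if filter_size == 3 and chunk_len >= 3:
        fractions = _chunk_fractions_fast(trace.values, chunk_len)
    else:
        n_chunks = len(trace.values) // chunk_len
        fractions = np.array(
            [
                chunk_on_fraction(
                    trace.values[i * chunk_len : (i + 1) * chunk_len], filter_size
                )
                for i in range(n_chunks)
            ]
        )
    return Measurement(
        chunk_on_fractions=fractions,
        median_on_fraction=float(np.median(fractions)),
        chunk_duration=chunk_duration,
        filter_size=filter_size,
    )
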