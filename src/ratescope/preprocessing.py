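"""Trace quality control.

Mirrors the imaging-side selection rules: an autofluorescence preselection
threshold (8,000 AU with at least ten points strictly above it), in-silico
synchronization of traces to cell division, truncation at the first
fluorescence maximum (restricting each trace to one cell cycle), and random
subsampling of 30-35 onset curves per construct.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace

import numpy as np

from .datatypes import FluorescenceTrace, QCReport
from .errors import ConfigurationError, DataError

DEFAULT_THRESHOLD = 8000.0
DEFAULT_MIN_POINTS = 10


def preselect(
    traces: list[FluorescenceTrace],
    threshold: float = DEFAULT_THRESHOLD,
    min_points: int = DEFAULT_MIN_POINTS,
    report: QCReport | None = None,
) -> tuple[list[FluorescenceTrace], QCReport]:
    """Keep traces with at least ``min_points`` samples strictly above
    ``threshold``; order is preserved."""
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    if not traces:
        raise DataError("no traces to preselect")
    report = report or QCReport()
    kept = []
    for tr in traces:
        n_above = int(np.sum(tr.values > threshold))
        ok = n_above >= min_points
        report.record(tr.cell_id, "preselect", ok,
                      "" if ok else f"only {n_above} points above {threshold:g}")
        if ok:
            kept.append(tr)
    report.count("preselect", len(traces), len(kept))
    return kept, report


def synchronize_to_division(
    trace: FluorescenceTrace,
    min_points: int = DEFAULT_MIN_POINTS,
    report: QCReport | None = None,
) -> list[FluorescenceTrace]:
    """Split a trace at its division markers into per-generation segments.

    Each segment is re-indexed with time zero at its start; the boundary
    sample joins the post-division segment (the post-mitotic marker opens
    the new generation).  Segments shorter than ``min_points`` are dropped
    with the reason recorded.
    """
    if trace.divisions.size == 0:
        return [trace]
    markers = np.sort(trace.divisions)
    if markers[0] < trace.times[0] or markers[-1] > trace.times[-1]:
        raise DataError(
            f"trace {trace.cell_id}: division marker outside the time range")
    # split index = first sample at or after the marker
    cuts = np.searchsorted(trace.times, markers, side="left")
    cuts = [0, *[int(c) for c in cuts], trace.times.size]
    segments = []
    for g, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:])):
        if hi <= lo:
            continue
        seg = FluorescenceTrace(
            cell_id=f"{trace.cell_id}/g{g}",
            construct_id=trace.construct_id,
            times=trace.times[lo:hi] - trace.times[lo],
            values=trace.values[lo:hi].copy(),
            metadata={**trace.metadata, "generation": g},
        )
        if seg.n_points < min_points:
            if report is not None:
                report.record(seg.cell_id, "synchronize", False,
                              f"segment has {seg.n_points} < {min_points} points")
            continue
        if report is not None:
            report.record(seg.cell_id, "synchronize", True)
        segments.append(seg)
    return segments


def truncate_at_peak(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Return the prefix up to and including the first global maximum.

    Idempotent; restricts the trajectory to the rising phase before signal
    dilution at division.
    """
    idx = int(np.argmax(trace.values))  # first occurrence of the maximum
    return replace(
        trace,
        times=trace.times[: idx + 1].copy(),
        values=trace.values[: idx + 1].copy(),
        divisions=trace.divisions[trace.divisions <= trace.times[idx]]
        if trace.divisions.size else trace.divisions,
    )


def subsample(
    traces: list[FluorescenceTrace],
    rng: np.random.Generator,
    n_low: int = 30,
    n_high: int = 35,
    report: QCReport | None = None,
) -> tuple[list[FluorescenceTrace], QCReport]:
    """Per construct, select uniformly without replacement a random number
    of traces drawn from [n_low, n_high], capped at availability.

    Constructs with fewer than ``n_low`` traces pass through unchanged with
    a warning.
    """
    report = report or QCReport()
    by_construct: dict[str, list[FluorescenceTrace]] = defaultdict(list)
    for tr in traces:
        by_construct[tr.construct_id].append(tr)
    out = []
    for construct in by_construct:  # insertion order
        group = by_construct[construct]
        if len(group) < n_low:
            report.warn(
                f"construct {construct}: only {len(group)} traces available "
                f"(< {n_low}); passing all through")
            out.extend(group)
            continue
        target = int(rng.integers(n_low, n_high + 1))
        target = min(target, len(group))
        idx = np.sort(rng.choice(len(group), size=target, replace=False))
        out.extend(group[i] for i in idx)
    report.count("subsample", len(traces), len(out))
    return out, report


def preprocess(
    traces: list[FluorescenceTrace],
    seed: int,
    threshold: float = DEFAULT_THRESHOLD,
    min_points: int = DEFAULT_MIN_POINTS,
    n_low: int = 30,
    n_high: int = 35,
) -> tuple[list[FluorescenceTrace], QCReport]:
    """Full QC pipeline: preselect -> synchronize -> truncate -> subsample.

    Returns the surviving traces and a reproducible QC report.  Every
    emitted trace has at least ``min_points`` samples.
    """
    report = QCReport(seed=seed)
    kept, _ = preselect(traces, threshold, min_points, report)
    synced: list[FluorescenceTrace] = []
    for tr in kept:
        synced.extend(synchronize_to_division(tr, min_points, report))
    truncated = []
    for tr in synced:
        cut = truncate_at_peak(tr)
        ok = cut.n_points >= min_points
        if report is not None:
            report.record(cut.cell_id, "truncate", ok,
                          "" if ok else f"peak within first {cut.n_points} points")
        if ok:
            truncated.append(cut)
    report.count("truncate", len(synced), len(truncated))
    rng = np.random.default_rng(seed)
    final, _ = subsample(truncated, rng, n_low, n_high, report)
    return final, report
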