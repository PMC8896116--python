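"""Benchmark statistics: detection power, call-set overlap, silencer strength.

Works on any interval-like records exposing ``contig``/``start``/``end``
attributes or plain ``(contig, start, end)`` triples, so calls, truth
regions and BED rows mix freely. The overlap rule is >= 1 bp everywhere;
no reciprocal-overlap fraction is required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coverage_io import CoverageTrack
from .curve_similarity import pearson_correlation

__all__ = [
    "EvalReport",
    "detection_power",
    "callset_overlap",
    "strength_ratio",
    "strength_ratio_from_sums",
    "similarity_strength_correlation",
]


@dataclass(frozen=True)
class EvalReport:
    n_calls: int
    n_truth: int
    n_recovered: int
    power: float
    venn: Optional[tuple[int, int, int]] = None  # (only_a, only_b, both)
    strength_ratios: tuple[float, ...] = field(default_factory=tuple)


def _as_triple(iv) -> tuple[str, int, int]:
    if hasattr(iv, "contig"):
        return (iv.contig, iv.start, iv.end)
    contig, start, end = iv[0], iv[1], iv[2]
    return (contig, start, end)


def _by_contig(intervals) -> dict[str, np.ndarray]:
    groups: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        contig, start, end = _as_triple(iv)
        groups.setdefault(contig, []).append((start, end))
    return {
        c: np.array(sorted(rows), dtype=np.int64).reshape(-1, 2)
        for c, rows in groups.items()
    }


def _check_disjoint(groups: dict[str, np.ndarray], label: str) -> None:
    for contig, arr in groups.items():
        if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError(f"{label} contains internally overlapping intervals on {contig}")


def _hits(query_groups: dict[str, np.ndarray], subject_groups: dict[str, np.ndarray]) -> int:
    """Number of query intervals overlapping >= 1 subject interval by >= 1 bp."""
    hits = 0
    for contig, q in query_groups.items():
        s = subject_groups.get(contig)
        if s is None or len(s) == 0:
            continue
        # subject intervals sorted and disjoint: query (a,b) overlaps one iff
        # some subject start < b and that subject's end > a
        idx = np.searchsorted(s[:, 1], q[:, 0], side="right")
        overlap = (idx < len(s)) & (s[np.minimum(idx, len(s) - 1), 0] < q[:, 1])
        hits += int(np.count_nonzero(overlap))
    return hits


def detection_power(calls: Sequence, truth: Sequence) -> tuple[int, float]:
    """(n_recovered, power): truth regions hit by >= 1 call, and their fraction.

    Each truth region counts once no matter how many calls overlap it; power
    is recovered spiked silencers over total spiked silencers.
    """
    if len(truth) == 0:
        raise ValueError("empty truth set")
    truth_groups = _by_contig(truth)
    _check_disjoint(truth_groups, "truth set")
    call_groups = _by_contig(calls)
    recovered = _hits(truth_groups, _merge(call_groups))
    return recovered, recovered / len(truth)


def _merge(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Merge possibly-overlapping sorted intervals so _hits can binary-search."""
    merged: dict[str, np.ndarray] = {}
    for contig, arr in groups.items():
        out: list[list[int]] = []
        for s, e in arr:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = np.array(out, dtype=np.int64).reshape(-1, 2)
    return merged


def callset_overlap(a: Sequence, b: Sequence) -> tuple[int, int, int]:
    """Venn counts (only_a, only_b, both) under the >= 1 bp overlap rule.

    Each input set must be internally disjoint. ``both`` is counted from
    set a's perspective (number of a-intervals touching b).
    """
    ga, gb = _by_contig(a), _by_contig(b)
    _check_disjoint(ga, "set a")
    _check_disjoint(gb, "set b")
    hits_a = _hits(ga, gb)
    hits_b = _hits(gb, ga)
    return (len(a) - hits_a, len(b) - hits_b, hits_a)


def strength_ratio_from_sums(treat_sum: float, control_sum: float, eps: float = 1.0) -> float:
    """−log2((treat + ε)/(control + ε)); ε (default 1) guards zero coverage."""
    return -math.log2((treat_sum + eps) / (control_sum + eps))


def strength_ratio(call, treat: CoverageTrack, control: CoverageTrack, eps: float = 1.0) -> float:
    """Silencer strength over a call: −log2 of the cDNA/insert read-depth ratio."""
    _, start, end = _as_triple(call)
    for track in (treat, control):
        if start < track.origin or end > track.end:
            raise ValueError("tracks do not cover the call interval")
    t = float(treat.values[start - treat.origin : end - treat.origin].sum())
    c = float(control.values[start - control.origin : end - control.origin].sum())
    return strength_ratio_from_sums(t, c, eps)


def similarity_strength_correlation(calls: Sequence) -> Optional[float]:
    """Pearson correlation of similarity index vs strength ratio across calls.

    Needs >= 3 calls with finite values of both; returns None (not
    available) otherwise, or when either quantity has zero variance.
    """
    idx = np.array([c.similarity_index for c in calls], dtype=np.float64)
    strength = np.array([c.strength_ratio for c in calls], dtype=np.float64)
    finite = np.isfinite(idx) & np.isfinite(strength)
    if np.count_nonzero(finite) < 3:
        return None
    idx, strength = idx[finite], strength[finite]
    if np.ptp(idx) == 0 or np.ptp(strength) == 0:
        warnings.warn("zero variance in similarity or strength; correlation undefined")
        return None
    return pearson_correlation(idx, strength)
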