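"""Silencer calling: anchors → windows → filters → overlap resolution → correction.

The pipeline, in order:

1. per-base coverage of the reporter (treat) and insert (control) libraries;
2. per-base negative-binomial depletion p-values;
3. count-difference prescreen (control − treat >= min_diff);
4. anchors = nucleotides passing both the prescreen and the p threshold;
5. each anchor seeds a window of ``window_size`` bp centered on it
   (clamped at contig edges);
6. windows keep only if >= ``min_fraction`` of their bases have p below the
   threshold;
7. overlapping windows resolved greedily, smallest window p-value first;
8. windows whose treat/control coverage curves are too similar are dropped;
9. the surviving window p-values are corrected (BH by default) and calls
   with adjusted p below the reporting threshold are emitted.

Every stage is deterministic, so a fixed input and config always produce
byte-identical output.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .coverage_io import CoverageTrack, FragmentSet, compute_coverage
from .curve_similarity import (
    METRICS,
    CoverageCurve,
    compute_similarity,
)
from .evaluation import strength_ratio_from_sums
from .nb_stats import PValueTrack, bh_adjust, bonferroni_adjust, prescreen_mask, pvalue_track

__all__ = [
    "AnchorSite",
    "CandidateWindow",
    "SilencerCall",
    "CallConfig",
    "find_anchors",
    "extend_window",
    "fraction_filter",
    "window_pvalue",
    "resolve_overlaps",
    "call_silencers",
]


@dataclass(frozen=True)
class AnchorSite:
    """A nucleotide passing both the count-difference and p-value screens."""

    contig: str
    position: int
    pvalue: float
    count_diff: int


@dataclass(frozen=True)
class CandidateWindow:
    contig: str
    start: int
    end: int
    window_p: float
    passing_fraction: float
    similarity_score: float = float("nan")
    similarity_index: float = float("nan")
    adjusted_p: float = float("nan")


@dataclass(frozen=True)
class SilencerCall:
    contig: str
    start: int
    end: int
    window_p: float
    adjusted_p: float
    similarity_score: float
    similarity_index: float
    strength_ratio: float


@dataclass(frozen=True)
class CallConfig:
    """Every threshold of the calling pipeline in one place.

    Defaults are the published operating point: per-site p < 1e-5 paired
    with a count difference of 12, 601-bp windows, 3/4 passing fraction,
    cosine similarity with threshold 0.9, BH correction and a corrected-p
    reporting threshold of 1e-5.
    """

    p_thresh: float = 1e-5
    min_diff: int = 12
    window_size: int = 601
    min_fraction: float = 0.75
    similarity_metric: str = "cosine"
    similarity_threshold: float = 0.9
    correction: str = "bh"  # "bh" or "bonferroni"
    report_thresh: float = 1e-5
    window_p_method: str = "min"  # "min" or "median"
    strength_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd (anchor-centered design)")
        if self.similarity_metric not in METRICS:
            raise ValueError(f"unknown similarity metric {self.similarity_metric!r}")
        if self.correction not in ("bh", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.window_p_method not in ("min", "median"):
            raise ValueError(f"unknown window_p_method {self.window_p_method!r}")


def find_anchors(
    ptrack: PValueTrack,
    mask: np.ndarray,
    p_thresh: float = 1e-5,
    count_diff: Optional[np.ndarray] = None,
) -> list[AnchorSite]:
    """Anchors at positions where the prescreen mask holds and p < p_thresh."""
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(ptrack):
        raise ValueError("mask and p-value track are misaligned")
    if count_diff is not None and len(count_diff) != len(ptrack):
        raise ValueError("count_diff and p-value track are misaligned")
    hit = np.flatnonzero(mask & (ptrack.pvalues < p_thresh))
    return [
        AnchorSite(
            contig=ptrack.contig,
            position=ptrack.origin + int(i),
            pvalue=float(ptrack.pvalues[i]),
            count_diff=int(count_diff[i]) if count_diff is not None else 0,
        )
        for i in hit
    ]


def extend_window(
    anchor: "AnchorSite | int", window_size: int = 601, contig_length: int | None = None
) -> tuple[int, int]:
    """Center a window of ``window_size`` bp on the anchor, clamped to the contig."""
    if window_size % 2 != 1:
        raise ValueError("window_size must be odd")
    pos = anchor.position if isinstance(anchor, AnchorSite) else int(anchor)
    half = (window_size - 1) // 2
    start = max(0, pos - half)
    end = pos + half + 1
    if contig_length is not None:
        end = min(end, contig_length)
    return start, end


def fraction_filter(
    window: tuple[int, int],
    ptrack: PValueTrack,
    frac: float = 0.75,
    p_thresh: float = 1e-5,
) -> tuple[bool, float]:
    """Keep a window iff >= ``frac`` of its (possibly clamped) bases pass p_thresh."""
    start, end = window
    if start >= end:
        raise ValueError("empty window")
    if start < ptrack.origin or end > ptrack.origin + len(ptrack):
        raise ValueError("window outside the p-value track span")
    sl = ptrack.pvalues[start - ptrack.origin : end - ptrack.origin]
    passing = float(np.count_nonzero(sl < p_thresh)) / (end - start)
    return passing >= frac, passing


def window_pvalue(
    window: tuple[int, int], ptrack: PValueTrack, method: str = "min"
) -> float:
    """Aggregate per-base p-values over a window (min by default, or median)."""
    start, end = window
    if start >= end or start < ptrack.origin or end > ptrack.origin + len(ptrack):
        raise ValueError("window outside the p-value track span")
    sl = ptrack.pvalues[start - ptrack.origin : end - ptrack.origin]
    if method == "min":
        return float(sl.min())
    if method == "median":
        return float(np.median(sl))
    raise ValueError(f"unknown method {method!r}")


def resolve_overlaps(windows: Sequence[CandidateWindow]) -> list[CandidateWindow]:
    """Greedy selection by ascending window p: keep a window iff it overlaps
    no better (already kept) window.

    Ties on window_p break by leftmost start, then smallest end, so the
    result is deterministic; the output is coordinate-sorted and pairwise
    disjoint. Greedy-by-p, unlike pairwise elimination, does not depend on
    input order and always keeps the smallest-p window of any overlap chain.
    """
    kept_by_contig: dict[str, tuple[list[int], list[int], list[CandidateWindow]]] = {}
    ranked = sorted(windows, key=lambda w: (w.window_p, w.contig, w.start, w.end))
    for w in ranked:
        starts, ends, kept = kept_by_contig.setdefault(w.contig, ([], [], []))
        i = bisect.bisect_right(starts, w.start)
        if i > 0 and ends[i - 1] > w.start:
            continue
        if i < len(starts) and starts[i] < w.end:
            continue
        starts.insert(i, w.start)
        ends.insert(i, w.end)
        kept.insert(i, w)
    out: list[CandidateWindow] = []
    for contig in sorted(kept_by_contig):
        out.extend(kept_by_contig[contig][2])
    return out


def call_silencers(
    treat: FragmentSet,
    control: FragmentSet,
    config: CallConfig = CallConfig(),
    contig_length: int | None = None,
) -> list[SilencerCall]:
    """Run the full calling pipeline on one contig's paired libraries."""
    if treat.contig != control.contig:
        raise ValueError("treat and control libraries are on different contigs")
    if contig_length is None:
        ends = [int(f.fragments[:, 1].max()) for f in (treat, control) if len(f)]
        if not ends:
            return []
        contig_length = max(ends)

    interval = (0, contig_length)
    tcov = compute_coverage(treat, interval)
    ccov = compute_coverage(control, interval)
    ptrack = pvalue_track(tcov, ccov, treat.total_count, control.total_count)
    mask = prescreen_mask(tcov, ccov, config.min_diff)
    diff = ccov.values - tcov.values

    anchors = find_anchors(ptrack, mask, config.p_thresh, count_diff=diff)
    if not anchors:
        return []

    # prefix sums make the per-window passing fraction O(1) per anchor
    passing = np.concatenate(
        ([0], np.cumsum((ptrack.pvalues < config.p_thresh).astype(np.int64)))
    )
    candidates: list[CandidateWindow] = []
    for a in anchors:
        start, end = extend_window(a, config.window_size, contig_length)
        frac = (passing[end] - passing[start]) / (end - start)
        if frac < config.min_fraction:
            continue
        wp = window_pvalue((start, end), ptrack, config.window_p_method)
        candidates.append(
            CandidateWindow(
                contig=treat.contig,
                start=start,
                end=end,
                window_p=wp,
                passing_fraction=float(frac),
            )
        )

    survivors = resolve_overlaps(candidates)

    shaped: list[CandidateWindow] = []
    for w in survivors:
        x = np.arange(w.start, w.end, dtype=np.float64)
        cu = CoverageCurve(x=x, y=tcov.values[w.start : w.end])
        cv = CoverageCurve(x=x, y=ccov.values[w.start : w.end])
        res = compute_similarity(cu, cv, config.similarity_metric)
        if res.similarity_score > config.similarity_threshold:
            continue
        shaped.append(
            replace(
                w,
                similarity_score=res.similarity_score,
                similarity_index=res.similarity_index,
            )
        )
    if not shaped:
        return []

    adjust = bh_adjust if config.correction == "bh" else bonferroni_adjust
    adjusted = adjust([w.window_p for w in shaped])

    calls: list[SilencerCall] = []
    for w, padj in zip(shaped, adjusted):
        if padj >= config.report_thresh:
            continue
        tsum = float(tcov.values[w.start : w.end].sum())
        csum = float(ccov.values[w.start : w.end].sum())
        calls.append(
            SilencerCall(
                contig=w.contig,
                start=w.start,
                end=w.end,
                window_p=w.window_p,
                adjusted_p=float(padj),
                similarity_score=w.similarity_score,
                similarity_index=w.similarity_index,
                strength_ratio=strength_ratio_from_sums(
                    tsum, csum, config.strength_pseudocount
                ),
            )
        )
    calls.sort(key=lambda c: (c.contig, c.start))
    return calls
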