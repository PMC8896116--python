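"""Alignment/coverage input and interval-table output.

All coordinates are 0-based half-open, matching BAM/BED/bedGraph conventions.
Fragments are template spans (proper pairs) or read spans (unpaired reads);
coverage is unstranded per-base fragment depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "FragmentSet",
    "CoverageTrack",
    "read_chrom_sizes",
    "load_fragments",
    "compute_coverage",
    "load_bedgraph",
    "write_bedgraph",
    "write_calls_bed",
    "load_bed_intervals",
]


@dataclass(frozen=True)
class FragmentSet:
    """Fragments of one sequencing library on one contig.

    ``total_count`` is the library-wide number of retained fragments (the
    treatTotal / controlTotal of the depletion test), not the per-contig
    count, so it may exceed ``len(fragments)``.
    """

    contig: str
    fragments: np.ndarray  # (N, 2) int64, start < end, 0-based half-open
    total_count: int

    def __post_init__(self) -> None:
        frags = np.asarray(self.fragments, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "fragments", frags)
        if frags.size:
            if np.any(frags[:, 0] < 0):
                raise ValueError("fragment start < 0")
            if np.any(frags[:, 0] >= frags[:, 1]):
                raise ValueError("fragment with start >= end")
        if self.total_count < len(frags):
            raise ValueError(
                f"total_count ({self.total_count}) smaller than fragments held "
                f"({len(frags)}); totals are library-wide"
            )

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base integer coverage over ``[origin, origin + len(values))``."""

    contig: str
    origin: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", vals)
        if vals.size and vals.min() < 0:
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> int:
        return self.origin + len(self.values)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` table into a name → length dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def load_fragments(
    path: str | Path,
    contig: str,
    *,
    mapq_min: int = 20,
    dedup: bool = True,
) -> FragmentSet:
    """Load fragments for one contig from a coordinate-sorted BAM/SAM file.

    Proper pairs contribute one fragment spanning the template (leftmost read
    start to start + TLEN); unpaired reads contribute their read span.
    Records below ``mapq_min`` and secondary/supplementary/unmapped records
    are dropped. With ``dedup`` (the default, mirroring duplicate removal in
    typical STARR-seq preprocessing), fragments with an identical
    (contig, start, end) beyond the first are dropped. ``total_count`` counts
    retained fragments over the whole library, not just ``contig``.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as af:
        if contig not in af.references:
            raise KeyError(f"contig {contig!r} not in {path} header")
        contig_len = af.get_reference_length(contig)

        total = 0
        frags: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        cur_ref: str | None = None
        last_start = -1
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    continue
                # count each pair once, from its leftmost mate
                if read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start = read.reference_start
                end = read.reference_end
                if end is None or end <= start:
                    continue
            rname = read.reference_name
            if rname != cur_ref:
                cur_ref = rname
                last_start = -1
                seen = set()
            if start < last_start:
                raise ValueError(f"{path} is not coordinate-sorted")
            last_start = start
            if dedup:
                key = (start, end)
                if key in seen:
                    continue
                seen.add(key)
            total += 1
            if rname == contig:
                frags.append((start, min(end, contig_len)))

    arr = np.array(frags, dtype=np.int64).reshape(-1, 2)
    return FragmentSet(contig=contig, fragments=arr, total_count=total)


def compute_coverage(frags: FragmentSet, interval: tuple[int, int]) -> CoverageTrack:
    """Per-base fragment depth over ``interval`` via difference-array accumulation.

    ``values[i]`` counts fragments f with ``f.start <= origin+i < f.end``.
    """
    start, end = interval
    if start < 0 or start >= end:
        raise ValueError(f"invalid interval {interval!r}")
    n = end - start
    diff = np.zeros(n + 1, dtype=np.int64)
    f = frags.fragments
    if len(f):
        s = np.clip(f[:, 0] - start, 0, n)
        e = np.clip(f[:, 1] - start, 0, n)
        keep = s < e
        np.add.at(diff, s[keep], 1)
        np.add.at(diff, e[keep], -1)
    return CoverageTrack(contig=frags.contig, origin=start, values=np.cumsum(diff[:-1]))


def load_bedgraph(
    path: str | Path, contig: str, interval: tuple[int, int]
) -> CoverageTrack:
    """Read a 4-column bedGraph into a coverage track over ``interval``.

    Positions not covered by any bedGraph line are 0; overlapping lines on
    the requested contig are a format error.
    """
    start, end = interval
    if start < 0 or start >= end:
        raise ValueError(f"invalid interval {interval!r}")
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if parts[0] == contig:
                rows.append((s, e, int(round(v))))
    rows.sort()
    values = np.zeros(end - start, dtype=np.int64)
    prev_end = -1
    for s, e, v in rows:
        if s < prev_end:
            raise ValueError(f"overlapping bedGraph intervals on {contig}")
        prev_end = e
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            values[lo - start : hi - start] = v
    return CoverageTrack(contig=contig, origin=start, values=values)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as run-length-encoded bedGraph (zeros omitted)."""
    v = track.values
    with open(path, "w") as fh:
        if len(v) == 0:
            return
        # boundaries of constant runs
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{track.contig}\t{track.origin + s}\t{track.origin + e}\t{v[s]}\n")


_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\t"
    "pvalue\tadjusted_pvalue\tsimilarity_score\tstrength_ratio"
)


def bed_score(adjusted_p: float) -> int:
    """BED score column: min(1000, round(-10*log10(adjusted p)))."""
    if adjusted_p <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(adjusted_p))))


def write_calls_bed(calls: Sequence, path: str | Path, *, header_extra: Iterable[str] = ()) -> None:
    """Write silencer calls as BED6+4 (p, adjusted p, similarity, strength).

    Calls must be sorted by (contig, start); extra ``#``-prefixed header
    lines (e.g. the thresholds used) can be prepended for provenance.
    """
    keys = [(c.contig, c.start) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (contig, start)")
    with open(path, "w") as fh:
        for line in header_extra:
            fh.write(f"#{line}\n")
        fh.write(_BED_HEADER + "\n")
        for i, c in enumerate(calls, 1):
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\tsilencer_{i}\t"
                f"{bed_score(c.adjusted_p)}\t.\t"
                f"{c.window_p:.6g}\t{c.adjusted_p:.6g}\t"
                f"{c.similarity_score:.6g}\t{c.strength_ratio:.6g}\n"
            )


def load_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (contig, start, end) triples from a BED-like file, skipping headers."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
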