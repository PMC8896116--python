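"""Per-nucleotide depletion p-values from the negative-binomial CDF.

The test asks how surprising the reporter-cDNA depth at a nucleotide is,
given the input-insert depth, when reporter fragment placement is modelled
as a negative-binomial process. With m = treatCount, n = treatTotal −
treatCount and single-success probability p = (controlTotal − controlCount)
/ controlTotal, the site p-value is

    P(X <= m) = sum_{i=0..m} C(i+n-1, n-1) p^n (1-p)^i,

the CDF of the failures-before-nth-success negative binomial. Small values
mean the reporter library is depleted at the site relative to the insert
library — the silencer signature. Evaluation uses the regularized
incomplete-beta identity I_p(n, m+1), which is stable for n up to library
size (~1e9); literal term summation is only ever an oracle at small n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .coverage_io import CoverageTrack

__all__ = [
    "PValueTrack",
    "nb_cdf",
    "site_pvalue",
    "pvalue_track",
    "prescreen_mask",
    "bh_adjust",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class PValueTrack:
    """Per-base p-values aligned 1:1 with the coverage tracks they came from."""

    contig: str
    origin: int
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pvalues, dtype=np.float64)
        object.__setattr__(self, "pvalues", p)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pvalues)


def nb_cdf(m: int, n: int, p: float) -> float:
    """P(X <= m) for X ~ NegBin(n, p) counting failures before the nth success.

    Computed as the regularized incomplete beta I_p(n, m+1), exactly the
    printed-summation CDF with the i = m term included.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must satisfy 0 < p <= 1")
    return float(special.betainc(n, m + 1, p))


def site_pvalue(
    treat_count: int, control_count: int, treat_total: int, control_total: int
) -> float:
    """Depletion p-value at one nucleotide; small = reporter cDNA depleted."""
    if treat_total <= 0 or control_total <= 0:
        raise ValueError("library totals must be positive")
    if treat_count > treat_total or control_count > control_total:
        raise ValueError("per-site count exceeds library total")
    if control_count == control_total:
        # success probability 0: degenerate parameterization, cannot support
        # a depletion claim; callers treat the site as undefined
        raise ValueError("undefined site: control coverage equals control total")
    p = (control_total - control_count) / control_total
    return nb_cdf(treat_count, treat_total - treat_count, p)


def pvalue_track(
    treat: CoverageTrack,
    control: CoverageTrack,
    treat_total: int,
    control_total: int,
) -> PValueTrack:
    """Element-wise :func:`site_pvalue` over aligned coverage tracks.

    Undefined sites (control coverage equal to the control total, or treat
    coverage equal to the treat total) are recorded as 1.0 so they are never
    called.
    """
    _check_aligned(treat, control)
    if treat_total <= 0 or control_total <= 0:
        raise ValueError("library totals must be positive")
    m = treat.values.astype(np.float64)
    n = treat_total - m
    p = (control_total - control.values) / control_total
    out = np.ones(len(m), dtype=np.float64)
    ok = (n >= 1) & (p > 0)
    out[ok] = special.betainc(n[ok], m[ok] + 1.0, p[ok])
    return PValueTrack(contig=treat.contig, origin=treat.origin, pvalues=out)


def prescreen_mask(
    treat: CoverageTrack, control: CoverageTrack, min_diff: int = 12
) -> np.ndarray:
    """Boolean mask of sites where control − treat depth >= ``min_diff``.

    The default of 12 is the count difference that pairs with the 1e-5
    per-site p-value threshold at typical STARR-seq depths; it is a fixed
    screen, not derived from library totals.
    """
    _check_aligned(treat, control)
    return (control.values - treat.values) >= min_diff


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = _validated(pvalues)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=np.float64)
    out[order] = adj
    return out


def bonferroni_adjust(pvalues) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p*N) element-wise."""
    p = _validated(pvalues)
    return np.minimum(p * len(p), 1.0)


def _validated(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _check_aligned(a: CoverageTrack, b: CoverageTrack) -> None:
    if a.contig != b.contig or a.origin != b.origin or len(a) != len(b):
        raise ValueError(
            f"misaligned tracks: ({a.contig},{a.origin},{len(a)}) vs "
            f"({b.contig},{b.origin},{len(b)})"
        )
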