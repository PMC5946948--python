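"""Spearman correlation between gene density and GC content.

Genome-wide, the two window tracks are correlated directly.  The regional
scan divides each chromosome into overlapping regions: a region collects 31
consecutive windows of the standard 1-Mb/100-kb track (window starts
spanning 3 Mb, hence a 4-Mb sequence footprint) and computes Spearman's rho
within it.  Regions with rho > 0.95 and p < 0.01 are flagged as
high-correlation; regions with rho < 0.7 as low-correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .windows import WindowTrack

__all__ = [
    "CorrelationResult",
    "RegionalCorrelation",
    "ScanThresholds",
    "spearman",
    "regional_scan",
    "flag_summary",
    "scan_to_tsv",
    "high_regions_to_bed",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float  # NaN when undefined (constant input)
    p_value: float
    n_pairs: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclass(frozen=True)
class ScanThresholds:
    high_rho: float = 0.95
    high_p: float = 0.01
    low_rho: float = 0.7


@dataclass(frozen=True)
class RegionalCorrelation:
    chrom: str
    region_start: int  # bp, 1-based
    region_end: int  # bp, inclusive; footprint = last window end
    result: CorrelationResult
    high_flag: bool
    low_flag: bool


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties and a two-sided
    asymptotic p-value.  Pairs with a NaN in either vector are dropped first
    (all-N GC windows carry NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n_pairs=n)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n_pairs=n)


def regional_scan(
    track: WindowTrack,
    region_span: int = 3_000_000,
    region_step: int = 100_000,
    thresholds: ScanThresholds = ScanThresholds(),
) -> list[RegionalCorrelation]:
    """Sliding regional correlation between gene counts and GC.

    ``region_span`` is the range the member window *starts* cover (3 Mb at
    defaults); with 1-Mb windows the region's sequence footprint is 4 Mb.
    Regions advance by ``region_step``.  Regions whose correlation is
    undefined (constant input after NaN removal) carry no flags.
    """
    if track.gene_counts is None or track.gc_fractions is None:
        raise ValueError("track needs both gene counts and GC fractions")
    step = track.spec.step
    if region_span % step or region_step % step:
        raise ValueError("region_span and region_step must be multiples of the track step")
    per_region = region_span // step + 1  # 31 windows at defaults
    n_win = len(track)
    out: list[RegionalCorrelation] = []
    if n_win < per_region:
        return out
    stride = region_step // step
    for j0 in range(0, n_win - per_region + 1, stride):
        sl = slice(j0, j0 + per_region)
        counts = np.asarray(track.gene_counts[sl], dtype=float)
        gc = np.asarray(track.gc_fractions[sl], dtype=float)
        keep = ~np.isnan(gc)
        if keep.sum() < 3 or len(set(counts[keep])) < 2 or len(set(gc[keep])) < 2:
            res = CorrelationResult(float("nan"), float("nan"), int(keep.sum()))
        else:
            res = spearman(counts, gc)
        high = res.defined and res.rho > thresholds.high_rho and res.p_value < thresholds.high_p
        low = res.defined and res.rho < thresholds.low_rho
        out.append(
            RegionalCorrelation(
                chrom=track.seq_id,
                region_start=int(track.starts[j0]),
                region_end=int(track.starts[j0 + per_region - 1])
                + track.spec.window_size
                - 1,
                result=res,
                high_flag=high,
                low_flag=low,
            )
        )
    return out


def flag_summary(scan: list[RegionalCorrelation]) -> dict[str, float | int]:
    """Fractions (and counts) of high- and low-correlation regions."""
    if not scan:
        raise ValueError("empty scan: flag fractions undefined")
    n = len(scan)
    n_high = sum(r.high_flag for r in scan)
    n_low = sum(r.low_flag for r in scan)
    return {
        "n_regions": n,
        "n_high": n_high,
        "n_low": n_low,
        "frac_high": n_high / n,
        "frac_low": n_low / n,
    }


def scan_to_tsv(scan: list[RegionalCorrelation]) -> str:
    lines = ["chrom\tregion_start\tregion_end\trho\tp\thigh_flag\tlow_flag"]
    for r in scan:
        rho = "" if not r.result.defined else f"{r.result.rho:.6f}"
        p = "" if not r.result.defined else f"{r.result.p_value:.3e}"
        lines.append(
            f"{r.chrom}\t{r.region_start}\t{r.region_end}\t{rho}\t{p}\t"
            f"{int(r.high_flag)}\t{int(r.low_flag)}"
        )
    return "\n".join(lines) + "\n"


def high_regions_to_bed(scan: list[RegionalCorrelation]) -> str:
    lines = [
        f"{r.chrom}\t{r.region_start - 1}\t{r.region_end}\thighcorr\t0"
        for r in scan
        if r.high_flag
    ]
    return "\n".join(lines) + ("\n" if lines else "")
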