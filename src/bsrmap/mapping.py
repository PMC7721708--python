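"""Euclidean-distance association mapping between two extreme-phenotype pools.

At each filtered SNP the two pools' reads are converted to base-frequency
vectors over (A, C, G, T) and compared by Euclidean distance

    ED = sqrt((A_RP - A_SP)^2 + (C_RP - C_SP)^2 + (G_RP - G_SP)^2 + (T_RP - T_SP)^2)

Frequencies, not raw depths, enter the formula so that unequal sequencing
yield between the pools does not bias the statistic. ED ranges from 0
(identical pools) to sqrt(2) (pools fixed for different bases). Raising ED to
the fifth power suppresses background noise relative to true signal; the
powered values are then smoothed within chromosomes by a sliding median over
the 50 SNPs up- and downstream of each site, and the genome-wide
median + 3*SD of the smoothed profile is the significance threshold.
Maximal runs of above-threshold sites become candidate mapping intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .filtering import BASES, SampleRoles, SnpRecord, _check_sorted

DEFAULT_POWER = 5
DEFAULT_FLANK = 50


class DegenerateInputError(ValueError):
    """Too few sites to compute a spread-based threshold."""


@dataclass
class EdPoint:
    """Per-site association statistic and its smoothed value."""

    chrom: str
    pos: int  # 1-based
    freq_rp: np.ndarray = field(repr=False)
    freq_sp: np.ndarray = field(repr=False)
    ed: float = 0.0
    ed_pow: float = 0.0
    fitted: float = float("nan")


@dataclass
class Interval:
    """A candidate mapping interval (1-based inclusive coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_fitted: float


@dataclass
class AssociationResult:
    points: list[EdPoint]
    threshold: float
    intervals: list[Interval]


def base_frequencies(record: SnpRecord, pool: str) -> np.ndarray:
    """Base-frequency vector over (A, C, G, T) for one pool at one site."""
    depths = np.array([record.depth_by_base[pool][b] for b in BASES], dtype=float)
    total = depths.sum()
    if total == 0:
        raise ZeroDivisionError(
            f"zero depth for {pool} at {record.chrom}:{record.pos}; "
            "apply the min-support filter first"
        )
    return depths / total


def euclidean_distance(freq_rp: np.ndarray, freq_sp: np.ndarray) -> float:
    """ED between two length-4 base-frequency vectors."""
    d = np.asarray(freq_rp, dtype=float) - np.asarray(freq_sp, dtype=float)
    return float(np.sqrt((d * d).sum()))


def power_transform(ed: float, power: float = DEFAULT_POWER) -> float:
    """Raise ED to the noise-suppressing power (default 5)."""
    return float(ed) ** power


def compute_ed_points(
    records: Sequence[SnpRecord], roles: SampleRoles, power: float = DEFAULT_POWER
) -> list[EdPoint]:
    """Compute per-site ED and powered ED for sorted records."""
    _check_sorted(records)
    points = []
    for r in records:
        f_rp = base_frequencies(r, roles.restorer_pool)
        f_sp = base_frequencies(r, roles.sterile_pool)
        ed = euclidean_distance(f_rp, f_sp)
        points.append(
            EdPoint(
                chrom=r.chrom,
                pos=r.pos,
                freq_rp=f_rp,
                freq_sp=f_sp,
                ed=ed,
                ed_pow=power_transform(ed, power),
            )
        )
    return points


def sliding_median_fit(points: Sequence[EdPoint], flank: int = DEFAULT_FLANK) -> list[EdPoint]:
    """Set each point's fitted value to the median powered ED in its window.

    The window holds up to ``flank`` SNPs upstream, the focal SNP itself, and
    up to ``flank`` SNPs downstream on the same chromosome; it is truncated,
    not padded, at chromosome ends. Points must be sorted by (chrom, pos).
    """
    _check_sorted(points)
    df = pd.DataFrame(
        {"chrom": [p.chrom for p in points], "ed_pow": [p.ed_pow for p in points]}
    )
    fitted = (
        df.groupby("chrom", sort=False)["ed_pow"]
        .transform(
            lambda s: s.rolling(2 * flank + 1, center=True, min_periods=1).median()
        )
        .to_numpy()
    )
    for p, f in zip(points, fitted):
        p.fitted = float(f)
    return list(points)


def compute_threshold(points: Sequence[EdPoint], sd_ddof: int = 1) -> float:
    """Significance threshold: genome-wide median + 3*SD of fitted values.

    The standard deviation uses the sample convention (``sd_ddof=1``) by
    default; pass ``sd_ddof=0`` for the population convention.
    """
    fitted = np.array([p.fitted for p in points], dtype=float)
    if fitted.size < 2:
        raise DegenerateInputError("need at least 2 fitted points for a threshold")
    return float(np.median(fitted) + 3.0 * np.std(fitted, ddof=sd_ddof))


def call_intervals(
    points: Sequence[EdPoint], threshold: float, gap_snps: int = 0
) -> list[Interval]:
    """Call candidate intervals as maximal runs of sites with fitted > threshold.

    Runs on the same chromosome separated by at most ``gap_snps``
    below-threshold sites are merged (default: no merging). Intervals span
    the first to last member site and are returned sorted by peak fitted
    value descending; ties break by interval length (longer first), then by
    (chrom, start).
    """
    intervals: list[Interval] = []
    run: list[EdPoint] = []
    gap = 0
    prev_chrom = None

    def close() -> None:
        while run and run[-1].fitted <= threshold:
            run.pop()
        if run:
            above = [p for p in run if p.fitted > threshold]
            intervals.append(
                Interval(
                    chrom=run[0].chrom,
                    start_bp=run[0].pos,
                    end_bp=run[-1].pos,
                    n_snps=len(above),
                    peak_fitted=max(p.fitted for p in above),
                )
            )

    for p in points:
        if p.chrom != prev_chrom:
            close()
            run, gap, prev_chrom = [], 0, p.chrom
        if p.fitted > threshold:
            run.append(p)
            gap = 0
        elif run:
            gap += 1
            if gap > gap_snps:
                close()
                run, gap = [], 0
            else:
                run.append(p)
    close()
    intervals.sort(
        key=lambda iv: (
            -iv.peak_fitted,
            -(iv.end_bp - iv.start_bp),
            iv.chrom,
            iv.start_bp,
        )
    )
    return intervals


def interval_width_mbp(interval: Interval) -> float:
    """Interval width in Mbp, reported to one decimal."""
    return round((interval.end_bp - interval.start_bp) / 1e6, 1)


def associate(
    records: Sequence[SnpRecord],
    roles: SampleRoles,
    power: float = DEFAULT_POWER,
    flank: int = DEFAULT_FLANK,
    sd_ddof: int = 1,
    gap_snps: int = 0,
) -> AssociationResult:
    """Run the full association scan: ED -> ED^power -> median fit ->
    threshold -> interval calling."""
    points = compute_ed_points(records, roles, power)
    sliding_median_fit(points, flank)
    threshold = compute_threshold(points, sd_ddof)
    intervals = call_intervals(points, threshold, gap_snps)
    return AssociationResult(points=points, threshold=threshold, intervals=intervals)


def write_association(result: AssociationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-site profile (TSV), intervals (BED + 1-based TSV) and a
    JSON summary with the threshold."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "ed_profile.tsv",
        "bed": out / "intervals.bed",
        "intervals": out / "intervals.tsv",
        "summary": out / "association.json",
    }
    pd.DataFrame(
        {
            "chrom": [p.chrom for p in result.points],
            "pos": [p.pos for p in result.points],
            "ed": [p.ed for p in result.points],
            "ed_pow": [p.ed_pow for p in result.points],
            "fitted": [p.fitted for p in result.points],
        }
    ).to_csv(paths["sites"], sep="\t", index=False)
    with open(paths["bed"], "w") as fh:
        for iv in result.intervals:
            # BED is 0-based half-open on disk
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.peak_fitted:g}\n")
    pd.DataFrame(
        [
            {
                "chrom": iv.chrom,
                "start_bp": iv.start_bp,
                "end_bp": iv.end_bp,
                "n_snps": iv.n_snps,
                "peak_fitted": iv.peak_fitted,
                "width_mbp": interval_width_mbp(iv),
            }
            for iv in result.intervals
        ],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "peak_fitted", "width_mbp"],
    ).to_csv(paths["intervals"], sep="\t", index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(
            {
                "threshold": result.threshold,
                "n_sites": len(result.points),
                "n_intervals": len(result.intervals),
            },
            fh,
            indent=2,
        )
    return paths


def plot_profile(result: AssociationResult, path: str | Path) -> None:
    """Manhattan-style plot of the fitted profile per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(p.chrom for p in result.points))
    fig, axes = plt.subplots(
        1, max(len(chroms), 1), figsize=(4 * max(len(chroms), 1), 3), sharey=True
    )
    if len(chroms) <= 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        xs = [p.pos / 1e6 for p in result.points if p.chrom == chrom]
        ys = [p.fitted for p in result.points if p.chrom == chrom]
        ax.plot(xs, ys, ".", ms=2)
        ax.axhline(result.threshold, color="hotpink", ls="--", lw=1)
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
    axes[0].set_ylabel("fitted ED$^5$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
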