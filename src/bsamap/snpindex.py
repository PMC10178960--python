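"""SNP-index statistics and the sliding-window genome scan.

The SNP-index of a bulk at a SNP is the fraction of its reads carrying the
maternal (mutant-parent) allele: 0 means every read came from the paternal
parent, 1 means every read came from the maternal parent.  Delta(SNP-index)
is the mutant-bulk index minus the normal-bulk index; near a recessive
causal locus it is expected to approach 1 - 1/3 = 2/3, since the mutant
bulk is fixed for the maternal allele while phenotypically normal plants
segregate 1 homozygous-wild : 2 heterozygous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import BULKS, RECORD_COLUMNS, WINDOW_COLUMNS, VariantSite


@dataclass
class ScanConfig:
    """Screening and scan parameters.

    window_size / step define the sliding-window grid (default 1 Mb windows
    advanced by 10 kb); min_depth is the per-bulk per-site read-depth floor;
    parental_ratio is the purity each parental bulk must show for its own
    allele for a SNP to count as parent-distinguishing.
    """

    window_size: int = 1_000_000
    step: int = 10_000
    min_depth: int = 7
    min_snps_per_window: int = 1
    parental_ratio: float = 0.8

    def __post_init__(self) -> None:
        if not self.window_size >= self.step > 0:
            raise ValueError("require window_size >= step > 0")
        if not 0.5 < self.parental_ratio <= 1.0:
            raise ValueError("parental_ratio must lie in (0.5, 1]")


def snp_index(maternal_reads: int, paternal_reads: int) -> float:
    """Maternal-allele read fraction; NaN when total depth is zero."""
    if maternal_reads < 0 or paternal_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = maternal_reads + paternal_reads
    if total == 0:
        return math.nan
    return maternal_reads / total


def delta_snp_index(index_o: float, index_n: float) -> float:
    """Mutant-bulk minus normal-bulk SNP-index; NaN if either is missing."""
    if math.isnan(index_o) or math.isnan(index_n):
        return math.nan
    return index_o - index_n


def screen_parental_snps(
    sites: Sequence[VariantSite], config: ScanConfig
) -> list[VariantSite]:
    """Keep sites that distinguish the parents and are covered in all bulks.

    A site survives iff (a) the maternal bulk's maternal-allele fraction is
    >= parental_ratio and the paternal bulk's is <= 1 - parental_ratio;
    (b) every bulk meets min_depth; (c) all four bulks carry the site
    (intersection of the parental-unique SNPs with both progeny bulks).
    """
    kept: list[VariantSite] = []
    for site in sites:
        if not site.complete:
            continue
        if any(site.depth(b) < config.min_depth for b in BULKS):
            continue
        f_mo = site.alt_fraction("MO")
        f_pn = site.alt_fraction("PN")
        if f_mo is None or f_pn is None:
            continue
        if f_mo >= config.parental_ratio and f_pn <= 1.0 - config.parental_ratio:
            kept.append(site)
    return kept


def compute_records(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Per-SNP indices for all four bulks plus delta, as a tidy table.

    Columns: chrom, pos, ref, alt, index_{MO,PN,O,N}, delta,
    depth_{MO,PN,O,N}.  Indices at zero depth are NaN, and delta is NaN
    whenever either progeny index is.
    """
    rows = []
    for s in sites:
        row: dict = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
        for b in BULKS:
            r, a = s.counts.get(b, (0, 0))
            row[f"index_{b}"] = snp_index(a, r)
            row[f"depth_{b}"] = r + a
        row["delta"] = delta_snp_index(row["index_O"], row["index_N"])
        rows.append(row)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def window_grid(chrom_length: int, config: ScanConfig) -> np.ndarray:
    """Window start positions for one chromosome: 1, 1+step, 1+2*step, ..."""
    return np.arange(1, chrom_length + 1, config.step, dtype=np.int64)


def sliding_window_scan(
    records: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    config: ScanConfig,
) -> pd.DataFrame:
    """Average SNP-index and delta over a sliding window along each chromosome.

    A SNP at position p belongs to the window [start, start + window_size - 1]
    iff start <= p <= start + window_size - 1 (1-based inclusive).  Window
    means are unweighted arithmetic means over the member SNPs' non-missing
    values; windows holding fewer than min_snps_per_window SNPs get NaN
    means.  Trailing windows are truncated at the chromosome end.

    Raises ``ValueError`` on input not sorted by (chrom, pos).
    """
    sorted_ok = (
        records[["chrom", "pos"]]
        .reset_index(drop=True)
        .equals(
            records[["chrom", "pos"]]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
    )
    if not sorted_ok:
        raise ValueError("records must be sorted by (chrom, pos)")

    out = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        sub = records[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        starts = window_grid(length, config)
        ends = np.minimum(starts + config.window_size - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        for col_in, col_out in (
            ("index_O", "mean_index_O"),
            ("index_N", "mean_index_N"),
            ("delta", "mean_delta"),
        ):
            vals = sub[col_in].to_numpy(dtype=float)
            csum = np.concatenate([[0.0], np.nancumsum(vals)])
            cnum = np.concatenate([[0], np.cumsum(~np.isnan(vals))])
            num = cnum[hi] - cnum[lo]
            tot = csum[hi] - csum[lo]
            if col_in == "index_O":
                n_snps = hi - lo
                frame = pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "n_snps": n_snps}
                )
            with np.errstate(invalid="ignore"):
                mean = np.where(num > 0, tot / np.maximum(num, 1), np.nan)
            frame[col_out] = mean
        frame.loc[frame["n_snps"] < config.min_snps_per_window,
                  ["mean_index_O", "mean_index_N", "mean_delta"]] = np.nan
        out.append(frame)
    return pd.concat(out, ignore_index=True)[WINDOW_COLUMNS]


def extract_candidate_interval(
    windows: pd.DataFrame,
    band: pd.DataFrame,
    level: int = 99,
) -> list[tuple[str, int, int]]:
    """Genomic intervals where the window-mean delta clears the null band.

    Maximal runs of consecutive (on the window grid) non-missing windows
    whose mean_delta exceeds the band's upper quantile at ``level`` (95 or
    99) are merged; each run is reported as the union span (min start, max
    end) in bp.  The window and band tables must share the same
    (chrom, start) grid.
    """
    if level not in (95, 99):
        raise ValueError("level must be 95 or 99")
    upper_col = f"upper{level}"
    merged = windows.merge(band[["chrom", "start", upper_col]], on=["chrom", "start"], how="left")
    if len(merged) != len(windows):
        raise ValueError("window grid and band grid do not align")
    if merged[upper_col].isna().all() and not band.empty:
        raise ValueError("window grid and band grid do not align")
    intervals: list[tuple[str, int, int]] = []
    for chrom, sub in merged.groupby("chrom", sort=False):
        supra = (
            sub["mean_delta"].notna()
            & sub[upper_col].notna()
            & (sub["mean_delta"] > sub[upper_col])
        ).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(supra):
            if supra[i]:
                j = i
                while j + 1 < len(supra) and supra[j + 1]:
                    j += 1
                intervals.append((chrom, int(starts[i]), int(ends[j])))
                i = j + 1
            else:
                i += 1
    return intervals


def format_interval_mb(interval: tuple[str, int, int]) -> str:
    """Human-readable interval rounded to 0.01 Mb, e.g. 'chr3:5.26-7.41 Mb'."""
    chrom, start, end = interval
    return f"{chrom}:{start / 1e6:.2f}-{end / 1e6:.2f} Mb"
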