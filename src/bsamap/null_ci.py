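"""Monte-Carlo confidence bands for delta(SNP-index) under the null.

Under the null hypothesis of no causal gene, both progeny bulks are random
draws from the same F2 population, so any non-zero delta(SNP-index) is
sampling noise from two stacked stages: (1) which plants entered each bulk
(each F2 plant carries maternal-allele dosage ~ Binomial(2, 1/2)) and
(2) which reads were sampled at each site (reads ~ Binomial(depth, bulk
allele frequency)).

At a single site the null delta is simulated exactly from those two stages
(:func:`simulate_null_site`).  For window-level bands the genotype stage is
correlated along the chromosome — member SNPs of a window are carried by
the same plants and are genetically linked, with dosage correlation
exp(-2d) at genetic distance d Morgans under the Haldane model — so
:func:`build_band` models the bulk-frequency fluctuation as a stationary
Gaussian Markov process with exactly that covariance, then layers
independent per-site binomial read sampling with the observed depths.
Ignoring the linkage correlation (``recomb_rate=None``) reproduces the
naive independent-site band, which is markedly anticonservative for
window means and is kept only for comparison.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .snpindex import ScanConfig, window_grid
from .variant_io import BAND_COLUMNS

logger = logging.getLogger(__name__)


def simulate_null_delta(
    bulk_size_o: int,
    bulk_size_n: int,
    depth_o: np.ndarray | int,
    depth_n: np.ndarray | int,
    rng: np.random.Generator,
    size: int | tuple[int, ...] | None = None,
) -> np.ndarray | float:
    """Draw null delta(SNP-index) values at a single site.

    Per bulk: the summed maternal dosage over n plants is
    Binomial(2n, 1/2) (the sum of n independent Binomial(2, 1/2) plant
    dosages), giving the bulk allele frequency f; reads are then
    Binomial(depth, f) and the index is reads/depth.  Returns
    index_O - index_N with shape ``size`` (scalar draw if None).
    Depths of zero yield NaN.
    """
    if bulk_size_o < 1 or bulk_size_n < 1:
        raise ValueError("bulk sizes must be >= 1")
    shape = size if size is not None else ()
    d_o = np.broadcast_to(np.asarray(depth_o), shape).astype(np.int64)
    d_n = np.broadcast_to(np.asarray(depth_n), shape).astype(np.int64)

    def one_bulk(n_plants: int, depth: np.ndarray) -> np.ndarray:
        f = rng.binomial(2 * n_plants, 0.5, size=shape) / (2.0 * n_plants)
        reads = rng.binomial(depth, f)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(depth > 0, reads / np.maximum(depth, 1), np.nan)

    delta = one_bulk(bulk_size_o, d_o) - one_bulk(bulk_size_n, d_n)
    return delta if size is not None else float(delta)


def simulate_null_site(
    bulk_size_o: int,
    bulk_size_n: int,
    depth_o: int,
    depth_n: int,
    rng: np.random.Generator,
) -> float:
    """One null delta draw for a single site (scalar convenience form)."""
    return simulate_null_delta(bulk_size_o, bulk_size_n, depth_o, depth_n, rng)


def null_delta_sd(bulk_size: int, depth: float) -> float:
    """Analytic null SD of the single-site delta for equal bulk sizes/depths.

    Per bulk, Var(index) = Var(f) + E[f(1-f)]/depth with Var(f) = 1/(8n)
    and E[f(1-f)] = 1/4 - 1/(8n); delta doubles it.  Serves as a
    closed-form cross-check of the Monte-Carlo machinery.
    """
    var_f = 1.0 / (8.0 * bulk_size)
    e_f1f = 0.25 - var_f
    var_index = var_f + e_f1f / depth
    return float(np.sqrt(2.0 * var_index))


def _null_genotype_freqs(
    pos: np.ndarray,
    n_sims: int,
    sigma_g: float,
    recomb_rate: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null bulk allele-frequency draws (n_sims x n_snps) around 1/2.

    With ``recomb_rate`` set, frequencies follow a stationary Gaussian
    Markov process whose correlation between sites at genetic distance d
    Morgans is exp(-2d) — the exact dosage autocorrelation of an F2
    chromosome under Haldane recombination.  With ``recomb_rate=None``
    sites are independent.
    """
    n_snps = len(pos)
    g = np.empty((n_sims, n_snps))
    g[:, 0] = rng.normal(0.0, sigma_g, size=n_sims)
    if recomb_rate is None:
        if n_snps > 1:
            g[:, 1:] = rng.normal(0.0, sigma_g, size=(n_sims, n_snps - 1))
    else:
        d_morgans = np.diff(pos) * recomb_rate / 1e8
        rho = np.exp(-2.0 * d_morgans)
        innov_sd = sigma_g * np.sqrt(1.0 - rho**2)
        for j in range(1, n_snps):
            g[:, j] = rho[j - 1] * g[:, j - 1] + rng.normal(
                0.0, innov_sd[j - 1], size=n_sims
            )
    return np.clip(0.5 + g, 0.0, 1.0)


def build_band(
    records: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    config: ScanConfig,
    bulk_size: int = 152,
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
    recomb_rate: float | None = 4.0,
    n_population: int | None = None,
) -> pd.DataFrame:
    """Null 95%/99% bands of the window-mean delta, per window.

    For each replicate, a null genome of per-SNP deltas is simulated at the
    observed O- and N-bulk depths (genotype stage correlated along the
    chromosome per the Haldane model at ``recomb_rate`` cM/Mb, read stage
    independent per site) and replicate window means are computed exactly
    as in the observed scan (unweighted mean over member SNPs).  The band
    is the empirical 2.5/97.5 and 0.5/99.5 percentile envelope over
    replicates (linear interpolation between order statistics); windows
    with no SNPs get a missing band.

    ``n_population`` is the total F2 population the two disjoint bulks were
    drawn from; when given, the genotype variance carries the
    finite-population correction (N - n)/(N - 1).  None means an
    effectively infinite population.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_sims < 1_000:
        logger.warning("n_sims=%d < 1000: tail quantiles will be unstable", n_sims)
    var_f = 1.0 / (8.0 * bulk_size)
    if n_population is not None:
        if n_population < 2 * bulk_size:
            raise ValueError("n_population must hold two disjoint bulks")
        var_f *= (n_population - bulk_size) / (n_population - 1)
    sigma_g = float(np.sqrt(var_f))

    out = []
    for chrom in chrom_lengths:
        sub = records[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        starts = window_grid(chrom_lengths[chrom], config)
        ends = np.minimum(starts + config.window_size - 1, chrom_lengths[chrom])
        n_win = len(starts)
        quants = np.full((4, n_win), np.nan)
        if len(pos) > 0:
            deltas = np.empty((n_sims, len(pos)))
            depth = {
                "O": sub["depth_O"].to_numpy(dtype=np.int64),
                "N": sub["depth_N"].to_numpy(dtype=np.int64),
            }
            index = {}
            for b in ("O", "N"):
                f = _null_genotype_freqs(pos, n_sims, sigma_g, recomb_rate, rng)
                reads = rng.binomial(depth[b][None, :], f)
                with np.errstate(invalid="ignore", divide="ignore"):
                    index[b] = np.where(
                        depth[b][None, :] > 0,
                        reads / np.maximum(depth[b][None, :], 1),
                        np.nan,
                    )
            deltas = index["O"] - index["N"]
            csum = np.concatenate(
                [np.zeros((n_sims, 1)), np.nancumsum(deltas, axis=1)], axis=1
            )
            cnum = np.concatenate(
                [np.zeros((n_sims, 1), dtype=np.int64),
                 np.cumsum(~np.isnan(deltas), axis=1)], axis=1
            )
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, ends, side="right")
            for w in range(n_win):
                if hi[w] <= lo[w]:
                    continue
                num = cnum[:, hi[w]] - cnum[:, lo[w]]
                tot = csum[:, hi[w]] - csum[:, lo[w]]
                means = tot[num > 0] / num[num > 0]
                if len(means) == 0:
                    continue
                quants[:, w] = np.quantile(means, [0.005, 0.025, 0.975, 0.995])
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "lower99": quants[0],
                    "lower95": quants[1],
                    "upper95": quants[2],
                    "upper99": quants[3],
                    "n_sims": n_sims,
                }
            )
        )
    return pd.concat(out, ignore_index=True)[BAND_COLUMNS]
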