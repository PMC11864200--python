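"""Spatial-vs-genomic distance scaling statistics.

Chromatin behaves like a polymer: the median 3D distance between two loci on
the same chromosome homolog grows as a power law of their genomic separation,
``d(g) ~ g**S``.  Neuronal chromatin shows two regimes with a crossover near
10 Mb, so power-law exponents are fitted separately below and above a
configurable genomic boundary (boundary pairs go to the long regime).
Log-log fits weight each locus pair equally.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_core import locus_midpoints


@dataclasses.dataclass
class ScalingFit:
    """Two-regime power-law fit of median spatial vs genomic distance."""

    s_short: float | None
    s_long: float | None
    intercept_short: float | None
    intercept_long: float | None
    boundary_bp: float
    r2: float | None                    # of the full-range order-2 log-log fit
    n_pairs_short: int
    n_pairs_long: int
    poly_coeffs: np.ndarray | None      # order-2 polynomial, log-log


def pairwise_distance_table(traces: pd.DataFrame, panel: pd.DataFrame,
                            cell_type: str | None = None,
                            min_cells: int = 20,
                            per_chrom: bool = False) -> pd.DataFrame:
    """Median cis spatial distance per locus pair.

    Pairs are cis-chromosomal within a single homolog copy; the median is
    taken over all (cell, homolog) copies with both loci decoded, and pairs
    observed in fewer than ``min_cells`` copies are dropped.

    Returns columns locus_i, locus_j, chrom, genomic_dist, median_spatial_dist,
    n_obs.
    """
    sub = traces if cell_type is None else traces[traces["cell_type"] == cell_type]
    mids = locus_midpoints(panel)
    panel_by_chrom = {c: g["locus_id"].tolist()
                      for c, g in panel.groupby("chrom", sort=False)}
    rows = []
    for chrom, loci in panel_by_chrom.items():
        chrom_tr = sub[sub["chrom"] == chrom]
        if chrom_tr.empty:
            continue
        index = {lid: i for i, lid in enumerate(loci)}
        n = len(loci)
        copies = []
        for (_, _), copy in chrom_tr.groupby(["cell_id", "homolog"], sort=False):
            coords = np.full((n, 3), np.nan)
            coords[[index[l] for l in copy["locus_id"]]] = \
                copy[["x", "y", "z"]].to_numpy(float)
            copies.append(coords)
        stack = np.stack(copies)                       # (n_copies, n, 3)
        diff = stack[:, :, None, :] - stack[:, None, :, :]
        dists = np.sqrt((diff ** 2).sum(axis=-1))      # (n_copies, n, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
            med = np.nanmedian(dists, axis=0)
        n_obs = np.isfinite(dists).sum(axis=0)
        gmids = mids[loci].to_numpy()
        iu, ju = np.triu_indices(n, k=1)
        ok = n_obs[iu, ju] >= min_cells
        for i, j in zip(iu[ok], ju[ok]):
            rows.append((loci[i], loci[j], chrom, abs(gmids[j] - gmids[i]),
                         med[i, j], int(n_obs[i, j])))
    return pd.DataFrame(rows, columns=["locus_i", "locus_j", "chrom",
                                       "genomic_dist", "median_spatial_dist",
                                       "n_obs"])


def fit_scaling(table: pd.DataFrame, boundary: float = 10_000_000.0) -> ScalingFit:
    """Fit power-law exponents below and above the genomic-distance boundary.

    Least-squares lines of log(median distance) on log(genomic distance) per
    regime (each pair weighted equally); a regime with fewer than three
    distinct genomic distances yields a null exponent.  An order-2 polynomial
    over the full log-log range is stored for curve plotting, together with
    its R².
    """
    if table.empty:
        raise ValueError("empty pair table")
    g = table["genomic_dist"].to_numpy(float)
    d = table["median_spatial_dist"].to_numpy(float)
    ok = (g > 0) & (d > 0) & np.isfinite(d)
    logg, logd = np.log10(g[ok]), np.log10(d[ok])
    short = g[ok] < boundary

    def _line(x, y):
        if len(np.unique(x)) < 3:
            return None, None, 0
        slope, intercept = np.polyfit(x, y, 1)
        return float(slope), float(intercept), len(x)

    s_short, b_short, n_short = _line(logg[short], logd[short])
    s_long, b_long, n_long = _line(logg[~short], logd[~short])
    poly, r2 = None, None
    if len(np.unique(logg)) >= 3:
        poly = np.polyfit(logg, logd, 2)
        resid = logd - np.polyval(poly, logg)
        ss_tot = ((logd - logd.mean()) ** 2).sum()
        r2 = float(1 - (resid ** 2).sum() / ss_tot) if ss_tot > 0 else 1.0
    return ScalingFit(s_short, s_long, b_short, b_long, boundary, r2,
                      n_short, n_long, poly)


def proximity_fractions(traces: pd.DataFrame, panel: pd.DataFrame,
                        cutoff: float = 0.75,
                        genomic_bins: tuple[float, ...] = (0, 10e6, 50e6, np.inf),
                        cell_type: str | None = None,
                        min_cells: int = 1) -> pd.Series:
    """Fraction of spatially proximal cis pairs per genomic-distance bin.

    Every observed proximal pair copy (spatial distance < ``cutoff`` µm)
    counts once; fractions are over all proximal observations, so they sum
    to 1 across the bins.  Raises when no pair is proximal at the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sub = traces if cell_type is None else traces[traces["cell_type"] == cell_type]
    mids = locus_midpoints(panel)
    counts = np.zeros(len(genomic_bins) - 1)
    for chrom, chrom_tr in sub.groupby("chrom", sort=False):
        for (_, _), copy in chrom_tr.groupby(["cell_id", "homolog"], sort=False):
            coords = copy[["x", "y", "z"]].to_numpy(float)
            gpos = mids[copy["locus_id"]].to_numpy()
            if len(coords) < 2:
                continue
            diff = coords[:, None, :] - coords[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=-1))
            iu, ju = np.triu_indices(len(coords), k=1)
            prox = dist[iu, ju] < cutoff
            gd = np.abs(gpos[iu] - gpos[ju])[prox]
            counts += np.histogram(gd, bins=genomic_bins)[0]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no proximal pairs at cutoff {cutoff} µm")
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(genomic_bins[:-1], genomic_bins[1:])]
    return pd.Series(counts / total, index=labels, name="fraction")


def scaling_by_activity(table: pd.DataFrame, locus_activity: pd.Series,
                        n_bins: int = 10,
                        boundary: float = 10_000_000.0) -> pd.DataFrame:
    """Per-activity-bin scaling fits.

    Pair activity is the mean of the two loci's activities; pairs are split
    into ``n_bins`` equal-count bins and fitted separately.  Returns one row
    per bin with the bin's mean activity and fitted exponents (null when a
    regime has fewer than three distinct genomic distances).
    """
    act = (locus_activity.reindex(table["locus_i"]).to_numpy()
           + locus_activity.reindex(table["locus_j"]).to_numpy()) / 2.0
    table = table.assign(pair_activity=act).dropna(subset=["pair_activity"])
    if n_bins == 1 or table["pair_activity"].nunique() == 1:
        bins = pd.Series(0, index=table.index)
    else:
        bins = pd.qcut(table["pair_activity"], q=n_bins, labels=False,
                       duplicates="drop")
    rows = []
    for b in sorted(bins.dropna().unique()):
        sub = table[bins == b]
        try:
            fit = fit_scaling(sub, boundary=boundary)
        except ValueError:
            fit = ScalingFit(None, None, None, None, boundary, None, 0, 0, None)
        rows.append((int(b), float(sub["pair_activity"].mean()), len(sub),
                     fit.s_short, fit.s_long))
    return pd.DataFrame(rows, columns=["bin", "mean_activity", "n_pairs",
                                       "s_short", "s_long"])


def activity_scaling_correlation(per_bin: pd.DataFrame,
                                 regime: str = "s_short") -> float:
    """Spearman correlation between bin activity and the fitted exponent."""
    sub = per_bin.dropna(subset=[regime])
    rho, _ = spearmanr(sub["mean_activity"], sub[regime])
    return float(rho)
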