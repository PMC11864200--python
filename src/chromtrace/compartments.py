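"""Matrix-level chromosome structure: compartments, insulation, megadomains.

A/B compartments are called per chromosome and cell type from single-cell
proximity frequencies: the observed contact fraction at a 0.75-µm cutoff is
normalized by the expected fraction at matched genomic distance (log-spaced
bins), a cross-correlation matrix is computed between the rows of this O/E
matrix, and the principal component (among the first three) that correlates
best with CpG density — a sequence covariate of active chromatin — defines
the compartment axis.  The first PC is *not* assumed to be the compartment
signal: in low-activity cell types it often reflects megadomains instead.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .io_core import locus_midpoints, log

OE_BINS_PER_DECADE = 20


@dataclasses.dataclass
class DistanceMatrix:
    chrom: str
    cell_type: str | None
    loci: list[str]
    median: np.ndarray       # n x n µm, NaN below min_cells
    counts: np.ndarray       # n x n observation counts


@dataclasses.dataclass
class CompartmentProfile:
    loci: list[str]
    pcs: np.ndarray          # (3, n) candidate PC values
    selected_pc: int         # 0-based index into pcs
    values: np.ndarray       # oriented values of the selected PC
    labels: np.ndarray       # 'A' / 'B' per locus
    cpg_corr: np.ndarray     # |corr with CpG| of each candidate PC


def _copy_stacks(traces: pd.DataFrame, panel: pd.DataFrame, chrom: str,
                 cell_type: str | None) -> tuple[list[str], np.ndarray]:
    """Stack (n_copies, n_loci, 3) coordinates for one chromosome, NaN-padded."""
    loci = panel.loc[panel["chrom"] == chrom, "locus_id"].tolist()
    if not loci:
        raise ValueError(f"chromosome {chrom!r} absent from panel")
    sub = traces[traces["chrom"] == chrom]
    if cell_type is not None:
        sub = sub[sub["cell_type"] == cell_type]
    if sub.empty:
        raise ValueError(f"no traces for chromosome {chrom!r}"
                         + (f" in cell type {cell_type!r}" if cell_type else ""))
    index = {lid: i for i, lid in enumerate(loci)}
    copies = []
    for (_, _), copy in sub.groupby(["cell_id", "homolog"], sort=False):
        coords = np.full((len(loci), 3), np.nan)
        coords[[index[l] for l in copy["locus_id"]]] = \
            copy[["x", "y", "z"]].to_numpy(float)
        copies.append(coords)
    return loci, np.stack(copies)


def _pairwise(stack: np.ndarray) -> np.ndarray:
    diff = stack[:, :, None, :] - stack[:, None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def median_distance_matrix(traces: pd.DataFrame, panel: pd.DataFrame, chrom: str,
                           cell_type: str | None = None,
                           min_cells: int = 20) -> DistanceMatrix:
    """Median pairwise spatial distance matrix over homolog copies.

    Entry (i, j) is the median over all copies with both loci decoded; NaN
    where fewer than ``min_cells`` observations, zero on the diagonal.
    """
    loci, stack = _copy_stacks(traces, panel, chrom, cell_type)
    dists = _pairwise(stack)
    counts = np.isfinite(dists).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        med = np.nanmedian(dists, axis=0)
    med[counts < min_cells] = np.nan
    np.fill_diagonal(med, 0.0)
    return DistanceMatrix(chrom, cell_type, loci, med, counts)


def _genomic_bin_ids(gdist: np.ndarray,
                     bins_per_decade: int = OE_BINS_PER_DECADE) -> np.ndarray:
    """Log-spaced genomic-distance bin index per entry (-1 on the diagonal)."""
    out = np.full(gdist.shape, -1, dtype=int)
    pos = gdist > 0
    out[pos] = np.floor(np.log10(gdist[pos]) * bins_per_decade).astype(int)
    return out


def normalized_proximity_matrix(traces: pd.DataFrame, panel: pd.DataFrame,
                                chrom: str, cell_type: str | None = None,
                                cutoff: float = 0.75, min_cells: int = 20,
                                bins_per_decade: int = OE_BINS_PER_DECADE,
                                ) -> tuple[list[str], np.ndarray]:
    """Observed/expected proximity frequency matrix for one chromosome.

    Observed(i, j) is the fraction of homolog copies (with both loci decoded)
    whose spatial distance is below ``cutoff``; the expectation is the mean
    observed value over all pairs in the same log-spaced genomic-distance bin
    (``bins_per_decade`` bins per decade).  Values near 1 mean no enrichment.
    A cutoff of infinity makes both observed and normalized identically 1.
    """
    loci, stack = _copy_stacks(traces, panel, chrom, cell_type)
    dists = _pairwise(stack)
    counts = np.isfinite(dists).sum(axis=0)
    with np.errstate(invalid="ignore"):
        observed = (dists < cutoff).sum(axis=0) / counts
    observed[counts < min_cells] = np.nan
    mids = locus_midpoints(panel)[loci].to_numpy()
    gdist = np.abs(mids[:, None] - mids[None, :])
    bin_ids = _genomic_bin_ids(gdist, bins_per_decade)
    expected = np.full_like(observed, np.nan)
    for b in np.unique(bin_ids[bin_ids >= 0]):
        mask = bin_ids == b
        vals = observed[mask]
        mean = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
        if mean == 0:
            log.warning("expected proximity 0 in genomic bin %d; NaN entries", b)
            mean = np.nan
        expected[mask] = mean
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = observed / expected
    np.fill_diagonal(normalized, np.nan)
    return loci, normalized


def _impute_by_offset(matrix: np.ndarray) -> np.ndarray:
    """Fill NaNs with the mean of their |i-j| diagonal offset (distance proxy)."""
    out = matrix.copy()
    n = len(matrix)
    idx = np.arange(n)
    offset = np.abs(idx[:, None] - idx[None, :])
    for off in range(1, n):
        mask = offset == off
        vals = out[mask]
        if np.isnan(vals).any():
            fill = np.nanmean(vals) if np.isfinite(vals).any() else 1.0
            block = out[mask]
            block[np.isnan(block)] = fill
            out[mask] = block
    return out


def cross_correlation_matrix(norm_prox: np.ndarray, exclude_adjacent: int = 1
                             ) -> np.ndarray:
    """Pearson correlation between rows of the O/E matrix.

    For each row pair (i, j), entries in columns within ``exclude_adjacent``
    of either i or j (and the diagonal) are masked out before correlating, to
    avoid self-correlation inflation.
    """
    n = len(norm_prox)
    corr = np.full((n, n), np.nan)
    cols = np.arange(n)
    for i in range(n):
        for j in range(i, n):
            mask = (np.abs(cols - i) > exclude_adjacent) \
                & (np.abs(cols - j) > exclude_adjacent)
            xi, xj = norm_prox[i, mask], norm_prox[j, mask]
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() >= 3 and xi[ok].std() > 0 and xj[ok].std() > 0:
                corr[i, j] = corr[j, i] = np.corrcoef(xi[ok], xj[ok])[0, 1]
    np.fill_diagonal(corr, 1.0)
    return corr


def call_compartments(norm_prox: np.ndarray, cpg_density: np.ndarray,
                      loci: list[str] | None = None,
                      max_nan_frac: float = 0.2) -> CompartmentProfile:
    """Call A/B compartments from an O/E proximity matrix and CpG density.

    NaNs (up to ``max_nan_frac`` off-diagonal) are imputed by the mean of
    their genomic-distance stratum; PCA is run on the column-centred
    cross-correlation matrix; among the first three PCs the one with the
    highest |Pearson correlation| to CpG density is selected and oriented so
    the correlation is positive.  Loci with positive oriented values are
    labelled A.
    """
    norm_prox = np.asarray(norm_prox, float)
    n = len(norm_prox)
    if loci is None:
        loci = [f"L{i:04d}" for i in range(n)]
    offdiag = ~np.eye(n, dtype=bool)
    nan_frac = np.isnan(norm_prox[offdiag]).mean()
    if nan_frac > max_nan_frac:
        raise ValueError(f"{nan_frac:.0%} NaN entries exceeds {max_nan_frac:.0%}")
    filled = _impute_by_offset(norm_prox)
    np.fill_diagonal(filled, 1.0)
    corr = cross_correlation_matrix(filled)
    corr = np.nan_to_num(corr, nan=0.0)
    if np.allclose(corr - np.diag(np.diag(corr)), 0.0) or np.ptp(filled) == 0:
        raise ValueError("no structure: constant proximity matrix")
    n_comp = min(3, n - 1)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(corr - corr.mean(axis=0, keepdims=True))
    pcs = scores.T                                   # (n_comp, n)
    cpg = np.asarray(cpg_density, float)
    corrs = np.zeros(n_comp)
    for k in range(n_comp):
        if pcs[k].std() > 0 and cpg.std() > 0:
            corrs[k] = pearsonr(pcs[k], cpg)[0]
    selected = int(np.argmax(np.abs(corrs)))
    values = pcs[selected] * np.sign(corrs[selected] if corrs[selected] != 0 else 1.0)
    labels = np.where(values > 0, "A", "B")
    return CompartmentProfile(loci=loci, pcs=pcs, selected_pc=selected,
                              values=values, labels=labels,
                              cpg_corr=np.abs(corrs))


def normalized_pair_distances(dm: DistanceMatrix, panel: pd.DataFrame,
                              bins_per_decade: int = OE_BINS_PER_DECADE
                              ) -> np.ndarray:
    """Genomic-distance-normalized median distance matrix.

    Each entry is divided by the median of all entries in its log-spaced
    genomic-distance bin, removing the polymer distance-decay so that A/B
    contrasts can be compared across genomic separations.
    """
    mids = locus_midpoints(panel)[dm.loci].to_numpy()
    gdist = np.abs(mids[:, None] - mids[None, :])
    bin_ids = _genomic_bin_ids(gdist, bins_per_decade)
    med = dm.median
    norm = np.full_like(med, np.nan)
    for b in np.unique(bin_ids[bin_ids >= 0]):
        mask = bin_ids == b
        ref = np.nanmedian(med[mask]) if np.isfinite(med[mask]).any() else np.nan
        if ref and np.isfinite(ref):
            norm[mask] = med[mask] / ref
    return norm


def segregation_from_matrix(dm: DistanceMatrix, panel: pd.DataFrame,
                            labels: pd.Series,
                            bins_per_decade: int = OE_BINS_PER_DECADE) -> float:
    """Segregation score from a precomputed median distance matrix."""
    lab = labels.reindex(dm.loci).to_numpy()
    present = set(lab[pd.notna(lab)])
    if not {"A", "B"} <= present:
        raise ValueError(
            f"both labels required on {dm.chrom}; found {sorted(present)}")
    norm = normalized_pair_distances(dm, panel, bins_per_decade)
    iu, ju = np.triu_indices(len(dm.loci), k=1)
    vals = norm[iu, ju]
    cross = lab[iu] != lab[ju]
    ok = np.isfinite(vals) & pd.notna(lab[iu]) & pd.notna(lab[ju])
    ab = np.nanmedian(vals[ok & cross])
    within = np.nanmedian(vals[ok & ~cross])
    return float(ab / within)


def segregation_score(traces: pd.DataFrame, panel: pd.DataFrame,
                      labels: pd.Series, chrom: str,
                      cell_type: str | None = None, min_cells: int = 20,
                      bins_per_decade: int = OE_BINS_PER_DECADE) -> float:
    """A/B segregation score for one chromosome.

    Each cis pair's median spatial distance is divided by the median distance
    of all pairs in its log-spaced genomic-distance bin (removing the genomic
    distance effect); the score is the median normalized distance of A-B
    pairs over that of pooled A-A and B-B pairs.  Values above 1 mean A and
    B loci are spatially segregated.
    """
    dm = median_distance_matrix(traces, panel, chrom, cell_type, min_cells)
    return segregation_from_matrix(dm, panel, labels, bins_per_decade)


def insulation_profile(norm_prox: np.ndarray, window: int = 5
                       ) -> tuple[np.ndarray, float, np.ndarray]:
    """Normalized insulation score along a chromosome, its IQR, and minima.

    ``IS(i)`` is the mean O/E proximity over the ``window x window`` square
    upstream x downstream of position ``i``; the normalized score is
    ``log2(IS / mean IS)``.  Low values mark positions across which proximity
    is depleted — domain boundaries.  Returns (scores with NaN margins, IQR,
    indices of local minima).
    """
    n = len(norm_prox)
    if window >= n / 2:
        raise ValueError(f"window {window} >= n/2 for n={n}")
    scores = np.full(n, np.nan)
    for i in range(window, n - window + 1):
        block = norm_prox[i - window:i, i:i + window]
        if np.isfinite(block).any():
            scores[i] = np.nanmean(block)
    valid = np.isfinite(scores)
    mean_is = np.nanmean(scores[valid])
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(valid, np.log2(scores / mean_is), np.nan)
    finite = normalized[np.isfinite(normalized)]
    iqr = float(np.percentile(finite, 75) - np.percentile(finite, 25)) \
        if len(finite) else np.nan
    minima = []
    for i in range(1, n - 1):
        if (np.isfinite(normalized[i]) and np.isfinite(normalized[i - 1])
                and np.isfinite(normalized[i + 1])
                and normalized[i] <= normalized[i - 1]
                and normalized[i] < normalized[i + 1]):
            minima.append(i)
    return normalized, iqr, np.array(minima, dtype=int)


def megadomain_strength(dist_matrix: np.ndarray, boundary: int) -> float:
    """Ratio of median inter- to intra-megadomain spatial distance.

    ``boundary`` is the locus index where the second megadomain starts; raw
    (un-normalized) distances are used.  Values above 1 indicate a bipartite
    megadomain structure.
    """
    n = len(dist_matrix)
    if not 0 < boundary < n:
        raise ValueError(f"boundary must be strictly inside (0, {n})")
    iu, ju = np.triu_indices(n, k=1)
    vals = np.asarray(dist_matrix, float)[iu, ju]
    cross = (iu < boundary) & (ju >= boundary)
    inter = np.nanmedian(vals[cross])
    intra = np.nanmedian(vals[~cross])
    return float(inter / intra)


def detect_megadomain_boundary(norm_prox: np.ndarray, window: int = 5) -> int:
    """De novo boundary: argmin of the normalized insulation profile."""
    normalized, _, _ = insulation_profile(norm_prox, window)
    return int(np.nanargmin(normalized))


def compartment_change(labels_ref: np.ndarray, labels_other: np.ndarray
                       ) -> dict[str, float]:
    """Fractions of loci by compartment conservation/change (sums to 1)."""
    labels_ref = np.asarray(labels_ref)
    labels_other = np.asarray(labels_other)
    if labels_ref.shape != labels_other.shape:
        raise ValueError("label arrays must have the same length")
    n = len(labels_ref)
    out = {}
    for a in ("A", "B"):
        for b in ("A", "B"):
            out[f"{a}->{b}"] = float(
                ((labels_ref == a) & (labels_other == b)).sum() / n)
    return out
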