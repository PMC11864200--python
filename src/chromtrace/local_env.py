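"""Locus-level chromatin environment and its coupling to expression.

The local A/B density ratio measures, for one locus in one cell, the
Gaussian-kernel-weighted density of *trans-chromosomal* compartment-A loci
over compartment-B loci in its spatial neighbourhood — a per-cell proxy for
how active a chromatin environment the locus sits in.  Around it this module
builds the gene-level machinery: gene-to-locus mapping, locus transcriptional
activity, differential-expression scores, equal-count radial binning, and
WT-vs-KO perturbation comparisons with Bonferroni-corrected sign tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import locus_midpoints

RATIO_PSEUDOCOUNT = 1e-3
MIN_TRANS_LOCI = 10


# ---------------------------------------------------------------------------
# Local A/B density ratio
# ---------------------------------------------------------------------------

def local_ab_density_ratio(cell_trace: pd.DataFrame, labels: pd.Series,
                           kernel_scale: float = 1.0,
                           min_trans: int = MIN_TRANS_LOCI) -> pd.DataFrame:
    """Per-locus local A/B density ratio within one cell.

    For locus ``p``, ``density_X = sum over trans-chromosomal loci q with
    label X of exp(-|p-q|^2 / (2 sigma^2))`` with ``sigma = kernel_scale``
    (µm); the ratio is ``(density_A + eps) / (density_B + eps)`` with
    ``eps = 1e-3``.  Both homologs of the query locus are scored
    independently.  Cells with fewer than ``min_trans`` decoded trans loci
    for a query yield NaN for that query.
    """
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be > 0")
    lab = labels.reindex(cell_trace["locus_id"]).to_numpy()
    if pd.isna(lab).any():
        missing = sorted(set(
            cell_trace.loc[pd.isna(lab), "locus_id"]))[:5]
        raise ValueError(f"labels missing for loci, e.g. {missing}")
    coords = cell_trace[["x", "y", "z"]].to_numpy(float)
    chroms = cell_trace["chrom"].to_numpy()
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    sq = (diff ** 2).sum(axis=-1)
    weights = np.exp(-sq / (2.0 * kernel_scale ** 2))
    trans = chroms[:, None] != chroms[None, :]
    is_a = (lab == "A")[None, :]
    dens_a = (weights * trans * is_a).sum(axis=1)
    dens_b = (weights * trans * ~is_a).sum(axis=1)
    n_trans = trans.sum(axis=1)
    ratio = (dens_a + RATIO_PSEUDOCOUNT) / (dens_b + RATIO_PSEUDOCOUNT)
    ratio = np.where(n_trans >= min_trans, ratio, np.nan)
    out = cell_trace[["cell_id", "cell_type", "genotype", "chrom",
                      "locus_id", "homolog"]].copy()
    out["local_ab_ratio"] = ratio
    out["n_trans"] = n_trans
    return out


def local_env_table(traces: pd.DataFrame, labels: pd.Series,
                    kernel_scale: float = 1.0,
                    min_trans: int = MIN_TRANS_LOCI) -> pd.DataFrame:
    """Local A/B density ratio for every cell in a trace table."""
    frames = [local_ab_density_ratio(cell, labels, kernel_scale, min_trans)
              for _, cell in traces.groupby("cell_id", sort=False)]
    return pd.concat(frames, ignore_index=True)


def median_ratio_per_locus(env: pd.DataFrame) -> pd.Series:
    """Median over cells of the per-cell ratios, per locus."""
    return env.groupby("locus_id")["local_ab_ratio"].median()


def normalize_ratio_across_groups(env_by_group: dict[str, pd.Series]
                                  ) -> dict[str, pd.Series]:
    """Remove overall ratio differences between groups (cell types/genotypes).

    Each group's per-locus median ratio is divided by the group's grand mean
    over loci, so every normalized group has grand mean 1 and only per-locus
    differences survive.
    """
    if len(env_by_group) < 2:
        raise ValueError("need at least two groups to normalize across")
    out = {}
    for name, ratios in env_by_group.items():
        if ratios.dropna().empty:
            raise ValueError(f"group {name!r} has no finite ratios")
        out[name] = ratios / ratios.mean()
    return out


# ---------------------------------------------------------------------------
# Genes, activity, differential expression
# ---------------------------------------------------------------------------

def map_genes_to_loci(genes: pd.DataFrame, panel: pd.DataFrame,
                      window: float = 100_000.0) -> pd.Series:
    """Map each gene to the nearest imaged locus within ``window`` bp.

    A gene qualifies for a locus when its TSS is within ``window`` of the
    locus interval (edge distance, inclusive); among qualifying loci the one
    with the nearest midpoint wins, ties to the lower coordinate.  Unmapped
    genes are absent from the returned Series (gene_id -> locus_id).
    """
    mapping = {}
    for chrom, group in genes.groupby("chrom", sort=False):
        loci = panel[panel["chrom"] == chrom]
        if loci.empty:
            continue
        starts = loci["start"].to_numpy(float)
        ends = loci["end"].to_numpy(float)
        mids = ((starts + ends) / 2.0)
        ids = loci["locus_id"].to_numpy()
        for gene in group.itertuples(index=False):
            edge = np.maximum(np.maximum(starts - gene.tss,
                                         gene.tss - (ends - 1)), 0)
            ok = edge <= window
            if not ok.any():
                continue
            middist = np.abs(mids[ok] - gene.tss)
            best = np.lexsort((mids[ok], middist))[0]
            mapping[gene.gene_id] = ids[ok][best]
    return pd.Series(mapping, name="locus_id")


def locus_activity(expression: pd.DataFrame, gene_map: pd.Series,
                   panel: pd.DataFrame) -> pd.DataFrame:
    """Transcriptional activity per locus: sum of mapped gene counts.

    Returns one row per panel locus with one column per count column of the
    expression table; loci with no mapped gene carry NaN.
    """
    count_cols = [c for c in expression.columns
                  if c not in ("gene_id", "chrom", "tss", "gene_length")]
    mapped = expression.assign(locus_id=gene_map.reindex(expression["gene_id"]).values)
    sums = mapped.dropna(subset=["locus_id"]).groupby("locus_id")[count_cols].sum()
    return sums.reindex(panel["locus_id"])


def activity_classes(activity: pd.Series, quantile: float = 0.25) -> pd.Series:
    """High/low/mid classes by top and bottom activity quartiles."""
    act = activity.dropna()
    lo, hi = act.quantile(quantile), act.quantile(1 - quantile)
    cls = pd.Series("mid", index=act.index)
    cls[act <= lo] = "low"
    cls[act >= hi] = "high"
    return cls.reindex(activity.index)


def de_score(counts_wt: pd.DataFrame, counts_ko: pd.DataFrame) -> pd.Series:
    """Per-gene Welch t statistic, KO minus WT orientation.

    Input frames are genes x cells; per-cell totals are scaled to the median
    total across all cells of both groups before testing.  Genes with zero
    variance in both groups yield NaN.  Requires >= 2 cells per group.
    """
    if counts_wt.shape[1] < 2 or counts_ko.shape[1] < 2:
        raise ValueError("need at least 2 cells per group")
    if not counts_wt.index.equals(counts_ko.index):
        raise ValueError("WT and KO tables must share the gene index")
    totals = np.concatenate([counts_wt.sum(axis=0).to_numpy(float),
                             counts_ko.sum(axis=0).to_numpy(float)])
    target = np.median(totals)

    def _norm(frame: pd.DataFrame) -> np.ndarray:
        t = frame.sum(axis=0).to_numpy(float)
        t[t == 0] = 1.0
        return frame.to_numpy(float) * (target / t)[None, :]

    wt, ko = _norm(counts_wt), _norm(counts_ko)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        t_stat, _ = stats.ttest_ind(ko, wt, axis=1, equal_var=False)
    return pd.Series(t_stat, index=counts_wt.index, name="de_score")


def split_per_cell_columns(expression: pd.DataFrame,
                           cell_type: str, genotype: str) -> pd.DataFrame:
    """Extract the genes x cells block for one cell type and genotype from a
    per-cell expression table with ``<cell_type>|<genotype>|<i>`` columns."""
    cols = [c for c in expression.columns
            if c.startswith(f"{cell_type}|{genotype}|")]
    return expression.set_index("gene_id")[cols]


# ---------------------------------------------------------------------------
# Radial binning and perturbation comparison
# ---------------------------------------------------------------------------

def radial_bin_analysis(values: pd.Series, radial_positions: pd.Series,
                        n_bins: int = 10) -> pd.DataFrame:
    """Per-radial-bin mean and normal-approximation 95% CI.

    Bins are equal-count on radial position (counts differ by at most one).
    Raises when fewer than ``n_bins`` finite points are available.
    """
    frame = pd.DataFrame({"value": values, "radial": radial_positions}).dropna()
    if len(frame) < n_bins:
        raise ValueError(f"{len(frame)} points < {n_bins} bins")
    order = frame["radial"].rank(method="first")
    frame["bin"] = np.ceil(order * n_bins / len(frame)).astype(int) - 1
    rows = []
    for b, grp in frame.groupby("bin"):
        mean = grp["value"].mean()
        sem = grp["value"].std(ddof=1) / np.sqrt(len(grp)) if len(grp) > 1 else np.nan
        rows.append((int(b), float(grp["radial"].mean()), len(grp), float(mean),
                     float(mean - 1.96 * sem) if np.isfinite(sem) else np.nan,
                     float(mean + 1.96 * sem) if np.isfinite(sem) else np.nan))
    return pd.DataFrame(rows, columns=["bin", "mean_radial", "n", "mean",
                                       "ci_low", "ci_high"])


@dataclasses.dataclass
class PerturbationComparison:
    """Per-locus WT-vs-KO deltas plus per-compartment significance tests."""

    table: pd.DataFrame              # locus_id, delta_ratio, delta_radial,
                                     # compartment, radial_bin, de_score
    compartment_tests: pd.DataFrame  # compartment, mean_delta, t, p_raw,
                                     # p_bonferroni, significant
    n_tests: int
    decile_profile: pd.DataFrame | None = None   # Δratio per WT radial decile
    de_correlation: float | None = None          # Spearman(Δratio decile, DE)


def perturbation_comparison(env_wt: pd.DataFrame, env_ko: pd.DataFrame,
                            labels: pd.Series, radial_wt: pd.Series,
                            de_scores: pd.Series | None = None,
                            radial_ko: pd.Series | None = None,
                            n_bins: int = 10, alpha: float = 0.05,
                            min_loci_per_test: int = 5) -> PerturbationComparison:
    """Compare local A/B environment between genotypes, locus by locus.

    Per-locus median ratios of each genotype are normalized to grand mean 1
    (removing the overall genotype offset), and the per-locus delta
    (KO - WT) is tested against 0 within each compartment with one-sample t
    tests under Bonferroni correction over the set of tests.  Loci are
    assigned to ``n_bins`` equal-count bins of their *WT* radial position;
    when ``de_scores`` are given, the per-decile mean DE score and the
    Spearman correlation between Δratio deciles and DE scores are reported.
    """
    ratios = normalize_ratio_across_groups({
        "WT": median_ratio_per_locus(env_wt),
        "KO": median_ratio_per_locus(env_ko),
    })
    delta = (ratios["KO"] - ratios["WT"]).rename("delta_ratio")
    table = pd.DataFrame({"delta_ratio": delta})
    table["compartment"] = labels.reindex(table.index)
    table["radial_wt"] = radial_wt.reindex(table.index)
    if radial_ko is not None:
        table["delta_radial"] = radial_ko.reindex(table.index) - table["radial_wt"]
    else:
        table["delta_radial"] = np.nan
    finite = table.dropna(subset=["delta_ratio", "radial_wt"])
    order = finite["radial_wt"].rank(method="first")
    table.loc[finite.index, "radial_bin"] = \
        np.ceil(order * n_bins / len(finite)).astype(int) - 1

    tests = []
    comps = [c for c in ("A", "B") if (table["compartment"] == c).any()]
    n_tests = len(comps)
    for comp in comps:
        vals = table.loc[table["compartment"] == comp, "delta_ratio"].dropna()
        if len(vals) < min_loci_per_test:
            tests.append((comp, float(vals.mean()) if len(vals) else np.nan,
                          np.nan, np.nan, np.nan, False))
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        p_adj = min(1.0, p * n_tests)
        tests.append((comp, float(vals.mean()), float(t), float(p),
                      float(p_adj), bool(p_adj <= alpha)))
    compartment_tests = pd.DataFrame(
        tests, columns=["compartment", "mean_delta", "t", "p_raw",
                        "p_bonferroni", "significant"])

    decile = table.dropna(subset=["radial_bin"]) \
        .groupby("radial_bin")["delta_ratio"].mean() \
        .rename("mean_delta_ratio").reset_index()

    de_corr = None
    if de_scores is not None:
        table["de_score"] = de_scores.reindex(table.index)
        sub = table.dropna(subset=["delta_ratio", "de_score"])
        if len(sub) >= n_bins:
            rank = sub["delta_ratio"].rank(method="first")
            dbin = np.ceil(rank * n_bins / len(sub)).astype(int) - 1
            per_bin = sub.assign(dbin=dbin).groupby("dbin").agg(
                mean_delta=("delta_ratio", "mean"),
                mean_de=("de_score", "mean"))
            rho, _ = stats.spearmanr(per_bin["mean_delta"], per_bin["mean_de"])
            de_corr = float(rho)
    else:
        table["de_score"] = np.nan

    return PerturbationComparison(table=table, compartment_tests=compartment_tests,
                                  n_tests=n_tests, decile_profile=decile,
                                  de_correlation=de_corr)


def conserved_compartment_filter(labels_wt: pd.Series, labels_ko: pd.Series
                                 ) -> tuple[pd.Index, dict[str, float]]:
    """Loci with identical compartment calls in both genotypes.

    Returns (conserved locus index, change fractions including 'conserved').
    """
    common = labels_wt.index.intersection(labels_ko.index)
    wt, ko = labels_wt[common], labels_ko[common]
    conserved = common[(wt == ko).to_numpy()]
    n = len(common)
    fractions = {
        "conserved": len(conserved) / n if n else np.nan,
        "A->B": float(((wt == "A") & (ko == "B")).sum() / n) if n else np.nan,
        "B->A": float(((wt == "B") & (ko == "A")).sum() / n) if n else np.nan,
    }
    return conserved, fractions
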