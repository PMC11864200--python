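"""Synthetic chromatin-trace, expression and accessibility generator.

Every downstream estimator in this package is tested against populations with
*planted* structure, produced here.  The generator emulates the statistical
features the analysis assumes — A/B compartment blocks, megadomains, a
two-regime spatial-vs-genomic distance scaling with a crossover near 10 Mb,
radially segregated active chromatin, detection dropout and localization
noise, and a knockout mode that de-segregates compartments — without
simulating polymer physics.

Backbone model
--------------
Each chromosome homolog is a sum of two fractional-Brownian (fBm) chains in
3D.  Fine chains with exponent ``h_short`` are generated independently per
crossover block (a run of loci spanning the crossover genomic distance
``g_c``) and centred within the block, so their contribution saturates beyond
``g_c``; a coarse block-level fBm with exponent ``h_long`` carries the
long-range scaling.  Amplitudes are matched so the root-mean-square 3D
distance at ``g_c`` equals ``contact_distance_um`` for both components,
placing the scaling crossover at ``g_c``.  When ``h_short == h_long`` a
single full-chromosome fBm is used so the planted exponent is exact at all
scales.  Each chain is then rescaled by a deterministic factor (computed from
the analytic chain covariance) so its expected radius of gyration equals
``territory_frac`` times the nucleus radius — chromosome territories tile the
nucleus as in real cells, and since the factor is non-random the planted
exponents survive the rescaling exactly.

Radial segregation is planted by the monotone warp ``r -> r**(1 + gamma)``
for compartment-A loci and ``r -> r**(1 - gamma)`` for compartment-B loci on
the normalized radius, followed by a window-3 moving average along the chain
to restore continuity.  The KO genotype mixes each warped configuration back
toward its unwarped, label-blind counterpart with weight ``ko_mixing``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_core import LOCUS_WIDTH, validate_locus_panel, validate_traces

_GOLDEN = 0.6180339887498949


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ChromosomeSpec:
    """One synthetic chromosome: locus count, spacing and planted structure."""

    name: str
    n_loci: int = 80
    spacing_bp: float = 2_500_000.0
    block_size: int = 8            # loci per A/B compartment block
    megadomain_boundary: int | None = None  # locus index; default n_loci // 2

    def __post_init__(self) -> None:
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        if self.block_size > self.n_loci:
            raise ValueError(
                f"block size {self.block_size} > chromosome length {self.n_loci}")
        if self.megadomain_boundary is None:
            self.megadomain_boundary = self.n_loci // 2


@dataclasses.dataclass
class CellTypeParams:
    """Per-cell-type geometry, scaling and perturbation-response parameters."""

    name: str
    nucleus_radius_um: float = 3.0
    activity_scale: float = 1.0
    h_short: float = 0.45
    h_long: float = 0.25
    gamma: float = 0.4             # radial A-interior bias strength
    megadomain_amp_um: float = 0.0
    h_activity_coupling: float = 0.0
    ko_response: float = 1.0       # neuron-like (1) vs glia-like (~0) KO effect

    def __post_init__(self) -> None:
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus_radius_um must be > 0")
        for h in (self.h_short, self.h_long):
            if not 0 < h < 1:
                raise ValueError("scaling exponents must lie in (0, 1)")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")


@dataclasses.dataclass
class SimulationParams:
    """Study conditions for a synthetic population.

    Defaults emulate the imaged system: ~2.5-Mb locus spacing, two homologs
    per chromosome, a 10-Mb scaling crossover, RMS pair distance ~2 µm at the
    crossover, 75% detection efficiency and 50-nm localization error.
    """

    chromosomes: list[ChromosomeSpec] = dataclasses.field(
        default_factory=lambda: [ChromosomeSpec("chr1"), ChromosomeSpec("chr2")])
    cell_types: list[CellTypeParams] = dataclasses.field(
        default_factory=lambda: [CellTypeParams("neuron")])
    n_cells_per_type: int = 100
    crossover_bp: float = 10_000_000.0
    contact_distance_um: float = 2.0   # RMS 3D pair distance at the crossover
    territory_frac: float = 0.5        # territory Rg as a fraction of R
    ko_mixing: float = 0.5             # convex weight toward the unwarped state
    p_det: float = 0.75
    localization_sigma_um: float = 0.05
    cpg_compartment_corr: float = 0.8
    expression_alpha: float = 1.0      # log-mean boost for compartment-A genes
    nb_dispersion: float | None = 2.0  # NB size parameter; None -> Poisson
    ko_expression_effect: float = 2.0  # log-scale radial DE coupling
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_det <= 1:
            raise ValueError("p_det must lie in (0, 1]")
        if not 0 <= self.ko_mixing <= 1:
            raise ValueError("ko_mixing must lie in [0, 1]")
        if not -1 <= self.cpg_compartment_corr <= 1:
            raise ValueError("cpg_compartment_corr must lie in [-1, 1]")
        if self.localization_sigma_um < 0:
            raise ValueError("localization_sigma_um must be >= 0")
        if self.crossover_bp <= 0 or self.contact_distance_um <= 0:
            raise ValueError("crossover_bp and contact_distance_um must be > 0")


def default_cell_types(n_types: int = 8, base_radius_um: float = 2.2,
                       activity_range: tuple[float, float] = (0.5, 8.0),
                       **overrides) -> list[CellTypeParams]:
    """Cell types with activity spread over a range and radius tied to it.

    The nucleus radius grows as the cube root of activity, so nuclear volume
    is proportional to total transcriptional activity across types.
    """
    activities = np.geomspace(activity_range[0], activity_range[1], n_types)
    return [
        CellTypeParams(name=f"ct{i:02d}", activity_scale=float(a),
                       nucleus_radius_um=float(base_radius_um * a ** (1 / 3)),
                       **overrides)
        for i, a in enumerate(activities)
    ]


# ---------------------------------------------------------------------------
# Truth panel
# ---------------------------------------------------------------------------

def make_truth_panel(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Locus panel plus ground-truth labels for a parameter set.

    Compartment labels alternate in blocks of ``block_size`` loci per
    chromosome; CpG density is constructed so its sample Pearson correlation
    with the A indicator equals ``cpg_compartment_corr`` exactly (the noise
    component is orthogonalized against the indicator before mixing).
    Each locus also carries a planted radial quantile and the radial position
    it maps to under the warp of the first cell type.
    """
    rng = np.random.default_rng([params.seed, 917])
    panel_rows, truth_rows = [], []
    for chrom in params.chromosomes:
        for k in range(chrom.n_loci):
            mid = 1_000_000 + k * chrom.spacing_bp
            start = int(mid - LOCUS_WIDTH / 2)
            block = k // chrom.block_size
            comp = "A" if block % 2 == 0 else "B"
            locus_id = f"{chrom.name}_L{k:04d}"
            panel_rows.append((locus_id, chrom.name, start, start + LOCUS_WIDTH,
                               "genome_wide"))
            q = 0.1 + 0.8 * ((k * _GOLDEN) % 1.0)
            truth_rows.append((locus_id, chrom.name, k, comp, block,
                               1 if k < chrom.megadomain_boundary else 2, q))
    panel = pd.DataFrame(panel_rows, columns=["locus_id", "chrom", "start", "end",
                                              "panel_group"])
    truth = pd.DataFrame(truth_rows, columns=["locus_id", "chrom", "locus_index",
                                              "compartment", "block_id",
                                              "megadomain", "radial_quantile"])

    # CpG density with exact sample correlation to the A indicator.
    a = (truth["compartment"] == "A").to_numpy(float)
    a_std = (a - a.mean())
    a_std /= np.linalg.norm(a_std)
    noise = rng.standard_normal(len(a))
    noise = noise - noise.mean()
    noise -= a_std * (noise @ a_std)          # orthogonalize against indicator
    norm = np.linalg.norm(noise)
    noise = noise / norm if norm > 0 else noise
    rho = params.cpg_compartment_corr
    z = rho * a_std + np.sqrt(max(0.0, 1 - rho ** 2)) * noise
    cpg = z - z.min() + 0.1                   # affine: correlation preserved
    panel["cpg_density"] = cpg * 10.0         # CpG per kb scale
    panel = validate_locus_panel(panel, strict_length=True)

    gamma0 = params.cell_types[0].gamma
    is_a = truth["compartment"] == "A"
    q = truth["radial_quantile"].to_numpy()
    truth["truth_radial"] = np.where(is_a, q ** (1 + gamma0), q ** (1 - gamma0))
    return panel, truth


# ---------------------------------------------------------------------------
# fBm chains
# ---------------------------------------------------------------------------

_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _fbm_cholesky(offsets: np.ndarray, hurst: float) -> np.ndarray:
    """Cholesky factor of the unit fBm covariance over the given offsets.

    ``offsets`` are nonnegative scaled genomic coordinates relative to the
    chain origin (the first entry must be 0); the origin row/column is
    dropped because the process is pinned to zero there.
    """
    key = (round(float(hurst), 9), tuple(np.round(offsets, 9)))
    if key not in _CHOL_CACHE:
        u = offsets[1:]
        h2 = 2 * hurst
        cov = 0.5 * (u[:, None] ** h2 + u[None, :] ** h2
                     - np.abs(u[:, None] - u[None, :]) ** h2)
        cov += 1e-12 * np.eye(len(u))
        _CHOL_CACHE[key] = np.linalg.cholesky(cov)
    return _CHOL_CACHE[key]


def _fbm_chain(offsets: np.ndarray, hurst: float, sigma_axis: float,
               rng: np.random.Generator) -> np.ndarray:
    """A 3D fBm chain over ``offsets`` with per-axis increment scale sigma."""
    n = len(offsets)
    chain = np.zeros((n, 3))
    if n > 1:
        chol = _fbm_cholesky(offsets - offsets[0], hurst)
        chain[1:] = sigma_axis * (chol @ rng.standard_normal((n - 1, 3)))
    return chain


def _unit_fbm_cov(offsets: np.ndarray, hurst: float) -> np.ndarray:
    """Full unit fBm covariance (pinned at the first offset)."""
    u = offsets - offsets[0]
    h2 = 2 * hurst
    return 0.5 * (u[:, None] ** h2 + u[None, :] ** h2
                  - np.abs(u[:, None] - u[None, :]) ** h2)


_RG2_CACHE: dict[tuple, float] = {}


def _expected_rg2(mids: np.ndarray, blocks_a_frac: np.ndarray | None,
                  ct: CellTypeParams, crossover_bp: float, d_c: float) -> float:
    """Expected squared radius of gyration of a backbone chain (µm²).

    Assembled analytically from the same fBm covariances used to draw the
    chain, so the chain-to-territory rescaling in :func:`simulate_cell` is a
    deterministic factor and leaves the planted scaling exponents untouched.
    """
    key = (tuple(np.round(mids, 3)), ct.h_short, ct.h_long,
           ct.h_activity_coupling,
           None if blocks_a_frac is None else tuple(np.round(blocks_a_frac, 6)),
           round(crossover_bp, 3))
    if key in _RG2_CACHE:
        return d_c ** 2 * _RG2_CACHE[key]
    u = mids / crossover_bp
    n = len(mids)
    if ct.h_short == ct.h_long and ct.h_activity_coupling == 0.0:
        cov = _unit_fbm_cov(u, ct.h_short)
    else:
        block_ids = np.floor((mids - mids[0]) / crossover_bp).astype(int)
        cov = np.zeros((n, n))
        uniq = np.unique(block_ids)
        for b in uniq:
            idx = np.flatnonzero(block_ids == b)
            h_b = ct.h_short
            if blocks_a_frac is not None and ct.h_activity_coupling != 0.0:
                h_b = float(np.clip(
                    ct.h_short + ct.h_activity_coupling
                    * (2 * blocks_a_frac[b] - 1), 0.05, 0.95))
            cb = _unit_fbm_cov(u[idx], h_b)
            center = np.eye(len(idx)) - 1.0 / len(idx)
            cov[np.ix_(idx, idx)] = center @ cb @ center
        centers = np.array([u[block_ids == b].mean() for b in uniq])
        cc = _unit_fbm_cov(centers, ct.h_long)
        center = np.eye(len(uniq)) - 1.0 / len(uniq)
        cc = center @ cc @ center
        lookup = {b: i for i, b in enumerate(uniq)}
        expand = np.array([lookup[b] for b in block_ids])
        cov = cov + cc[np.ix_(expand, expand)]
    unit_rg2 = float(cov.trace() / n - cov.mean())
    _RG2_CACHE[key] = unit_rg2
    return d_c ** 2 * unit_rg2


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    mat = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(mat)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _backbone(mids: np.ndarray, blocks_a_frac: np.ndarray | None,
              ct: CellTypeParams, crossover_bp: float, d_c: float,
              rng: np.random.Generator) -> np.ndarray:
    """Backbone chain for one homolog (before placement), loci in order."""
    u = mids / crossover_bp
    sigma = d_c / np.sqrt(3.0)   # per-axis scale; E|d3D|^2 = d_c^2 at u-gap 1
    n = len(mids)
    if ct.h_short == ct.h_long and ct.h_activity_coupling == 0.0:
        return _fbm_chain(u - u[0], ct.h_short, sigma, rng)
    block_ids = np.floor((mids - mids[0]) / crossover_bp).astype(int)
    chain = np.zeros((n, 3))
    uniq = np.unique(block_ids)
    for b in uniq:
        idx = np.flatnonzero(block_ids == b)
        h_b = ct.h_short
        if blocks_a_frac is not None and ct.h_activity_coupling != 0.0:
            h_b = float(np.clip(
                ct.h_short + ct.h_activity_coupling * (2 * blocks_a_frac[b] - 1),
                0.05, 0.95))
        fine = _fbm_chain(u[idx] - u[idx[0]], h_b, sigma, rng)
        chain[idx] = fine - fine.mean(axis=0)
    centers = np.array([u[block_ids == b].mean() for b in uniq])
    coarse = _fbm_chain(centers - centers[0], ct.h_long, sigma, rng)
    coarse -= coarse.mean(axis=0)
    lookup = {b: i for i, b in enumerate(uniq)}
    chain += coarse[[lookup[b] for b in block_ids]]
    return chain


# ---------------------------------------------------------------------------
# Per-cell simulation
# ---------------------------------------------------------------------------

def _moving_average(points: np.ndarray, window: int = 3) -> np.ndarray:
    out = np.empty_like(points)
    n = len(points)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def simulate_cell(panel: pd.DataFrame, truth: pd.DataFrame,
                  params: SimulationParams, ct: CellTypeParams,
                  genotype: str, rng: np.random.Generator,
                  cell_id: str = "cell0") -> pd.DataFrame:
    """Simulate the decoded trace rows of one cell.

    Two homolog copies per chromosome; see the module docstring for the
    backbone, warp and KO-mixing model.  Each locus is retained independently
    with probability ``p_det`` and isotropic Gaussian localization noise is
    added last.
    """
    if genotype not in ("WT", "KO"):
        raise ValueError(f"genotype must be WT or KO, got {genotype!r}")
    mixing = params.ko_mixing if genotype == "KO" else 0.0
    radius = ct.nucleus_radius_um
    merged = truth.merge(panel[["locus_id", "start", "end"]], on="locus_id")

    pos_list, meta = [], []
    for chrom in params.chromosomes:
        sub = merged[merged["chrom"] == chrom.name].sort_values("locus_index")
        mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy(float)
        is_a = (sub["compartment"] == "A").to_numpy()
        mega = sub["megadomain"].to_numpy()
        block_ids = np.floor((mids - mids[0]) / params.crossover_bp).astype(int)
        a_frac = np.full(block_ids.max() + 1, 0.5)
        for b in np.unique(block_ids):
            a_frac[b] = is_a[block_ids == b].mean()
        rg2 = _expected_rg2(mids, a_frac, ct, params.crossover_bp,
                            params.contact_distance_um)
        territory_scale = params.territory_frac * radius / np.sqrt(rg2)
        for homolog in (0, 1):
            chain = _backbone(mids, a_frac, ct, params.crossover_bp,
                              params.contact_distance_um, rng)
            chain = chain * territory_scale
            if ct.megadomain_amp_um > 0:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                chain = chain + np.where(mega[:, None] == 2, 0.5, -0.5) \
                    * ct.megadomain_amp_um * direction
            chain = chain - chain.mean(axis=0)
            chain = chain @ _random_rotation(rng).T
            offset_dir = rng.standard_normal(3)
            offset_dir /= np.linalg.norm(offset_dir)
            chain = chain + offset_dir * (0.6 * radius * rng.random() ** (1 / 3))
            pos_list.append(chain)
            for li, lid in enumerate(sub["locus_id"]):
                meta.append((chrom.name, lid, homolog, is_a[li]))

    pos = np.concatenate(pos_list, axis=0)
    max_r = np.linalg.norm(pos, axis=1).max()
    if max_r > 0.95 * radius:
        pos *= 0.95 * radius / max_r

    # Radial warp: A inward, B outward, on the normalized radius.
    is_a_all = np.array([m[3] for m in meta])
    r_norm = np.linalg.norm(pos, axis=1) / radius
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(is_a_all, r_norm ** ct.gamma,
                          r_norm ** (-ct.gamma))
    factor = np.where(r_norm > 0, factor, 1.0)
    warped = pos * factor[:, None]

    # Restore chain continuity, homolog by homolog: the warp displacement
    # field (not the backbone itself) is smoothed along the chain, so label
    # flips at block boundaries cannot tear the chain while the backbone's
    # fine-scale distance statistics stay untouched.
    smoothed = np.empty_like(warped)
    start = 0
    for chain in pos_list:
        n = len(chain)
        displacement = warped[start:start + n] - pos[start:start + n]
        smoothed[start:start + n] = pos[start:start + n] \
            + _moving_average(displacement)
        start += n

    final = (1 - mixing) * smoothed + mixing * pos
    keep = rng.random(len(final)) < params.p_det
    final = final + rng.normal(0.0, params.localization_sigma_um, final.shape)

    rows = pd.DataFrame(
        [(cell_id, ct.name, genotype, m[0], m[1], m[2]) for m in meta],
        columns=["cell_id", "cell_type", "genotype", "chrom", "locus_id", "homolog"])
    rows[["x", "y", "z"]] = final
    rows["score"] = np.nan
    return rows.loc[keep].reset_index(drop=True)


def simulate_population(panel: pd.DataFrame, truth: pd.DataFrame,
                        params: SimulationParams,
                        genotypes: tuple[str, ...] = ("WT",)) -> pd.DataFrame:
    """Simulate ``n_cells_per_type`` cells per cell type and genotype.

    Each cell draws from its own counter-based rng stream keyed on
    ``(seed, cell index)``, so the table is reproducible and order-independent.
    """
    frames = []
    for ti, ct in enumerate(params.cell_types):
        for gi, genotype in enumerate(genotypes):
            for i in range(params.n_cells_per_type):
                cell_index = (ti * len(genotypes) + gi) * params.n_cells_per_type + i
                rng = np.random.default_rng([params.seed, 1_000_003, cell_index])
                cell_id = f"{ct.name}_{genotype}_{i:05d}"
                frames.append(simulate_cell(panel, truth, params, ct, genotype,
                                            rng, cell_id=cell_id))
    traces = pd.concat(frames, ignore_index=True)
    return validate_traces(traces, panel=panel)


# ---------------------------------------------------------------------------
# Expression and accessibility
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float | None) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_expression(panel: pd.DataFrame, truth: pd.DataFrame,
                        params: SimulationParams, genotype: str = "WT",
                        per_cell: bool = False, n_cells: int = 100,
                        alpha: float | None = None) -> pd.DataFrame:
    """Gene-level counts tied to the planted compartment structure.

    One gene is placed at each locus midpoint.  Counts are negative binomial
    with log-mean ``log(activity_scale) + alpha * A_indicator + eps_gene``
    (``eps_gene`` fixed across cell types and genotypes).  For the KO
    genotype each gene's log-mean is shifted by
    ``ko_expression_effect * ko_response * (truth_radial - median)``:
    interior genes down, peripheral genes up, scaled by the cell type's
    neuron-like response factor.

    With ``per_cell=True``, one count column per cell
    (``<cell_type>|<genotype>|<i>``) instead of one per cell type.
    """
    if alpha is None:
        alpha = params.expression_alpha
    if alpha is None:
        raise ValueError("expression alpha is unset")
    rng_genes = np.random.default_rng([params.seed, 424243])
    merged = truth.merge(panel[["locus_id", "start", "end"]], on="locus_id")
    mid = ((merged["start"] + merged["end"]) / 2.0).astype(int)
    expr = pd.DataFrame({
        "gene_id": ["g_" + lid for lid in merged["locus_id"]],
        "chrom": merged["chrom"],
        "tss": mid,
        "gene_length": np.round(
            rng_genes.lognormal(mean=10.5, sigma=1.0, size=len(merged))).astype(int),
    })
    a_ind = (merged["compartment"] == "A").to_numpy(float)
    eps = rng_genes.normal(0.0, 0.3, size=len(merged))
    r_truth = merged["truth_radial"].to_numpy() if "truth_radial" in merged \
        else merged["radial_quantile"].to_numpy()
    radial_dev = r_truth - np.median(r_truth)

    rng_counts = np.random.default_rng(
        [params.seed, 52289, 0 if genotype == "WT" else 1])
    count_cols = {}
    for ct in params.cell_types:
        log_mu = np.log(ct.activity_scale) + alpha * a_ind + eps
        if genotype == "KO":
            log_mu = log_mu + params.ko_expression_effect * ct.ko_response * radial_dev
        mu = 20.0 * np.exp(log_mu)
        if per_cell:
            for i in range(n_cells):
                count_cols[f"{ct.name}|{genotype}|{i}"] = _nb_draw(
                    rng_counts, mu, params.nb_dispersion)
        else:
            count_cols[ct.name] = _nb_draw(rng_counts, mu * n_cells,
                                           params.nb_dispersion)
    return pd.concat([expr, pd.DataFrame(count_cols, index=expr.index)], axis=1)


def simulate_accessibility(panel: pd.DataFrame, truth: pd.DataFrame,
                           params: SimulationParams,
                           alpha: float = 1.0) -> pd.DataFrame:
    """Per-cell-type accessibility signal per locus (A loci more accessible)."""
    rng = np.random.default_rng([params.seed, 777001])
    a_ind = (truth["compartment"] == "A").to_numpy(float)
    eps = rng.normal(0.0, 0.3, size=len(truth))
    acc = truth[["locus_id", "chrom"]].copy()
    for ct in params.cell_types:
        acc[ct.name] = ct.activity_scale * np.exp(alpha * a_ind + eps)
    return acc
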