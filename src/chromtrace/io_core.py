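"""Readers, writers, validation and run configuration.

Tabular data is carried as plain :class:`pandas.DataFrame` objects with fixed
column schemas; the functions here are the only place where on-disk formats are
parsed, and every reader validates the documented invariants instead of
silently coercing.

Conventions
-----------
* Genomic coordinates are 0-based half-open (BED convention); loci are
  unstranded fixed-width segments and genomic distance between two loci is the
  absolute difference of their midpoints in bp.
* Spatial coordinates are in micrometres, right-handed axes, per-cell origin.
* Missing data are absent rows (traces) or NaN (matrices), never sentinels.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("chromtrace")

LOCUS_WIDTH = 20_000  # bp spanned by the encoding probes of one locus

PANEL_GROUPS = ("genome_wide", "super_enhancer", "tss")
GENOTYPES = ("WT", "KO", "NA")

PANEL_COLUMNS = ["locus_id", "chrom", "start", "end", "panel_group",
                 "cpg_density", "barcode_id"]
TRACE_COLUMNS = ["cell_id", "cell_type", "genotype", "chrom", "locus_id",
                 "homolog", "x", "y", "z", "score"]
EXPRESSION_KEY_COLUMNS = ["gene_id", "chrom", "tss", "gene_length"]


class ValidationError(ValueError):
    """An input table violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message carries the offending line."""


def configure_logging(level: str = "INFO") -> None:
    """Configure plain-text logging for the package logger."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """All pipeline tunables with their default values.

    Attributes
    ----------
    proximity_cutoff_um:
        Spatial distance below which a locus pair counts as proximal (µm).
    scaling_boundary_bp:
        Genomic distance separating the short- and long-range scaling regimes.
    min_loci_per_cell:
        Minimum decoded loci for nuclear-volume estimation (alternate: 600).
    kernel_scale_um:
        Gaussian kernel sigma for the local A/B density ratio.
    n_radial_bins:
        Number of equal-count radial bins in binned analyses.
    min_cells_per_pair:
        Minimum observations for a pairwise median distance entry.
    insulation_window:
        Insulation-score window in loci.
    seed:
        Master seed; every stochastic operation derives its stream from here.
    """

    proximity_cutoff_um: float = 0.75
    scaling_boundary_bp: float = 10_000_000.0
    min_loci_per_cell: int = 1250
    kernel_scale_um: float = 1.0
    n_radial_bins: int = 10
    min_cells_per_pair: int = 20
    insulation_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proximity_cutoff_um <= 0:
            raise ValidationError("proximity_cutoff_um must be > 0")
        if self.scaling_boundary_bp <= 0:
            raise ValidationError("scaling_boundary_bp must be > 0")
        if self.n_radial_bins < 1:
            raise ValidationError("n_radial_bins must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Locus panels
# ---------------------------------------------------------------------------

def validate_locus_panel(panel: pd.DataFrame, strict_length: bool = False) -> pd.DataFrame:
    """Check LocusPanel invariants and return the panel sorted by (chrom, start).

    Raises :class:`ValidationError` on duplicate locus ids, negative CpG
    densities, non-positive intervals, or (with ``strict_length``) intervals
    that are not exactly 20 kb.
    """
    missing = [c for c in ("locus_id", "chrom", "start", "end") if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel missing columns: {missing}")
    panel = panel.copy()
    if panel["locus_id"].duplicated().any():
        dup = panel.loc[panel["locus_id"].duplicated(), "locus_id"].tolist()
        raise ValidationError(f"duplicate locus_id: {dup}")
    if (panel["end"] <= panel["start"]).any():
        raise ValidationError("panel contains empty or inverted intervals")
    if strict_length and (panel["end"] - panel["start"] != LOCUS_WIDTH).any():
        bad = panel.loc[panel["end"] - panel["start"] != LOCUS_WIDTH, "locus_id"].tolist()
        raise ValidationError(f"loci not {LOCUS_WIDTH} bp wide: {bad}")
    if "cpg_density" in panel.columns and (panel["cpg_density"].dropna() < 0).any():
        raise ValidationError("cpg_density must be >= 0")
    if "panel_group" in panel.columns:
        bad_groups = set(panel["panel_group"].dropna()) - set(PANEL_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown panel_group values: {sorted(bad_groups)}")
    for col in ("panel_group", "cpg_density", "barcode_id"):
        if col not in panel.columns:
            panel[col] = np.nan
    panel = panel.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return panel[PANEL_COLUMNS]


def locus_midpoints(panel: pd.DataFrame) -> pd.Series:
    """Midpoint (bp) of each locus, indexed by locus_id."""
    mid = (panel["start"] + panel["end"]) / 2.0
    return pd.Series(mid.values, index=panel["locus_id"].values, name="midpoint")


def read_locus_panel(path: str | Path, strict_length: bool = False) -> pd.DataFrame:
    """Read a locus panel from BED (3-4 columns, no header) or TSV (header).

    BED names become locus ids; unnamed BED records get ``chrom:start-end``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("locus_id"):
        panel = pd.read_csv(path, sep="\t")
    else:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
                rows.append((name, parts[0], start, end))
        panel = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])
    return validate_locus_panel(panel, strict_length=strict_length)


def write_locus_panel(panel: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write a panel as TSV (full schema) or 4-column BED."""
    path = Path(path)
    if fmt == "tsv":
        panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        panel[["chrom", "start", "end", "locus_id"]].to_csv(
            path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown panel format {fmt!r}")


# ---------------------------------------------------------------------------
# Chromatin trace tables
# ---------------------------------------------------------------------------

def validate_traces(traces: pd.DataFrame, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check ChromatinTraceTable invariants.

    ``(cell_id, locus_id, homolog)`` must be unique, coordinates finite,
    genotypes in {WT, KO, NA}, and (when a panel is given) every locus_id
    must exist in the companion panel.
    """
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns and c != "score"]
    if missing:
        raise ValidationError(f"trace table missing columns: {missing}")
    traces = traces.copy()
    if "score" not in traces.columns:
        traces["score"] = np.nan
    key = ["cell_id", "locus_id", "homolog"]
    dup_mask = traces.duplicated(key, keep=False)
    if dup_mask.any():
        offender = traces.loc[dup_mask, key].iloc[0].tolist()
        n_dup = int(traces.duplicated(key).sum())
        raise ValidationError(
            f"{n_dup} duplicated (cell_id, locus_id, homolog) rows, e.g. {offender}")
    coords = traces[["x", "y", "z"]].to_numpy(float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite spatial coordinates in trace table")
    if (traces["homolog"].to_numpy() < 0).any():
        raise ValidationError("homolog indices must be >= 0")
    bad_gt = set(traces["genotype"].unique()) - set(GENOTYPES)
    if bad_gt:
        raise ValidationError(f"unknown genotype values: {sorted(bad_gt)}")
    if panel is not None:
        unknown = sorted(set(traces["locus_id"]) - set(panel["locus_id"]))
        if unknown:
            raise ValidationError(f"locus_ids absent from panel: {unknown[:10]}")
    return traces[TRACE_COLUMNS]


def read_traces(path: str | Path, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a chromatin trace table from CSV and validate it."""
    traces = pd.read_csv(path)
    return validate_traces(traces, panel=panel)


def write_traces(traces: pd.DataFrame, path: str | Path) -> None:
    traces[TRACE_COLUMNS].to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check ExpressionTable invariants (unique gene ids, counts >= 0)."""
    missing = [c for c in EXPRESSION_KEY_COLUMNS if c not in expr.columns]
    if missing:
        raise ValidationError(f"expression table missing columns: {missing}")
    if expr["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in expression table")
    count_cols = [c for c in expr.columns if c not in EXPRESSION_KEY_COLUMNS]
    if not count_cols:
        raise ValidationError("expression table has no count columns")
    if (expr[count_cols].to_numpy(float) < 0).any():
        raise ValidationError("negative counts in expression table")
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    return validate_expression(pd.read_csv(path, sep="\t"))


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ATAC peak tables
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read ATAC peaks from BED: chrom, start, end, [signal], [cell_type]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            signal = float(parts[3]) if len(parts) > 3 else 1.0
            cell_type = parts[4] if len(parts) > 4 else "all"
            rows.append((parts[0], int(parts[1]), int(parts[2]), signal, cell_type))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "signal", "cell_type"])
    if (peaks["start"] >= peaks["end"]).any():
        raise ValidationError("peak with start >= end")
    if (peaks["signal"] < 0).any():
        raise ValidationError("negative peak signal")
    return peaks.sort_values(["cell_type", "chrom", "start"], kind="stable").reset_index(drop=True)
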