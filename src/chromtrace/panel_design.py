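"""Genome-wide locus selection, probe-window filters, super-enhancer calling.

The imaging panel consists of fixed 20-kb genomic segments.  Genome-wide loci
are placed on an even ~2.5-Mb grid per chromosome (the Y chromosome is
excluded).  Each candidate segment must support enough 42-nt encoding-probe
target windows (GC 40-60%, Tm 57-67 C, non-overlapping) to be retained.
Cell type-specific super-enhancer loci are called from ATAC peaks by TSS
exclusion, 12.5-kb stitching, the ROSE tangent-slope-1 rank cutoff, and a
cross-cell-type merge with an overlap-ratio filter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

from .io_core import LOCUS_WIDTH, log, validate_locus_panel

PROBE_LENGTH = 42
GC_RANGE = (0.40, 0.60)
TM_RANGE_C = (57.0, 67.0)
# Nearest-neighbor Tm reference conditions: 50 mM Na+, 250 nM oligo.  At
# molar salt a 42-mer with 40-60% GC always melts above 67 C, which would
# empty the selection band, so the standard low-salt reference is used.
TM_SALT_MM = 50.0
TM_OLIGO_NM = 250.0

STITCH_GAP_BP = 12_500
TSS_EXCLUSION_BP = 2_500
MERGE_WINDOW_BP = 100_000
MIN_OVERLAP_RATIO = 0.8
MIN_MERGED_LENGTH_BP = 15_000


def select_genomewide_loci(chrom_sizes: dict[str, int],
                           spacing: float = 2_500_000.0,
                           locus_width: int = LOCUS_WIDTH) -> pd.DataFrame:
    """Evenly spaced fixed-width loci per chromosome, excluding chrY.

    Locus *k* on a chromosome is centred at ``k * spacing`` and clipped to
    the chromosome bounds; the per-chromosome count is
    ``floor((size - locus_width) / spacing) + 1``.  Chromosomes shorter than
    one locus are skipped with a warning.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if chrom.lstrip("chr").upper() == "Y":
            continue
        if size < locus_width:
            log.warning("chromosome %s (%d bp) shorter than locus width; skipped",
                        chrom, size)
            continue
        n_loci = int((size - locus_width) // spacing) + 1
        for k in range(n_loci):
            start = int(np.clip(k * spacing - locus_width / 2, 0, size - locus_width))
            rows.append((f"{chrom}_L{k:04d}", chrom, start, start + locus_width,
                         "genome_wide"))
    panel = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end",
                                        "panel_group"])
    return validate_locus_panel(panel)


# ---------------------------------------------------------------------------
# Probe windows
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProbeWindow:
    start: int          # offset within the locus sequence
    end: int            # start + 42
    gc_frac: float
    tm: float           # degrees C


@dataclasses.dataclass
class ProbeDesignResult:
    windows: list[ProbeWindow]
    n_candidates: int   # windows passing filters before overlap removal
    kept: bool          # locus retained (len(windows) >= min_probes)


def probe_tm(sequence: str) -> float:
    """Nearest-neighbor melting temperature at the fixed reference conditions."""
    return float(MeltingTemp.Tm_NN(Seq(sequence), Na=TM_SALT_MM,
                                   dnac1=TM_OLIGO_NM, dnac2=0.0))


def design_probe_windows(sequence: str, min_probes: int = 50) -> ProbeDesignResult:
    """Score all 42-nt windows of a locus sequence and select probe targets.

    Windows containing N are rejected; surviving windows must have GC
    fraction in [0.40, 0.60] and nearest-neighbor Tm in [57, 67] C.
    Non-overlapping windows are then chosen greedily left to right.  The
    locus is flagged ``kept=False`` when fewer than ``min_probes`` windows
    survive.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n = len(seq)
    passing: list[ProbeWindow] = []
    for start in range(0, n - PROBE_LENGTH + 1):
        window = seq[start:start + PROBE_LENGTH]
        if "N" in window:
            continue
        gc = (window.count("G") + window.count("C")) / PROBE_LENGTH
        if not GC_RANGE[0] <= gc <= GC_RANGE[1]:
            continue
        tm = probe_tm(window)
        if not TM_RANGE_C[0] <= tm <= TM_RANGE_C[1]:
            continue
        passing.append(ProbeWindow(start, start + PROBE_LENGTH, gc, tm))
    selected: list[ProbeWindow] = []
    cursor = -1
    for win in passing:  # already in left-to-right order
        if win.start > cursor:
            selected.append(win)
            cursor = win.end - 1
    return ProbeDesignResult(windows=selected, n_candidates=len(passing),
                             kept=len(selected) >= min_probes)


# ---------------------------------------------------------------------------
# Super-enhancer calling
# ---------------------------------------------------------------------------

def _exclude_near_tss(peaks: pd.DataFrame, tss: pd.DataFrame,
                      max_dist: float = TSS_EXCLUSION_BP) -> pd.DataFrame:
    """Drop peaks with any point within ``max_dist`` of a TSS."""
    keep = np.ones(len(peaks), dtype=bool)
    for i, row in enumerate(peaks.itertuples(index=False)):
        near = tss[tss["chrom"] == row.chrom]
        if len(near) == 0:
            continue
        pos = near["tss"].to_numpy(float)
        # distance from a point to the half-open interval [start, end)
        dist = np.maximum(row.start - pos, pos - (row.end - 1))
        dist = np.maximum(dist, 0)
        if (dist <= max_dist).any():
            keep[i] = False
    return peaks.loc[keep].reset_index(drop=True)


def stitch_peaks(peaks: pd.DataFrame, gap: float = STITCH_GAP_BP) -> pd.DataFrame:
    """Merge peaks whose nearest edges are within ``gap`` bp (per chromosome).

    Returns stitched regions with the summed signal of member peaks.
    Stitching is idempotent: re-stitching the output is a no-op.
    """
    rows = []
    for chrom, group in peaks.sort_values("start").groupby("chrom", sort=True):
        start = end = signal = None
        for row in group.itertuples(index=False):
            if start is None:
                start, end, signal = row.start, row.end, row.signal
            elif row.start - end <= gap:
                end = max(end, row.end)
                signal += row.signal
            else:
                rows.append((chrom, start, end, signal))
                start, end, signal = row.start, row.end, row.signal
        if start is not None:
            rows.append((chrom, start, end, signal))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


def rose_cutoff(signals: np.ndarray) -> float:
    """Signal threshold by the ROSE tangent rule on the scaled rank curve.

    Signals are ranked ascending and both rank and signal are min-max scaled
    to [0, 1]; the cutoff is the signal at the first point (left to right)
    where the forward slope of the scaled curve exceeds 1.  Regions with
    signal strictly above the returned threshold are super-enhancers.
    """
    signals = np.sort(np.asarray(signals, dtype=float))
    n = len(signals)
    if n == 0:
        return np.inf
    if n == 1 or signals[-1] == signals[0]:
        return signals[0] - 1.0  # keep everything: no curve to cut
    x = np.arange(n) / (n - 1)
    y = (signals - signals[0]) / (signals[-1] - signals[0])
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes > 1.0)
    if len(above) == 0:
        return signals[0] - 1.0
    return float(signals[above[0]])


def _iterative_merge(regions: pd.DataFrame, window: float = MERGE_WINDOW_BP) -> pd.DataFrame:
    """Iteratively merge regions within ``window`` bp until a fixed point.

    Each output row carries the list of member (start, end) intervals from
    the input, used downstream for the overlap-ratio filter.
    """
    current = [(r.chrom, r.start, r.end, [(r.start, r.end)], [r.cell_type])
               for r in regions.itertuples(index=False)]
    for _ in range(max(len(current), 1)):
        current.sort(key=lambda t: (t[0], t[1]))
        merged: list = []
        changed = False
        for item in current:
            if merged and item[0] == merged[-1][0] and item[1] - merged[-1][2] <= window:
                prev = merged[-1]
                merged[-1] = (prev[0], prev[1], max(prev[2], item[2]),
                              prev[3] + item[3], prev[4] + item[4])
                changed = True
            else:
                merged.append(item)
        current = merged
        if not changed:
            break
    return pd.DataFrame(
        [(c, s, e, members, cts) for c, s, e, members, cts in current],
        columns=["chrom", "start", "end", "members", "cell_types"])


def call_super_enhancers(peaks: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Call merged cell type-specific super-enhancer loci from ATAC peaks.

    Per cell type: peaks within 2.5 kb of a TSS are excluded, the remainder
    stitched at a 12.5-kb gap, and stitched regions above the ROSE cutoff
    kept.  Across cell types, super-enhancers within 100 kb are merged
    iteratively to a fixed point; merged regions are retained when the mean
    member-length / merged-length ratio is >= 0.8 and the merged length
    exceeds 15 kb.

    ``peaks`` needs columns chrom/start/end/signal/cell_type; ``tss`` needs
    chrom/tss.  An empty peak table yields an empty result.
    """
    per_type = []
    for cell_type, group in peaks.groupby("cell_type", sort=True):
        kept = _exclude_near_tss(group.reset_index(drop=True), tss)
        stitched = stitch_peaks(kept)
        if len(stitched) == 0:
            continue
        cutoff = rose_cutoff(stitched["signal"].to_numpy())
        ses = stitched[stitched["signal"] > cutoff].copy()
        ses["cell_type"] = cell_type
        per_type.append(ses)
    if not per_type:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "cell_types"])
    all_ses = pd.concat(per_type, ignore_index=True)
    merged = _iterative_merge(all_ses)
    rows = []
    for row in merged.itertuples(index=False):
        merged_len = row.end - row.start
        ratios = [(e - s) / merged_len for s, e in row.members]
        if np.mean(ratios) >= MIN_OVERLAP_RATIO and merged_len > MIN_MERGED_LENGTH_BP:
            rows.append((row.chrom, row.start, row.end, float(np.mean(ratios)),
                         ",".join(sorted(set(row.cell_types)))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "cell_types"])
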