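"""Constant-weight error-correcting barcode construction, assignment, decoding.

MERFISH identifies each locus (or RNA species) by a binary barcode read out
over sequential imaging rounds.  Barcodes are drawn from a constant-weight
code: every codeword has exactly ``w`` on-bits and every pair of codewords is
at Hamming distance >= 4, which permits single-bit error correction.

For constant-weight words the pairwise Hamming distance is ``2 * (w - o)``
where ``o`` is the on-bit overlap, so a minimum distance of ``2d`` is
equivalent to forbidding any shared on-bit subset of size ``w - d + 1``.
The randomized-greedy construction exploits this: it tracks the set of used
forbidden subsets and accepts a shuffled candidate iff none of its forbidden
subsets has been consumed, which makes each acceptance test O(1).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd


class CodeCapacityError(RuntimeError):
    """The greedy construction could not reach the requested code size."""


@dataclasses.dataclass
class Codebook:
    """A constant-weight code and an optional locus -> codeword assignment.

    ``codewords`` is an (n_words, n_bits) uint8 array; ``assignment`` maps
    locus_id -> row index into ``codewords``.
    """

    n_bits: int
    weight: int
    min_hd: int
    codewords: np.ndarray
    assignment: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codewords = np.asarray(self.codewords, dtype=np.uint8)
        if self.codewords.ndim != 2 or self.codewords.shape[1] != self.n_bits:
            raise ValueError("codewords must be (n_words, n_bits)")
        if (self.codewords.sum(axis=1) != self.weight).any():
            raise ValueError(f"every codeword must have weight {self.weight}")
        if len(self.assignment) != len(set(self.assignment.values())):
            raise ValueError("assignment must be injective")

    def __len__(self) -> int:
        return len(self.codewords)

    def verify_min_distance(self) -> int:
        """Exhaustively verify the pairwise minimum Hamming distance.

        Returns the realized minimum distance; raises if it is below
        ``min_hd``.
        """
        words = self.codewords.astype(np.int32)
        overlap = words @ words.T
        np.fill_diagonal(overlap, -1)
        max_overlap = int(overlap.max()) if len(words) > 1 else -1
        realized = 2 * (self.weight - max_overlap) if max_overlap >= 0 else 2 * self.n_bits
        if realized < self.min_hd:
            raise ValueError(f"minimum pairwise distance {realized} < {self.min_hd}")
        return realized

    def barcode_strings(self) -> list[str]:
        """Codewords as bit-strings, MSB = bit 1."""
        return ["".join(map(str, row)) for row in self.codewords]

    def to_frame(self) -> pd.DataFrame:
        """Assignment table: locus_id, barcode bit-string, on-bit indices."""
        rows = []
        for locus, idx in sorted(self.assignment.items()):
            word = self.codewords[idx]
            on_bits = ";".join(str(b) for b in np.flatnonzero(word))
            rows.append((locus, "".join(map(str, word)), on_bits))
        return pd.DataFrame(rows, columns=["locus_id", "barcode", "on_bits"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, min_hd: int = 4) -> "Codebook":
        frame = pd.read_csv(path, dtype={"barcode": str})
        words = np.array([[int(c) for c in b] for b in frame["barcode"]], dtype=np.uint8)
        n_bits = words.shape[1]
        weight = int(words[0].sum())
        assignment = {locus: i for i, locus in enumerate(frame["locus_id"])}
        return cls(n_bits=n_bits, weight=weight, min_hd=min_hd,
                   codewords=words, assignment=assignment)


def enumerate_weight_words(n_bits: int, w: int) -> np.ndarray:
    """All C(n_bits, w) constant-weight words in lexicographic order.

    Returned as an (n_words, w) int array of on-bit indices (ascending per
    row); lexicographic order of the index tuples coincides with descending
    numeric order of the MSB-first bit strings, matching itertools.
    """
    if not 0 < w <= n_bits:
        raise ValueError(f"need 0 < w <= n_bits, got w={w}, n_bits={n_bits}")
    return np.array(list(combinations(range(n_bits), w)), dtype=np.int64)


def onbits_to_matrix(onbits: np.ndarray, n_bits: int) -> np.ndarray:
    """Expand (n_words, w) on-bit indices into a dense (n_words, n_bits) 0/1 array."""
    words = np.zeros((len(onbits), n_bits), dtype=np.uint8)
    rows = np.repeat(np.arange(len(onbits)), onbits.shape[1])
    words[rows, onbits.ravel()] = 1
    return words


def _greedy_code(onbits: np.ndarray, forbid_size: int, rng: np.random.Generator) -> np.ndarray:
    """One greedy pass over a shuffled candidate list.

    A candidate conflicts with the accepted set iff it shares an on-bit subset
    of size ``forbid_size`` with any accepted word.
    """
    order = rng.permutation(len(onbits))
    used: set[tuple[int, ...]] = set()
    accepted: list[int] = []
    for idx in order:
        word = tuple(onbits[idx])
        subs = list(combinations(word, forbid_size))
        if any(s in used for s in subs):
            continue
        used.update(subs)
        accepted.append(idx)
    return np.array(sorted(accepted), dtype=np.int64)


def build_code(n_bits: int, w: int, min_hd: int = 4, target_size: int | None = None,
               restarts: int = 20, seed: int = 0) -> Codebook:
    """Randomized-greedy constant-weight code construction.

    Shuffles the full enumeration of weight-``w`` words and greedily accepts
    words at Hamming distance >= ``min_hd`` to all accepted words, keeping the
    largest code over ``restarts`` shuffles.  The pairwise distance is
    verified exhaustively before returning.

    Raises :class:`CodeCapacityError` if the best code over all restarts is
    smaller than ``target_size``.
    """
    if min_hd % 2 != 0 or min_hd > 2 * w:
        raise ValueError("min_hd must be even and <= 2*w for constant-weight codes")
    forbid_size = w - min_hd // 2 + 1
    onbits = enumerate_weight_words(n_bits, w)
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best: np.ndarray | None = None
    for child in seeds:
        accepted = _greedy_code(onbits, forbid_size, np.random.default_rng(child))
        if best is None or len(accepted) > len(best):
            best = accepted
    assert best is not None
    if target_size is not None and len(best) < target_size:
        raise CodeCapacityError(
            f"capacity not reached: best size {len(best)} < target {target_size} "
            f"after {restarts} restarts")
    book = Codebook(n_bits=n_bits, weight=w, min_hd=min_hd,
                    codewords=onbits_to_matrix(onbits[best], n_bits))
    book.verify_min_distance()
    return book


# ---------------------------------------------------------------------------
# Barcode assignment
# ---------------------------------------------------------------------------

def _same_bit_gaps(onbit_lists: list[np.ndarray], midpoints: np.ndarray,
                   n_bits: int) -> np.ndarray:
    """Gaps between genomically consecutive loci sharing an on-bit.

    ``onbit_lists[i]`` holds the on-bit indices of the barcode assigned to the
    i-th locus of one chromosome (loci in genomic order).
    """
    per_bit: dict[int, list[float]] = {}
    for i, bits in enumerate(onbit_lists):
        for b in bits:
            per_bit.setdefault(int(b), []).append(midpoints[i])
    gaps: list[float] = []
    for positions in per_bit.values():
        if len(positions) > 1:
            pos = np.sort(np.asarray(positions))
            gaps.extend(np.diff(pos))
    return np.asarray(gaps, dtype=float)


def _gap_objective(gaps: np.ndarray) -> tuple[float, float]:
    """(min gap, -CV of gaps); larger is better lexicographically."""
    if len(gaps) == 0:
        return (np.inf, 0.0)
    mean = gaps.mean()
    cv = gaps.std() / mean if mean > 0 else np.inf
    return (float(gaps.min()), -float(cv))


def assign_barcodes(panel: pd.DataFrame, codebook: Codebook, seed: int = 0,
                    n_restarts: int = 4, max_passes: int = 50) -> Codebook:
    """Assign codewords to panel loci, balancing bit usage then spreading bits.

    Stage 1 assigns, per chromosome and locus, the available codeword that
    minimizes the maximum per-bit load (ties by total load of its on-bits,
    then lexicographically), so per-bit usage counts stay within one of each
    other wherever combinatorially feasible.  Stage 2 performs within-
    chromosome swaps of assigned barcodes, accepting a swap iff it strictly
    improves (min same-bit genomic gap, -CV of same-bit gaps), to a fixed
    point; the best of ``n_restarts`` shuffled starts is kept.

    Returns a new :class:`Codebook` sharing the codewords with ``assignment``
    filled in.
    """
    n_loci = len(panel)
    if len(codebook) < n_loci:
        raise ValueError(f"{len(codebook)} codewords < {n_loci} loci")
    words_onbits = [np.flatnonzero(w) for w in codebook.codewords]
    rng = np.random.default_rng(seed)

    # Stage 1: greedy bit balancing over a seed-shuffled candidate order.
    bit_load = np.zeros(codebook.n_bits, dtype=np.int64)
    available = list(rng.permutation(len(codebook)))
    assignment: dict[str, int] = {}
    per_chrom: dict[str, list[tuple[int, float]]] = {}  # chrom -> [(word_idx, midpoint)]
    panel_sorted = panel.sort_values(["chrom", "start"], kind="stable")
    for chrom, group in panel_sorted.groupby("chrom", sort=False):
        chosen: list[tuple[int, float]] = []
        for _, row in group.iterrows():
            best_key, best_pos = None, None
            for pos, widx in enumerate(available):
                bits = words_onbits[widx]
                new_max = max(int(bit_load[b]) + 1 for b in bits)
                key = (new_max, int(bit_load[bits].sum()), tuple(bits))
                if best_key is None or key < best_key:
                    best_key, best_pos = key, pos
            widx = available.pop(best_pos)
            bit_load[words_onbits[widx]] += 1
            assignment[row["locus_id"]] = widx
            chosen.append((widx, (row["start"] + row["end"]) / 2.0))
        per_chrom[chrom] = chosen

    # Stage 2: within-chromosome swap local search on (min gap, -CV).
    for chrom, group in panel_sorted.groupby("chrom", sort=False):
        locus_ids = group["locus_id"].tolist()
        mids = ((group["start"] + group["end"]) / 2.0).to_numpy(float)
        n = len(locus_ids)
        if n < 2:
            continue
        base = [assignment[lid] for lid in locus_ids]
        best_perm, best_obj = None, None
        for restart in range(n_restarts):
            perm = list(base) if restart == 0 else list(rng.permutation(base))
            onbit_lists = [words_onbits[w] for w in perm]
            obj = _gap_objective(_same_bit_gaps(onbit_lists, mids, codebook.n_bits))
            for _ in range(max_passes):
                improved = False
                for i in range(n):
                    for j in range(i + 1, n):
                        perm[i], perm[j] = perm[j], perm[i]
                        onbit_lists[i], onbit_lists[j] = onbit_lists[j], onbit_lists[i]
                        cand = _gap_objective(
                            _same_bit_gaps(onbit_lists, mids, codebook.n_bits))
                        if cand > obj:
                            obj = cand
                            improved = True
                        else:
                            perm[i], perm[j] = perm[j], perm[i]
                            onbit_lists[i], onbit_lists[j] = onbit_lists[j], onbit_lists[i]
                if not improved:
                    break
            if best_obj is None or obj > best_obj:
                best_obj, best_perm = obj, list(perm)
        for lid, widx in zip(locus_ids, best_perm):
            assignment[lid] = widx

    return Codebook(n_bits=codebook.n_bits, weight=codebook.weight,
                    min_hd=codebook.min_hd, codewords=codebook.codewords,
                    assignment=assignment)


def per_bit_usage(codebook: Codebook) -> np.ndarray:
    """Number of assigned loci reading 1 at each bit."""
    counts = np.zeros(codebook.n_bits, dtype=np.int64)
    for idx in codebook.assignment.values():
        counts += codebook.codewords[idx]
    return counts


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_readout(bits: np.ndarray, codebook: Codebook) -> str | None:
    """Decode a readout bit vector to a locus id, or None.

    Exact codeword matches decode directly; otherwise, if exactly one
    codeword lies at Hamming distance 1, the single-bit error is corrected
    (valid because min_hd >= 4).  Anything else decodes to None.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (codebook.n_bits,):
        raise ValueError(f"expected {codebook.n_bits} bits, got shape {bits.shape}")
    if not codebook.assignment:
        raise ValueError("codebook has no locus assignment to decode against")
    loci = list(codebook.assignment)
    words = codebook.codewords[[codebook.assignment[l] for l in loci]]
    dists = np.abs(words.astype(np.int16) - bits.astype(np.int16)).sum(axis=1)
    exact = np.flatnonzero(dists == 0)
    if len(exact) == 1:
        return loci[exact[0]]
    near = np.flatnonzero(dists == 1)
    if len(near) == 1:
        return loci[near[0]]
    return None
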