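"""Per-contig feature space for insert binning.

Two signals are computed for every contig: canonical (strand-collapsed)
tetranucleotide frequencies — a 136-dimensional compositional fingerprint
of the source genome — and a coverage summary, either averaged over
fixed-width windows of a per-base depth track or taken from the
assembler-reported k-mer coverage in the FASTA header.

Canonicalization collapses each 4-mer with its reverse complement to the
lexicographically smaller of the two, giving (256 - 16) / 2 + 16 = 136
classes. Contigs assemble in arbitrary orientation, so strand-invariant
features are a requirement of the binning use-case, not an optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import Contig, reverse_complement

__all__ = [
    "ContigFeatures",
    "DEFAULT_WINDOW",
    "DEFAULT_COVERAGE_WEIGHT",
    "canonical_tetranucleotide_index",
    "tetranucleotide_frequencies",
    "windowed_coverage_summary",
    "compute_contig_features",
    "build_feature_matrix",
]

DEFAULT_WINDOW = 500
#: Weight applied to the single coverage column so its expected squared
#: contribution to K-means distances matches the whole 136-column
#: composition block (both blocks are per-column standardized first).
DEFAULT_COVERAGE_WEIGHT = float(np.sqrt(136.0))

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp4(kmer: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(kmer))


def canonical_tetranucleotide_index() -> list[str]:
    """Ordered list of the 136 canonical 4-mers.

    Each of the 256 4-mers maps to the lexicographic minimum of itself and
    its reverse complement; the distinct representatives are returned
    sorted, so the ordering is stable across runs and releases.
    """
    reps = {min(k, _revcomp4(k)) for k in _all_4mers()}
    return sorted(reps)


def _all_4mers() -> list[str]:
    return [
        a + b + c + d
        for a in _BASES
        for b in _BASES
        for c in _BASES
        for d in _BASES
    ]


def _build_class_map() -> tuple[np.ndarray, list[str]]:
    """Map 4-mer integer codes (base-4, A=0 C=1 G=2 T=3) to canonical class."""
    index = canonical_tetranucleotide_index()
    class_of = {k: i for i, k in enumerate(index)}
    table = np.empty(256, dtype=np.int64)
    for code, kmer in enumerate(_all_4mers()):
        table[code] = class_of[min(kmer, _revcomp4(kmer))]
    return table, index

_CLASS_OF_CODE, CANONICAL_4MERS = _build_class_map()

# base byte -> code; N (and anything else) -> -1 so windows containing it
# produce a negative window code and are skipped
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i


def tetranucleotide_frequencies(sequence: str) -> np.ndarray:
    """Canonical 4-mer frequency vector of a DNA string.

    A width-4 window slides with step 1; windows containing N are skipped;
    counts accumulate on the 136 canonical classes and are normalized by
    the number of valid windows. Raises if no valid window exists.
    """
    counts, n_valid = tetranucleotide_counts(sequence)
    if n_valid == 0:
        raise ValueError(
            "no valid 4-mer window (sequence shorter than 4 or all windows contain N)"
        )
    return counts / n_valid


def tetranucleotide_counts(sequence: str) -> tuple[np.ndarray, int]:
    """Raw canonical 4-mer counts and the number of valid windows."""
    seq = sequence.upper()
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        return np.zeros(136, dtype=float), 0
    # window code = 64*b0 + 16*b1 + 4*b2 + b3; any N makes it negative
    win = 64 * codes[:-3] + 16 * codes[1:-2] + 4 * codes[2:-1] + codes[3:]
    # negative entries can be any of several sums; mark invalid via each base
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    win = win[valid]
    counts = np.bincount(_CLASS_OF_CODE[win], minlength=136).astype(float)
    return counts, int(win.size)


def windowed_coverage_summary(
    depth: np.ndarray, window_size: int = DEFAULT_WINDOW
) -> tuple[np.ndarray, float]:
    """Mean depth per non-overlapping window, and the mean of window means.

    Windows of ``window_size`` start at position 1. A trailing remainder
    shorter than half a window is merged into the previous window
    (avoiding high-variance tiny windows); a remainder of at least half a
    window stands alone. Contigs shorter than one window form a single
    window.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = depth.size
    n_full = n // window_size
    remainder = n - n_full * window_size
    if n_full == 0:
        bounds = [(0, n)]
    else:
        bounds = [(i * window_size, (i + 1) * window_size) for i in range(n_full)]
        if remainder:
            if remainder < window_size / 2:
                lo, _ = bounds[-1]
                bounds[-1] = (lo, n)
            else:
                bounds.append((n_full * window_size, n))
    means = np.array([depth[lo:hi].mean() for lo, hi in bounds])
    return means, float(means.mean())


@dataclass
class ContigFeatures:
    """Feature bundle for one contig: composition + coverage summary."""

    contig_id: str
    tetra: np.ndarray  # 136 canonical 4-mer frequencies
    coverage_summary: float
    n_valid_windows: int  # 4-mer windows counted
    coverage_source: str  # "depth" | "header" | "simulated"
    length: int = 0

    def __post_init__(self) -> None:
        self.tetra = np.asarray(self.tetra, dtype=float)
        if self.tetra.shape != (136,):
            raise ValueError("tetra vector must have dimension 136")
        if self.coverage_summary < 0:
            raise ValueError("coverage_summary must be non-negative")
        if self.coverage_source not in ("depth", "header", "simulated"):
            raise ValueError(f"bad coverage_source {self.coverage_source!r}")


def compute_contig_features(
    contig: Contig,
    window_size: int = DEFAULT_WINDOW,
    coverage_source: Optional[str] = None,
) -> ContigFeatures:
    """Features for one contig.

    Coverage precedence: a per-base depth track, when attached, wins over
    the assembler header scalar; with neither, an error is raised. Pass
    ``coverage_source="simulated"`` to label depth tracks produced by the
    pool simulator.
    """
    tetra = tetranucleotide_frequencies(contig.sequence)
    _, n_valid = tetranucleotide_counts(contig.sequence)
    if contig.depth is not None:
        _, summary = windowed_coverage_summary(contig.depth, window_size)
        source = coverage_source or "depth"
    elif contig.header_coverage is not None:
        summary = float(contig.header_coverage)
        source = coverage_source or "header"
    else:
        raise ValueError(
            f"contig {contig.id!r}: no coverage available "
            "(neither depth track nor header coverage)"
        )
    return ContigFeatures(
        contig_id=contig.id,
        tetra=tetra,
        coverage_summary=summary,
        n_valid_windows=n_valid,
        coverage_source=source,
        length=len(contig),
    )


def _zscore_columns(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    out = np.zeros_like(mat)
    nz = sd > 0
    out[:, nz] = (mat[:, nz] - mean[nz]) / sd[nz]
    return out


def build_feature_matrix(
    features: Sequence[ContigFeatures],
    coverage_weight: float = DEFAULT_COVERAGE_WEIGHT,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the n x 137 clustering matrix.

    Columns 1-136 are per-column z-scored tetranucleotide frequencies
    (zero-variance columns become 0); column 137 is the z-scored
    log2(1 + coverage) scaled by ``coverage_weight``. Coverage spans
    orders of magnitude across inserts, so the log transform keeps the
    K-means geometry sane. Row order follows the input.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 contigs to build a feature matrix")
    tetra = np.vstack([f.tetra for f in features])
    cov = np.array([f.coverage_summary for f in features], dtype=float)
    cov_col = _zscore_columns(np.log2(1.0 + cov)[:, None]) * coverage_weight
    mat = np.hstack([_zscore_columns(tetra), cov_col])
    columns = list(CANONICAL_4MERS) + ["coverage"]
    return mat, columns
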