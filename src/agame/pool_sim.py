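"""Synthetic pooled-insert data and the FosBin fragmentation benchmark.

Real pooled functional-metagenomics benchmarks start from clone inserts
whose origin is known (barcoded single-insert assemblies). Here those are
replaced by synthetic inserts sampled from per-source order-2 Markov
chains with Dirichlet(alpha=1) transition rows: each "source genome" gets
its own compositional signature, controllably distinct between sources
and shared by all inserts drawn from the same source. A pool is built by
drawing inserts from a panel of sources, fragmenting each insert into a
fixed number of contigs at uniform random breakpoints, and simulating a
per-base Poisson depth track with one depth rate per insert.

The benchmark grid mirrors the study design for evaluating clone
deconvolution: pools of 8, 12 or 18 inserts, fragmented into 2, 3 or 5
contigs each, 100 independent replicates per cell, clustered with k =
pool size, and scored with binning sensitivity/specificity. Two coverage
modes are compared: ``uniform`` (one depth rate per insert drawn from
Uniform(20, 100)) and ``multiplied`` (the same rate additionally scaled
by a random factor from {2, 4, 8, 16}, emulating deliberately unequal
insert concentrations).

Pools draw their inserts round-robin from a fixed panel of source
genomes (default 6), so larger pools recruit more clones per source.
Clones of one source share its compositional signature and only the
coverage channel can separate them — the regime the multiplied-coverage
mode is designed to help with, and the reason deconvolution gets harder
as pools grow. Real libraries show the same structure in miniature
(overlapping clones from a single genome occur). Being synthetic, none
of this reproduces any published benchmark's numeric values; it
reproduces the *design* so the method's qualitative behavior can be
checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .core_io import Contig, EndTag
from .features import (
    DEFAULT_COVERAGE_WEIGHT,
    DEFAULT_WINDOW,
    build_feature_matrix,
    compute_contig_features,
)
from .fosbin import binning_sensitivity, binning_specificity, fosbin_bin

__all__ = [
    "PoolSpec",
    "SourceInsert",
    "generate_source_inserts",
    "fragment_insert",
    "simulate_coverage",
    "simulate_pool",
    "pool_feature_matrix",
    "run_benchmark",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF_BYTE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BYTE[_b] = _i


@dataclass(frozen=True)
class PoolSpec:
    """Study conditions for the pool-fragmentation benchmark."""

    pool_sizes: tuple[int, ...] = (8, 12, 18)
    fragments_per_insert: tuple[int, ...] = (2, 3, 5)
    n_replicates: int = 100
    coverage_modes: tuple[str, ...] = ("uniform", "multiplied")
    multipliers: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
    seed: int = 7
    min_fragment_length: int = 500
    insert_length_mean: float = 33000.0
    insert_length_sd: float = 5000.0
    insert_length_bounds: tuple[float, float] = (10000.0, 45000.0)
    source_panel_size: int = 6
    tag_length: int = 700
    tag_error_rate: float = 0.005
    base_depth_range: tuple[float, float] = (20.0, 100.0)
    window_size: int = DEFAULT_WINDOW
    coverage_weight: float = DEFAULT_COVERAGE_WEIGHT
    kmeans_restarts: int = 25

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.pool_sizes):
            raise ValueError("pool sizes must be >= 2")
        if any(f < 1 for f in self.fragments_per_insert):
            raise ValueError("fragments_per_insert must be >= 1")
        if "multiplied" in self.coverage_modes and not self.multipliers:
            raise ValueError("multiplied mode needs a non-empty multiplier set")
        lo, hi = self.insert_length_bounds
        if not lo < hi:
            raise ValueError("insert length bounds must satisfy lo < hi")
        if self.min_fragment_length * max(self.fragments_per_insert) > lo:
            raise ValueError(
                "min_fragment_length x fragments may exceed the shortest insert"
            )
        if self.source_panel_size < 1:
            raise ValueError("source_panel_size must be >= 1")


@dataclass(frozen=True)
class SourceInsert:
    insert_id: str
    source_id: str
    sequence: str
    tags: tuple[EndTag, EndTag]


@njit(cache=False)
def _markov_sample(cum_rows: np.ndarray, uniforms: np.ndarray, b0: int, b1: int) -> np.ndarray:
    """Sample an order-2 chain; cum_rows is the (16, 4) cumulative
    transition matrix, one output base per uniform draw."""
    n = uniforms.shape[0] + 2
    out = np.empty(n, dtype=np.int8)
    out[0] = b0
    out[1] = b1
    for i in range(2, n):
        state = out[i - 2] * 4 + out[i - 1]
        r = uniforms[i - 2]
        b = 0
        while b < 3 and r > cum_rows[state, b]:
            b += 1
        out[i] = b
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes.astype(np.intp)].tobytes().decode("ascii")


def _truncated_normal_length(spec: PoolSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.insert_length_bounds
    for _ in range(10000):
        x = rng.normal(spec.insert_length_mean, spec.insert_length_sd)
        if lo <= x <= hi:
            return int(round(x))
    raise RuntimeError("insert length truncation bounds rejected 10000 draws")


def _mutate_tag(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    hit = rng.random(codes.shape[0]) < rate
    if hit.any():
        codes = codes.copy()
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes[hit] = (codes[hit] + shift) % 4
    return codes


def generate_source_inserts(
    n_sources: int,
    inserts_per_source: int,
    spec: PoolSpec,
    rng: np.random.Generator,
    counts: Optional[Sequence[int]] = None,
) -> list[SourceInsert]:
    """Synthesize source genomes and sample inserts with end-tags.

    Each source is an order-2 Markov chain whose 16 transition rows are
    independent Dirichlet(1) draws; inserts sampled from one source share
    its compositional signature. End-tags are the first and last
    ``tag_length`` bases with Sanger-like substitution errors applied.
    ``counts`` overrides ``inserts_per_source`` with a per-source number
    of inserts. Fully deterministic given ``rng``.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if counts is None:
        counts = [inserts_per_source] * n_sources
    if len(counts) != n_sources:
        raise ValueError("counts must have one entry per source")
    out: list[SourceInsert] = []
    for s in range(n_sources):
        rows = rng.dirichlet(np.ones(4), size=16)
        cum = np.cumsum(rows, axis=1)
        cum[:, -1] = 1.0  # guard against cumulative round-off
        for j in range(counts[s]):
            length = _truncated_normal_length(spec, rng)
            b0, b1 = rng.integers(0, 4, size=2)
            codes = _markov_sample(cum, rng.random(length - 2), int(b0), int(b1))
            seq = _codes_to_str(codes)
            tag_l = _mutate_tag(
                codes[: spec.tag_length], spec.tag_error_rate, rng
            )
            tag_r = _mutate_tag(
                codes[-spec.tag_length:], spec.tag_error_rate, rng
            )
            insert_id = f"s{s}i{j}"
            out.append(
                SourceInsert(
                    insert_id=insert_id,
                    source_id=f"s{s}",
                    sequence=seq,
                    tags=(
                        EndTag(insert_id, "L", _codes_to_str(tag_l)),
                        EndTag(insert_id, "R", _codes_to_str(tag_r)),
                    ),
                )
            )
    return out


def fragment_insert(
    insert: SourceInsert | str,
    n_fragments: int,
    min_len: int,
    rng: np.random.Generator,
    insert_id: Optional[str] = None,
) -> list[Contig]:
    """Cut an insert into ``n_fragments`` contigs at random breakpoints.

    Breakpoints are uniform over positions subject to every fragment
    being at least ``min_len``, realized by rejection sampling. Fragments
    partition the insert exactly; contig ids are ``<insert_id>.f<k>``.
    """
    if isinstance(insert, SourceInsert):
        seq, iid = insert.sequence, insert.insert_id
    else:
        seq, iid = insert, insert_id or "insert"
    L = len(seq)
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if n_fragments * min_len > L:
        raise ValueError(
            f"cannot cut {L} bp into {n_fragments} fragments of >= {min_len} bp"
        )
    if n_fragments == 1:
        return [Contig(id=f"{iid}.f0", sequence=seq)]
    for _ in range(10000):
        cuts = np.sort(rng.integers(1, L, size=n_fragments - 1))
        bounds = np.concatenate(([0], cuts, [L]))
        if np.diff(bounds).min() >= min_len:
            return [
                Contig(id=f"{iid}.f{k}", sequence=seq[bounds[k]:bounds[k + 1]])
                for k in range(n_fragments)
            ]
    raise RuntimeError("breakpoint rejection sampling failed after 10000 attempts")


def simulate_coverage(
    contigs: Sequence[Contig],
    truth: dict[str, str],
    mode: str,
    multipliers: Sequence[float],
    rng: np.random.Generator,
    base_depth_range: tuple[float, float] = (20.0, 100.0),
) -> dict[str, float]:
    """Attach Poisson per-base depth tracks; one depth rate per insert.

    All fragments of an insert share a rate lambda ~ Uniform(lo, hi); in
    ``multiplied`` mode the rate is further scaled by a random choice from
    ``multipliers``. Returns the realized per-insert rates.
    """
    if mode not in ("uniform", "multiplied"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    lo, hi = base_depth_range
    rates: dict[str, float] = {}
    for insert_id in sorted({truth[c.id] for c in contigs}):
        lam = float(rng.uniform(lo, hi))
        if mode == "multiplied":
            lam *= float(multipliers[int(rng.integers(len(multipliers)))])
        rates[insert_id] = lam
    for c in contigs:
        c.depth = rng.poisson(rates[truth[c.id]], size=len(c)).astype(float)
    return rates


def _pool_inserts(
    n_inserts: int, spec: PoolSpec, rng: np.random.Generator
) -> list[SourceInsert]:
    """Draw a pool's inserts round-robin from the source panel."""
    n_sources = min(spec.source_panel_size, n_inserts)
    counts = [
        n_inserts // n_sources + (1 if s < n_inserts % n_sources else 0)
        for s in range(n_sources)
    ]
    return generate_source_inserts(n_sources, 0, spec, rng, counts=counts)


def simulate_pool(
    n_inserts: int,
    n_fragments: int,
    mode: str,
    spec: PoolSpec,
    rng: np.random.Generator,
) -> tuple[list[Contig], dict[str, str], list[SourceInsert]]:
    """One synthetic pool: contigs with depth, truth labels, and inserts."""
    inserts = _pool_inserts(n_inserts, spec, rng)
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    for ins in inserts:
        frags = fragment_insert(ins, n_fragments, spec.min_fragment_length, rng)
        for f in frags:
            truth[f.id] = ins.insert_id
        contigs.extend(frags)
    simulate_coverage(
        contigs, truth, mode, spec.multipliers, rng, spec.base_depth_range
    )
    return contigs, truth, inserts


def pool_feature_matrix(
    contigs: Sequence[Contig], spec: PoolSpec
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix of a simulated pool (rows follow contig order)."""
    feats = [
        compute_contig_features(c, spec.window_size, coverage_source="simulated")
        for c in contigs
    ]
    matrix, _ = build_feature_matrix(feats, spec.coverage_weight)
    return matrix, [c.id for c in contigs]


def _replicate_scores(
    n_inserts: int,
    n_fragments: int,
    spec: PoolSpec,
    rep: int,
    cell_key: tuple[int, int],
) -> dict[str, tuple[float, float]]:
    """Score every coverage mode on one shared replicate pool.

    The pool (inserts, fragmentation) and the per-insert base depth rates
    are drawn once; the ``multiplied`` mode scales those same rates by a
    per-insert random factor — the mode comparison is paired, isolating
    the effect of spreading the coverage values.
    """
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(*cell_key, rep))
    rng = np.random.default_rng(ss)
    inserts = _pool_inserts(n_inserts, spec, rng)
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    for ins in inserts:
        for f in fragment_insert(ins, n_fragments, spec.min_fragment_length, rng):
            truth[f.id] = ins.insert_id
            contigs.append(f)
    lo, hi = spec.base_depth_range
    insert_ids = sorted({truth[c.id] for c in contigs})
    base_rate = {i: float(rng.uniform(lo, hi)) for i in insert_ids}
    factor = {
        i: float(spec.multipliers[int(rng.integers(len(spec.multipliers)))])
        for i in insert_ids
    }
    out: dict[str, tuple[float, float]] = {}
    for mode_index, mode in enumerate(spec.coverage_modes):
        rates = {
            i: base_rate[i] * (factor[i] if mode == "multiplied" else 1.0)
            for i in insert_ids
        }
        mode_ss = np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(*cell_key, rep, mode_index)
        )
        mode_rng = np.random.default_rng(mode_ss)
        for c in contigs:
            c.depth = mode_rng.poisson(rates[truth[c.id]], size=len(c)).astype(float)
        matrix, ids = pool_feature_matrix(contigs, spec)
        kseed = int(mode_ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        assignment = fosbin_bin(
            matrix, k=n_inserts, seed=kseed,
            n_restarts=spec.kmeans_restarts, contig_ids=ids,
        )
        out[mode] = (
            binning_sensitivity(assignment, truth),
            binning_specificity(assignment, truth),
        )
    return out


def run_benchmark(spec: PoolSpec = PoolSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full benchmark grid.

    Returns ``(table, per_replicate)``: the summary table has one row per
    (pool size x fragmentation x coverage mode) cell with means and
    standard deviations of sensitivity and specificity over replicates;
    the second frame carries every replicate's scores. Deterministic
    given ``spec.seed``; each replicate derives an independent child seed
    from (seed, cell, replicate), so any replicate can be reproduced in
    isolation.
    """
    rows = []
    for pi, n_inserts in enumerate(spec.pool_sizes):
        for fi, n_fragments in enumerate(spec.fragments_per_insert):
            for rep in range(spec.n_replicates):
                scores = _replicate_scores(
                    n_inserts, n_fragments, spec, rep, (pi, fi)
                )
                for mode, (sens, sp) in scores.items():
                    rows.append((n_inserts, n_fragments, mode, rep, sens, sp))
    per_rep = pd.DataFrame(
        rows,
        columns=[
            "n_inserts", "n_fragments", "mode", "replicate",
            "sensitivity", "specificity",
        ],
    )
    grouped = per_rep.groupby(["n_inserts", "n_fragments", "mode"], sort=True)
    table = grouped.agg(
        mean_sensitivity=("sensitivity", "mean"),
        mean_specificity=("specificity", "mean"),
        sd_sensitivity=("sensitivity", "std"),
        sd_specificity=("specificity", "std"),
        n_replicates=("replicate", "count"),
    ).reset_index()
    return table, per_rep
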