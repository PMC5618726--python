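"""Stranded paired-end read simulation with Pareto fragment lengths.

Fragments are drawn from a Pareto distribution (scale = minimum fragment,
shape = tail index) and truncated at a maximum insert size by rejection.
Read 2 is the first ``read_length`` bases of the fragment on the forward
strand; read 1 is the reverse complement of the last ``read_length`` bases,
matching a stranded sequencing protocol. Base errors are uniform
substitutions; qualities are a constant phred value.

The simulator serves two purposes: generating the per-allele read sets that
reference k-mer profiles are aggregated from (error-free), and generating
evaluation samples (error rate 0.001, Q30 by convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, List, Optional

import numpy as np

from .sequtils import PHRED_OFFSET, ReadPair, revcomp

logger = logging.getLogger(__name__)

__all__ = ["SimulationParams", "sample_fragment_length", "sample_fragment_lengths", "simulate_read_pairs", "truncated_pareto_cdf"]


@dataclass(frozen=True)
class SimulationParams:
    """Fragment and read model parameters.

    Defaults are the reference-profile simulation settings: 500,000
    error-free pairs of 50 bp reads per allele, Pareto(scale=80, shape=0.7)
    fragments capped at 1,000 bp. Evaluation samples typically override
    ``num_reads`` and set ``error_rate=0.001`` (with Q30 qualities).
    """

    scale: float = 80.0
    shape: float = 0.7
    max_insert: int = 1000
    num_reads: int = 500_000
    read_length: int = 50
    error_rate: float = 0.0
    base_quality: int = 30
    seed: Optional[int] = None

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError("Pareto shape must be > 0")
        if self.read_length > self.max_insert:
            raise ValueError("read_length must not exceed max_insert")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_fragment_lengths(
    n: int, params: SimulationParams, rng: np.random.Generator, upper: Optional[int] = None
) -> np.ndarray:
    """Draw ``n`` integer fragment lengths in ``[read_length, upper]``.

    Pareto draws above ``upper`` (default ``max_insert``) are rejected and
    redrawn; draws below ``read_length`` are clamped up (a fragment must
    hold at least one read). If ``upper`` does not exceed the Pareto scale
    the distribution degenerates to ``upper``.
    """
    if upper is None:
        upper = params.max_insert
    upper = min(upper, params.max_insert)
    if upper <= params.scale:
        return np.full(n, max(upper, params.read_length), dtype=np.int64)
    out = np.empty(n, dtype=np.float64)
    filled = 0
    while filled < n:
        draw = (rng.pareto(params.shape, size=n - filled) + 1.0) * params.scale
        ok = draw[draw <= upper]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    frags = np.floor(out).astype(np.int64)
    return np.clip(frags, params.read_length, upper)


def sample_fragment_length(params: SimulationParams, rng: np.random.Generator) -> int:
    """Single truncated-Pareto fragment draw."""
    return int(sample_fragment_lengths(1, params, rng)[0])


def truncated_pareto_cdf(x, scale: float, shape: float, upper: float):
    """Closed-form CDF of a Pareto(scale, shape) truncated at ``upper``."""
    x = np.asarray(x, dtype=float)
    denom = 1.0 - (scale / upper) ** shape
    cdf = (1.0 - (scale / np.clip(x, scale, None)) ** shape) / denom
    return np.clip(cdf, 0.0, 1.0)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(read: str, n_errors: int, rng: np.random.Generator) -> str:
    arr = bytearray(read, "ascii")
    positions = rng.choice(len(arr), size=n_errors, replace=False)
    for pos in positions:
        current = arr[pos]
        choices = [b for b in _BASES if b != current]
        arr[pos] = int(rng.choice(choices))
    return arr.decode("ascii")


def simulate_read_pairs(
    sequence: str,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    name_prefix: str = "sim",
) -> Iterator[ReadPair]:
    """Simulate ``params.num_reads`` stranded pairs from one sequence.

    Fragment starts are uniform over valid positions; sequences shorter than
    the maximum insert simply resample shorter fragments (rejection upper
    bound = sequence length). Sequences shorter than the read length are
    skipped with a warning.
    """
    if rng is None:
        rng = params.rng()
    L = len(sequence)
    rl = params.read_length
    if L < rl:
        warnings.warn(f"sequence ({L} bp) shorter than read length {rl}; skipped")
        return
    n = params.num_reads
    frags = sample_fragment_lengths(n, params, rng, upper=L)
    starts = rng.integers(0, L - frags + 1)
    qual = chr(params.base_quality + PHRED_OFFSET) * rl
    if params.error_rate > 0:
        n_errors = rng.binomial(2 * rl, params.error_rate, size=n)
    else:
        n_errors = None
    for i in range(n):
        s, f = int(starts[i]), int(frags[i])
        fragment = sequence[s : s + f]
        r2 = fragment[:rl]
        r1 = revcomp(fragment[-rl:])
        if n_errors is not None and n_errors[i] > 0:
            ne = int(n_errors[i])
            # split the pair's error count uniformly over the 2*rl bases
            split = int(rng.integers(0, ne + 1)) if ne > 1 else int(rng.integers(0, 2))
            if ne == 1:
                n1, n2 = (1, 0) if split else (0, 1)
            else:
                n1, n2 = split, ne - split
            n1, n2 = min(n1, rl), min(n2, rl)
            if n1:
                r1 = _apply_errors(r1, n1, rng)
            if n2:
                r2 = _apply_errors(r2, n2, rng)
        yield ReadPair(f"{name_prefix}_{i}", r1, qual, r2, qual)


def simulate_allele_reads(
    record, params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> List[ReadPair]:
    """Materialized pair list for one allele record (convenience wrapper)."""
    return list(
        simulate_read_pairs(record.sequence, params, rng=rng, name_prefix=str(record.name).replace("*", "_"))
    )
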