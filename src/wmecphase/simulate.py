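"""Diploid read simulator with full truth bookkeeping.

Generates a heterozygous haplotype pair and error-bearing reads over it,
in *SNP-column space*: a read is the set of consecutive SNP columns it
covers, its length measured in covered columns, not bases -- the phasing
engine never sees anything between SNPs.  Paired-end fragments are one
read with an internal call-free gap, which exercises the span-active
assignment rule.

Every site is simulated heterozygous (the second haplotype is the bitwise
complement of the first), matching the all-heterozygous benchmark design.
Each call is flipped independently with probability `error_rate`; weights
are either a fixed value or the phred score round(-10*log10(error_rate)).

All randomness flows from a single seed through one generator, with a
fixed sampling order per read: length (and gap for paired ends), start,
source haplotype, then one error draw per covered column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np

from .fragmat_io import Call, Fragment, FragmentMatrix

#: phred weight used when error_rate is 0 (a flip probability of exactly
#: zero has no finite phred score; Q60 is the conventional cap).
_PHRED_CAP = 60


@dataclass
class SimParams:
    """Study-condition knobs of the generator.

    m: number of heterozygous SNP columns.
    coverage: target mean physical (span) coverage per column.
    read_len: mean covered columns per read (geometric lengths).
    paired / mean_gap: simulate paired-end fragments with a call-free gap
        of geometric mean `mean_gap` columns.
    error_rate: per-call allele flip probability, in [0, 0.5).
    weight_mode: 'phred' (round(-10*log10(error_rate)), capped at Q60) or
        'fixed' (every weight = fixed_weight).
    """

    m: int
    coverage: float = 15.0
    read_len: float = 6.0
    paired: bool = False
    mean_gap: float = 2.0
    error_rate: float = 0.01
    weight_mode: str = "phred"
    fixed_weight: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.coverage > 0:
            raise ValueError("coverage must be > 0")
        if not self.read_len >= 1:
            raise ValueError("read_len must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.weight_mode not in ("phred", "fixed"):
            raise ValueError("weight_mode must be 'phred' or 'fixed'")
        if self.weight_mode == "fixed" and not self.fixed_weight > 0:
            raise ValueError("fixed_weight must be positive")


@dataclass
class Truth:
    """Ground truth: the haplotype pair, each read's source haplotype, and
    a per-call error indicator aligned with each fragment's calls."""

    haplotypes: tuple[str, str]
    source: list[int]
    errors: list[tuple[bool, ...]]


def call_weight(params: SimParams) -> float:
    if params.weight_mode == "fixed":
        return float(params.fixed_weight)
    if params.error_rate == 0:
        return float(_PHRED_CAP)
    return float(min(_PHRED_CAP, round(-10.0 * math.log10(params.error_rate))))


def simulate_haplotypes(
    m: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A heterozygous haplotype pair: h1 uniform bits, h2 its complement."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h1 = rng.integers(0, 2, size=m, dtype=np.int8)
    return h1, 1 - h1


def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric draw with the given mean, support {1, 2, ...}."""
    if mean <= 1:
        return 1
    return int(rng.geometric(1.0 / mean))


def simulate_reads(
    haplotypes: tuple[np.ndarray, np.ndarray], params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[FragmentMatrix, Truth]:
    """Sample reads from a haplotype pair.

    Read count is m*coverage / E[span], starts are uniform over positions
    where the whole span fits, so realised mean column coverage tracks the
    target (up to sampling noise).
    """
    h1, h2 = haplotypes
    m = params.m
    if len(h1) != m or len(h2) != m:
        raise ValueError("haplotype length does not match params.m")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    haps = (np.asarray(h1), np.asarray(h2))

    mean_span = params.read_len + (params.mean_gap if params.paired else 0.0)
    n_reads = max(1, round(params.m * params.coverage / mean_span))
    weight = call_weight(params)

    fragments: list[Fragment] = []
    source: list[int] = []
    errors: list[tuple[bool, ...]] = []
    width = len(str(n_reads))
    for i in range(n_reads):
        if params.paired:
            left = _geometric(rng, params.read_len / 2.0)
            right = _geometric(rng, params.read_len / 2.0)
            gap = _geometric(rng, params.mean_gap)
            span = left + gap + right
            if span > m:  # shrink gap first, then the mates, to fit
                gap = max(0, m - left - right)
                span = left + gap + right
                if span > m:
                    left = min(left, max(1, m // 2))
                    right = max(1, m - left - gap) if m - left - gap >= 1 else 0
                    span = left + gap + right
            cols_rel = list(range(left)) + list(range(left + gap, span))
        else:
            span = min(m, _geometric(rng, params.read_len))
            cols_rel = list(range(span))
        start = int(rng.integers(0, m - span + 1))
        src = int(rng.integers(0, 2))
        hap = haps[src]
        calls: list[Call] = []
        errs: list[bool] = []
        for rel in cols_rel:
            col = start + rel
            err = bool(rng.random() < params.error_rate)
            allele = int(hap[col]) ^ int(err)
            calls.append(Call(column=col, allele=allele, weight=weight))
            errs.append(err)
        fragments.append(Fragment(read_id=f"r{i:0{width}d}", calls=tuple(calls)))
        source.append(src)
        errors.append(tuple(errs))

    matrix = FragmentMatrix(fragments=tuple(fragments), num_columns=m)
    truth = Truth(
        haplotypes=("".join(map(str, h1)), "".join(map(str, h2))),
        source=source,
        errors=errors,
    )
    return matrix, truth


def simulate_dataset(params: SimParams) -> tuple[FragmentMatrix, Truth]:
    """Haplotypes + reads from one seed; the one-stop entry point."""
    rng = np.random.default_rng(params.seed)
    haps = simulate_haplotypes(params.m, rng)
    return simulate_reads(haps, params, rng)


# -- truth file dialect ------------------------------------------------------


def write_truth(truth: Truth, read_ids: Iterable[str]) -> str:
    lines = [
        f"#TRUTH v1 m={len(truth.haplotypes[0])}",
        f"#HAP1 {truth.haplotypes[0]}",
        f"#HAP2 {truth.haplotypes[1]}",
    ]
    for rid, src, errs in zip(read_ids, truth.source, truth.errors):
        estr = "".join("1" if e else "0" for e in errs)
        lines.append(f"{rid}\t{src}\t{estr}")
    return "\n".join(lines) + "\n"


def read_truth(source: IO[str] | str) -> Truth:
    if hasattr(source, "read"):
        source = source.read()  # type: ignore[union-attr]
    lines = [ln for ln in str(source).splitlines() if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith("#TRUTH v1"):
        raise ValueError("not a truth file (missing #TRUTH v1 header)")
    h1 = lines[1].split(" ", 1)[1].strip()
    h2 = lines[2].split(" ", 1)[1].strip()
    src: list[int] = []
    errors: list[tuple[bool, ...]] = []
    for ln in lines[3:]:
        _rid, s, estr = ln.split("\t")
        src.append(int(s))
        errors.append(tuple(ch == "1" for ch in estr))
    return Truth(haplotypes=(h1, h2), source=src, errors=errors)
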