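"""Weighted fragment-matrix data model and text I/O.

The phasing engine consumes a *fragment matrix*: one row per sequencing
read, one column per heterozygous SNP site, entries in {0, 1, -}.  A read
is a set of allele observations ("calls"), each carrying a positive
confidence weight -- the cost the optimizer pays to flip that call.  '-'
means the read does not observe the site.

On-disk dialect (UTF-8 text, columns 1-based in files, 0-based in memory)::

    #FRAGMAT v1 columns=<m>
    #POSITIONS <p1> <p2> ... <pm>          (optional, 1-based genomic coords)
    <read_id>\t<col>:<allele>:<weight>[,<col>:<allele>:<weight>]...

Phased output is VCF 4.2 with per-sample GT and PS (phase set) fields.
"""

from __future__ import annotations

import io
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import IO, TYPE_CHECKING, Iterable

from .errors import FragmentFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .dp_core import PhasingResult

_HEADER_PREFIX = "#FRAGMAT v1 columns="


@dataclass(frozen=True)
class Call:
    """A single allele observation: 0-based column, allele in {0,1}, weight > 0."""

    column: int
    allele: int
    weight: float

    def __post_init__(self):
        if self.column < 0:
            raise ValueError(f"call column must be >= 0, got {self.column}")
        if self.allele not in (0, 1):
            raise ValueError(f"allele must be 0 or 1, got {self.allele!r}")
        if not self.weight > 0:
            raise ValueError(f"call weight must be positive, got {self.weight!r}")


@dataclass(frozen=True)
class Fragment:
    """One read: an id plus its calls, sorted by strictly increasing column."""

    read_id: str
    calls: tuple[Call, ...]

    def __post_init__(self):
        if not self.calls:
            raise ValueError(f"fragment {self.read_id!r} has no calls")
        cols = [c.column for c in self.calls]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError(
                f"fragment {self.read_id!r}: call columns must be strictly increasing"
            )
        object.__setattr__(self, "_columns", tuple(cols))

    @property
    def first_column(self) -> int:
        return self.calls[0].column

    @property
    def last_column(self) -> int:
        return self.calls[-1].column

    def call_at(self, column: int) -> Call | None:
        """The call at `column`, or None (a gap or outside the span)."""
        cols: tuple[int, ...] = self._columns  # type: ignore[attr-defined]
        i = bisect_left(cols, column)
        if i < len(cols) and cols[i] == column:
            return self.calls[i]
        return None


@dataclass(frozen=True)
class FragmentMatrix:
    """n fragments over m SNP columns, optionally with genomic positions."""

    fragments: tuple[Fragment, ...]
    num_columns: int
    positions: tuple[int, ...] | None = None

    def __post_init__(self):
        for frag in self.fragments:
            if frag.last_column >= self.num_columns:
                raise ValueError(
                    f"fragment {frag.read_id!r} calls column {frag.last_column} "
                    f"but the matrix declares {self.num_columns} columns"
                )
        if self.positions is not None:
            if len(self.positions) != self.num_columns:
                raise ValueError(
                    f"positions length {len(self.positions)} != num_columns "
                    f"{self.num_columns}"
                )
            if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
                raise ValueError("positions must be strictly increasing")
            if self.positions and self.positions[0] < 1:
                raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n(self) -> int:
        return len(self.fragments)

    @property
    def m(self) -> int:
        return self.num_columns


def _format_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def read_fragments(source: IO[str] | str | Iterable[str]) -> FragmentMatrix:
    """Parse the fragment dialect from a file object, string, or line iterable.

    Raises FragmentFormatError naming the offending line on any violation:
    malformed header or call, allele outside {0,1}, non-positive weight,
    duplicate or unsorted columns within a read, column beyond the declared
    count.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = iter(source)

    try:
        header = next(lines)
    except StopIteration:
        raise FragmentFormatError("empty input: missing #FRAGMAT header", 1) from None
    header = header.rstrip("\n")
    if not header.startswith(_HEADER_PREFIX):
        raise FragmentFormatError(
            f"expected header starting with {_HEADER_PREFIX!r}, got {header!r}", 1
        )
    try:
        num_columns = int(header[len(_HEADER_PREFIX):])
    except ValueError:
        raise FragmentFormatError(f"bad column count in header {header!r}", 1) from None
    if num_columns < 0:
        raise FragmentFormatError("column count must be >= 0", 1)

    positions: tuple[int, ...] | None = None
    fragments: list[Fragment] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(lines, start=2):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#POSITIONS"):
            if positions is not None:
                raise FragmentFormatError("duplicate #POSITIONS line", lineno)
            if fragments:
                raise FragmentFormatError("#POSITIONS must precede data lines", lineno)
            try:
                positions = tuple(int(tok) for tok in line.split()[1:])
            except ValueError:
                raise FragmentFormatError("non-integer genomic position", lineno) from None
            continue
        if line.startswith("#"):
            raise FragmentFormatError(f"unrecognized directive {line.split()[0]!r}", lineno)

        parts = line.split("\t")
        if len(parts) != 2:
            raise FragmentFormatError(
                "expected '<read_id>\\t<calls>' with exactly one tab", lineno
            )
        read_id, calls_text = parts
        if not read_id:
            raise FragmentFormatError("empty read id", lineno)
        if read_id in seen_ids:
            raise FragmentFormatError(f"duplicate read id {read_id!r}", lineno)
        seen_ids.add(read_id)

        calls: list[Call] = []
        for tok in calls_text.split(","):
            fields = tok.split(":")
            if len(fields) != 3:
                raise FragmentFormatError(f"malformed call {tok!r}", lineno)
            col_s, allele_s, weight_s = fields
            try:
                col = int(col_s)
                allele = int(allele_s)
                weight = float(weight_s)
            except ValueError:
                raise FragmentFormatError(f"malformed call {tok!r}", lineno) from None
            if col < 1:
                raise FragmentFormatError(
                    f"call column {col} must be >= 1 (columns are 1-based on disk)",
                    lineno,
                )
            if col > num_columns:
                raise FragmentFormatError(
                    f"call column {col} exceeds declared column count {num_columns}",
                    lineno,
                )
            try:
                calls.append(Call(column=col - 1, allele=allele, weight=weight))
            except ValueError as exc:
                raise FragmentFormatError(str(exc), lineno) from None
        try:
            fragments.append(Fragment(read_id=read_id, calls=tuple(calls)))
        except ValueError as exc:
            raise FragmentFormatError(str(exc), lineno) from None

    try:
        return FragmentMatrix(
            fragments=tuple(fragments), num_columns=num_columns, positions=positions
        )
    except ValueError as exc:
        raise FragmentFormatError(str(exc)) from None


def write_fragments(matrix: FragmentMatrix) -> str:
    """Serialize a matrix to the fragment dialect (read_fragments inverse)."""
    out = [f"{_HEADER_PREFIX}{matrix.num_columns}"]
    if matrix.positions is not None:
        out.append("#POSITIONS " + " ".join(str(p) for p in matrix.positions))
    for frag in matrix.fragments:
        calls = ",".join(
            f"{c.column + 1}:{c.allele}:{_format_weight(c.weight)}" for c in frag.calls
        )
        out.append(f"{frag.read_id}\t{calls}")
    return "\n".join(out) + "\n"


def write_phased_vcf(
    result: "PhasingResult",
    matrix: FragmentMatrix,
    sample_name: str = "SAMPLE",
    *,
    chrom: str = "1",
    ref_allele: str = "A",
    alt_allele: str = "C",
    het_unphased: bool = False,
) -> str:
    """Render a phasing result as VCF 4.2 text with GT and PS fields.

    One record per matrix column.  A column is *phased* when both haplotypes
    carry a definite allele there; its GT uses '|' and its PS is the genomic
    position of the first column of the block it belongs to.  Unphased
    columns are emitted as './.' (or '0/1' when `het_unphased` is set).

    The matrix must carry genomic positions; allele labels 0/1 are reported
    as `ref_allele`/`alt_allele` since the matrix abstracts real nucleotides
    away.
    """
    if matrix.positions is None:
        raise ValueError("matrix has no genomic positions; cannot write VCF")
    h1, h2 = result.haplotypes
    if len(h1) != matrix.num_columns:
        raise ValueError("result haplotype length does not match matrix columns")

    block_start_pos: dict[int, int] = {}
    for block in result.blocks:
        ps = matrix.positions[block.start]
        for j in range(block.start, block.stop):
            block_start_pos[j] = ps

    lines = [
        "##fileformat=VCFv4.2",
        "##source=wmecphase",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}",
    ]
    for j in range(matrix.num_columns):
        pos = matrix.positions[j]
        a, b = h1[j], h2[j]
        if a in "01" and b in "01" and j in block_start_pos:
            sample = f"{a}|{b}:{block_start_pos[j]}"
        else:
            sample = ("0/1" if het_unphased else "./.") + ":."
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref_allele}\t{alt_allele}\t.\tPASS\t.\tGT:PS\t{sample}"
        )
    return "\n".join(lines) + "\n"
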