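"""Trimming of SELEX probes to the variable region and the single-core filter.

A SELEX probe reads as barcode + left_flank + variable + right_flank (the
right flank may be truncated by the read length). The variable region of a
fixed-core library carries the invariant core (e.g. CGTG in the 8N-CGTG-10N
design) at a known offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from ._seq import revcomp
from .io_formats import SelexReadSet

__all__ = ["SelexLibraryDesign", "TrimResult", "FilterResult",
           "trim_to_variable", "count_core_occurrences", "filter_single_core",
           "RANDOM_18MER", "FIXED_CORE_8N_CGTG_10N"]


@dataclass(frozen=True)
class SelexLibraryDesign:
    """Geometry of a SELEX probe.

    fixed_core, when present, is (sequence, offset) with the offset measured
    within the variable region.
    """

    left_flank: str = ""
    right_flank: str = ""
    barcode: str = ""
    variable_length: int = 18
    fixed_core: Optional[Tuple[str, int]] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variable_length <= 0:
            raise ValueError("variable_length must be > 0")
        if self.fixed_core is not None:
            core, offset = self.fixed_core
            if offset < 0 or offset + len(core) > self.variable_length:
                raise ValueError("fixed core does not fit in the variable region")

    @property
    def prefix(self) -> str:
        return self.barcode + self.left_flank

    def variable_region_ok(self, variable: str, max_mismatch: int = 0) -> bool:
        """Check the fixed core (when designed) within a variable region."""
        if self.fixed_core is None:
            return True
        core, offset = self.fixed_core
        observed = variable[offset:offset + len(core)]
        mismatches = sum(a != b for a, b in zip(observed, core))
        return len(observed) == len(core) and mismatches <= max_mismatch


# The two library geometries used throughout: a fully random 18-mer and the
# fixed-core 8N-CGTG-10N 22-mer.
RANDOM_18MER = SelexLibraryDesign(variable_length=18, name="random18")
FIXED_CORE_8N_CGTG_10N = SelexLibraryDesign(
    variable_length=22, fixed_core=("CGTG", 8), name="fixedcore_8N_CGTG_10N")


@dataclass
class TrimResult:
    reads: SelexReadSet
    n_input: int
    n_dropped_flank: int
    n_dropped_core: int

    @property
    def n_kept(self) -> int:
        return len(self.reads)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_to_variable(reads: SelexReadSet, design: SelexLibraryDesign,
                     max_mismatch: int = 0, check_core: bool = True) -> TrimResult:
    """Trim barcode/flanks, keeping reads whose constant parts match.

    A read survives when (a) the barcode+left-flank prefix and whatever part
    of the right flank the read covers each match within max_mismatch, and
    (b) for fixed-core designs with check_core, the core is present at the
    design offset. Surviving reads all have length design.variable_length.
    """
    prefix = design.prefix
    min_len = len(prefix) + design.variable_length
    if reads.reads and min_len > len(reads.reads[0]):
        raise ValueError(
            f"design needs reads of >= {min_len} bp, got {len(reads.reads[0])} bp")

    kept: list[str] = []
    n_flank = n_core = 0
    for read in reads.reads:
        if len(read) < min_len:
            n_flank += 1
            continue
        ok = _mismatches(read[:len(prefix)], prefix) <= max_mismatch
        if ok and design.right_flank:
            observed_right = read[min_len:min_len + len(design.right_flank)]
            ok = _mismatches(observed_right,
                             design.right_flank[:len(observed_right)]) <= max_mismatch
        if not ok:
            n_flank += 1
            continue
        variable = read[len(prefix):min_len]
        if check_core and not design.variable_region_ok(variable):
            n_core += 1
            continue
        kept.append(variable)
    return TrimResult(
        reads=SelexReadSet(reads.round_index, kept, design_ref=design.name),
        n_input=len(reads), n_dropped_flank=n_flank, n_dropped_core=n_core)


def count_core_occurrences(read: str, core: str, both_strands: bool = True) -> int:
    """Count core occurrences by sliding window (overlaps counted).

    With both_strands, occurrences of the reverse complement of the core on
    the read strand are added (a dsDNA ligand presents both strands to the
    dimer).
    """
    if len(core) > len(read):
        raise ValueError("core longer than read")
    n = sum(read.startswith(core, i) for i in range(len(read) - len(core) + 1))
    if both_strands:
        rc = revcomp(core)
        if rc != core:
            n += sum(read.startswith(rc, i) for i in range(len(read) - len(rc) + 1))
    return n


@dataclass
class FilterResult:
    reads: SelexReadSet
    n_input: int
    n_dropped: int

    @property
    def n_kept(self) -> int:
        return len(self.reads)


def filter_single_core(reads: SelexReadSet, core: str = "CGTG",
                       both_strands: bool = True,
                       mode: str = "exactly_one") -> FilterResult:
    """Retain reads whose core-occurrence count satisfies `mode`.

    mode="exactly_one" keeps reads with exactly one occurrence (the default
    for fixed-core libraries, where the designed core itself counts);
    mode="at_most_one" also keeps core-free reads. Idempotent: filtering a
    filtered set changes nothing.
    """
    if mode not in {"exactly_one", "at_most_one"}:
        raise ValueError(f"unknown mode {mode!r}")
    kept = []
    for read in reads.reads:
        n = count_core_occurrences(read, core, both_strands=both_strands)
        if n == 1 or (mode == "at_most_one" and n == 0):
            kept.append(read)
    return FilterResult(
        reads=SelexReadSet(reads.round_index, kept, design_ref=reads.design_ref),
        n_input=len(reads), n_dropped=len(reads) - len(kept))
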