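"""Detection of perfect short tandem repeats (microsatellites) in DNA sequence.

A microsatellite here is a maximal perfect tandem run of a primitive 2-4 bp
motif: the run cannot be extended by one base on either side while keeping
the motif period, and the motif itself is not a power of a shorter string
(so a (CA)8 run is never double-reported as (CACA)4).  Coordinates are
1-based inclusive throughout, matching the convention of the classic SSR
scanners; conversion to 0-based half-open happens only when writing BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_VALID_SEQ = re.compile(r"[ACGTN]*\Z")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: minimum repeat counts per motif length, in the spirit of standard SSR
#: scanner defaults for di-/tri-/tetranucleotide motifs
DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 5}


class SequenceAlphabetError(ValueError):
    """Sequence contains a character outside A/C/G/T/N."""


@dataclass(frozen=True)
class RepeatThresholds:
    """Minimum repeat count required per motif (unit) length.

    Only motif lengths present in the mapping are scanned; each minimum
    must be at least 2 (a single unit is not a repeat).
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        for unit, min_count in self.min_repeats.items():
            if unit < 1 or unit > 6:
                raise ValueError(f"unsupported motif length {unit}")
            if min_count < 2:
                raise ValueError(
                    f"minimum repeat count for unit {unit} must be >= 2, got {min_count}"
                )

    @property
    def unit_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.min_repeats))


@dataclass(frozen=True, order=True)
class MicrosatelliteLocus:
    """A maximal perfect tandem repeat: 1-based inclusive span."""

    scaffold: str
    start: int
    end: int
    motif: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.length != len(self.motif) * self.repeat_count:
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with "
                f"({self.motif}){self.repeat_count}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def notation(self) -> str:
        """Compact motif notation, e.g. ``(AAC)5``."""
        return f"({self.motif}){self.repeat_count}"

    def overlaps(self, start: int, end: int) -> bool:
        """True if the 1-based inclusive interval [start, end] shares >= 1 bp."""
        return self.start <= end and start <= self.end


def is_primitive(motif: str) -> bool:
    """True unless the motif is a concatenation of >= 2 copies of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation over both strands (grouping key).

    Loci are reported with the motif as spelled at the locus start; this
    key lets callers group e.g. (CA)n, (AC)n and (TG)n loci together.
    """
    rc = motif.translate(_COMPLEMENT)[::-1]
    rotations = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(rotations)


def find_microsatellites(
    sequence: str,
    scaffold_name: str,
    thresholds: RepeatThresholds | None = None,
) -> list[MicrosatelliteLocus]:
    """Scan one sequence for maximal perfect tandem repeats.

    Runs containing N are broken at the N.  A run whose total length is not
    a whole number of units is reported over its complete units only; the
    repeat count is the floor of run length / unit length.  Output is sorted
    by start position, then motif length.
    """
    thresholds = thresholds or RepeatThresholds()
    seq = sequence.upper()
    if not _VALID_SEQ.match(seq):
        pos = next(i for i, c in enumerate(seq) if c not in "ACGTN")
        raise SequenceAlphabetError(
            f"invalid character {seq[pos]!r} at position {pos + 1} of {scaffold_name}"
        )
    n = len(seq)
    loci: list[MicrosatelliteLocus] = []
    for unit in thresholds.unit_lengths:
        min_count = thresholds.min_repeats[unit]
        i = 0
        while i + unit <= n:
            window = seq[i : i + unit]
            if "N" in window or not is_primitive(window):
                i += 1
                continue
            j = i + unit
            while j < n and seq[j] == seq[j - unit]:
                j += 1
            # left-maximal iff the run cannot be extended one base leftward
            if i == 0 or seq[i - 1] != seq[i - 1 + unit]:
                count = (j - i) // unit
                if count >= min_count:
                    loci.append(
                        MicrosatelliteLocus(
                            scaffold=scaffold_name,
                            start=i + 1,
                            end=i + count * unit,
                            motif=window,
                            repeat_count=count,
                        )
                    )
            # any qualifying run overlapping this one must start past j - unit
            i = max(i + 1, j - unit + 1)
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def scan_fasta(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
    thresholds: RepeatThresholds | None = None,
) -> list[MicrosatelliteLocus]:
    """Scan several named sequences; loci sorted by scaffold then start."""
    items = records.items() if isinstance(records, Mapping) else records
    loci: list[MicrosatelliteLocus] = []
    for name, seq in items:
        loci.extend(find_microsatellites(seq, name, thresholds))
    loci.sort(key=lambda l: (l.scaffold, l.start, len(l.motif)))
    return loci


# ---------------------------------------------------------------------------
# Tabular output: MISA-style TSV (1-based inclusive) and BED (0-based half-open)
# ---------------------------------------------------------------------------

_MISA_HEADER = ["ID", "SSR nr.", "SSR", "size", "start", "end"]


def write_msat_table(
    loci: Sequence[MicrosatelliteLocus], path: str | Path, dialect: str = "misa"
) -> None:
    """Write loci as a MISA-style TSV (``dialect='misa'``) or BED (``'bed'``)."""
    path = Path(path)
    if dialect == "misa":
        lines = ["\t".join(_MISA_HEADER)]
        counter: dict[str, int] = {}
        for locus in loci:
            counter[locus.scaffold] = counter.get(locus.scaffold, 0) + 1
            lines.append(
                "\t".join(
                    [
                        locus.scaffold,
                        str(counter[locus.scaffold]),
                        locus.notation,
                        str(locus.length),
                        str(locus.start),
                        str(locus.end),
                    ]
                )
            )
    elif dialect == "bed":
        lines = [
            f"{l.scaffold}\t{l.start - 1}\t{l.end}\t{l.notation}" for l in loci
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


_NOTATION = re.compile(r"\(([ACGT]+)\)(\d+)\Z")


def read_msat_table(path: str | Path, dialect: str = "misa") -> list[MicrosatelliteLocus]:
    """Read loci back from :func:`write_msat_table` output."""
    path = Path(path)
    loci: list[MicrosatelliteLocus] = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if dialect == "misa":
        lines = lines[1:]  # header
    for line in lines:
        fields = line.split("\t")
        if dialect == "misa":
            scaffold, _, notation, _, start, end = fields[:6]
            start_i, end_i = int(start), int(end)
        elif dialect == "bed":
            scaffold, start, end, notation = fields[:4]
            start_i, end_i = int(start) + 1, int(end)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        m = _NOTATION.match(notation)
        if not m:
            raise ValueError(f"cannot parse motif notation {notation!r}")
        loci.append(
            MicrosatelliteLocus(
                scaffold=scaffold,
                start=start_i,
                end=end_i,
                motif=m.group(1),
                repeat_count=int(m.group(2)),
            )
        )
    return loci
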