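"""Small sequence helpers shared across modules."""

from __future__ import annotations

from typing import Mapping

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Fetch an upper-case reference slice from a dict of strings or a pyfaidx.Fasta.

    ``start``/``end`` are 0-based half-open and assumed already clamped.
    """
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in the supplied genome") from None
    return str(record[start:end]).upper()


def chrom_length(genome: Mapping[str, object], chrom: str) -> int:
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in the supplied genome") from None
    return len(record)
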