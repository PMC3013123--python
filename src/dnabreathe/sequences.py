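"""Promoter sequences and the TSS-anchored coordinate frame.

Every downstream breathing profile is reported in promoter coordinates:
the transcription start site (TSS) is position +1, the base immediately
upstream is -1, and there is no position 0.  Sequences are single-strand
5'->3'; the lattice model treats each position as a base *pair*, so no
reverse-complement handling is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Morse-well class of each base: two H-bonds for A/T, three for G/C.
BASE_CLASS = {"A": "AT", "T": "AT", "G": "GC", "C": "GC"}


class SequenceError(ValueError):
    """Raised for invalid sequence content or coordinates."""


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter sequence with a declared transcription start site.

    Parameters
    ----------
    name : str
        Record label.
    bases : str
        Upper-case sequence over {A, C, G, T}, length >= 2 (the stacking
        term needs at least one dinucleotide step).
    tss_index : int
        0-based internal index of the base reported as position +1.
    """

    name: str
    bases: str
    tss_index: int

    def __post_init__(self):
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if len(bases) < 2:
            raise SequenceError(
                f"sequence {self.name!r}: length {len(bases)} < 2; the "
                "stacking term needs at least one dinucleotide step"
            )
        for i, b in enumerate(bases):
            if b not in VALID_BASES:
                raise SequenceError(
                    f"sequence {self.name!r}: invalid base {b!r} at "
                    f"position {i + 1} (only A/C/G/T accepted; ambiguity "
                    "codes are rejected, not imputed)"
                )
        if not 0 <= self.tss_index < len(bases):
            raise SequenceError(
                f"sequence {self.name!r}: tss_index {self.tss_index} out of "
                f"range [0, {len(bases)})"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def base_classes(self) -> list[str]:
        """Per-position Morse class, 'AT' or 'GC'."""
        return [BASE_CLASS[b] for b in self.bases]

    def tss_coordinate(self, internal_index: int) -> int:
        """Map a 0-based internal index to the signed promoter coordinate.

        The TSS maps to +1 and the base before it to -1; position 0 does
        not exist (standard promoter numbering).
        """
        n = len(self.bases)
        if not 0 <= internal_index < n:
            raise SequenceError(
                f"internal index {internal_index} out of range [0, {n})"
            )
        delta = internal_index - self.tss_index
        return delta + 1 if delta >= 0 else delta

    def internal_index(self, tss_coordinate: int) -> int:
        """Inverse of :meth:`tss_coordinate`."""
        if tss_coordinate == 0:
            raise SequenceError("promoter coordinate 0 does not exist")
        idx = self.tss_index + tss_coordinate - (1 if tss_coordinate > 0 else 0)
        if not 0 <= idx < len(self.bases):
            raise SequenceError(
                f"promoter coordinate {tss_coordinate:+d} outside sequence"
            )
        return idx

    def gc_fraction(self, window: tuple[int, int] | None = None) -> float:
        """Fraction of G+C in the sequence or a [start, stop) index window."""
        start, stop = (0, len(self.bases)) if window is None else window
        if not (0 <= start < stop <= len(self.bases)):
            raise SequenceError(f"empty or out-of-range window [{start}, {stop})")
        sub = self.bases[start:stop]
        return (sub.count("G") + sub.count("C")) / len(sub)


def _parse_tss_token(description: str) -> int | None:
    """Extract a 1-based ``tss=<n>`` token from a FASTA header, if present."""
    for token in description.split():
        if token.lower().startswith("tss="):
            value = token[4:]
            try:
                return int(value)
            except ValueError:
                raise SequenceError(
                    f"malformed tss token {token!r} in header {description!r}"
                ) from None
    return None


def read_fasta(path, tss_overrides: dict[str, int] | None = None) -> list[PromoterSequence]:
    """Read promoter records from a FASTA file.

    The TSS is taken, in order of precedence, from ``tss_overrides``
    (record name -> 1-based offset), then from a ``tss=<n>`` header token,
    else it defaults to the record midpoint with a logged warning.

    Raises
    ------
    SequenceError
        On malformed FASTA, non-ACGT characters (position named), or an
        out-of-range TSS offset.
    """
    tss_overrides = tss_overrides or {}
    records: list[PromoterSequence] = []
    with open(path) as fh:
        # Pre-check: SeqIO silently returns nothing for a non-FASTA body.
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is not None and not first[1].startswith(">"):
            raise SequenceError(
                f"{path}: line {first[0]} is not a FASTA header: "
                f"{first[1].strip()!r}"
            )
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            bases = str(rec.seq).upper()
            n = len(bases)
            if n == 0:
                raise SequenceError(f"record {rec.id!r}: empty sequence")
            if rec.id in tss_overrides:
                tss_1b = tss_overrides[rec.id]
            else:
                tss_1b = _parse_tss_token(rec.description)
            if tss_1b is None:
                tss_1b = n // 2 + 1
                logger.warning(
                    "record %r has no tss= token; defaulting TSS to the "
                    "midpoint (position %d of %d)", rec.id, tss_1b, n
                )
            if not 1 <= tss_1b <= n:
                raise SequenceError(
                    f"record {rec.id!r}: tss offset {tss_1b} outside [1, {n}]"
                )
            records.append(
                PromoterSequence(name=rec.id, bases=bases, tss_index=tss_1b - 1)
            )
    return records


def write_fasta(seqs: list[PromoterSequence], path) -> None:
    """Write records with the ``tss=`` header token (round-trips read_fasta)."""
    recs = [
        SeqRecord(Seq(s.bases), id=s.name, description=f"tss={s.tss_index + 1}")
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
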