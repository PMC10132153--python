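"""Transcript sequences partitioned into 5'UTR, CDS and 3'UTR.

Coordinates are 1-based inclusive on the transcript throughout, matching the
convention used for motif and uORF reports.  Sequences are stored in the DNA
alphabet; RNA input is accepted with U mapped to T at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class Transcript:
    """An mRNA with annotated region lengths.

    Parameters
    ----------
    id : str
        Transcript identifier.
    sequence : str
        Nucleotide sequence over {A, C, G, T}; ``U`` is mapped to ``T``.
        IUPAC ambiguity codes are rejected.
    utr5_length, cds_length, utr3_length : int
        Region lengths in nucleotides; they must sum to the sequence length.
    """

    id: str
    sequence: str
    utr5_length: int
    cds_length: int
    utr3_length: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID
        if bad:
            raise ValidationError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)} "
                "(IUPAC ambiguity codes are not supported)"
            )
        for name in ("utr5_length", "cds_length", "utr3_length"):
            if getattr(self, name) < 0:
                raise ValidationError(f"transcript {self.id!r}: {name} < 0")
        total = self.utr5_length + self.cds_length + self.utr3_length
        if total != len(seq):
            raise ValidationError(
                f"transcript {self.id!r}: region lengths sum to {total} but "
                f"sequence length is {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    # -- region arithmetic (1-based inclusive) -------------------------------

    @property
    def cds_start(self) -> int:
        """1-based position of the first CDS base (utr5_length + 1)."""
        return self.utr5_length + 1

    @property
    def cds_end(self) -> int:
        return self.utr5_length + self.cds_length

    @property
    def utr5(self) -> str:
        return self.sequence[: self.utr5_length]

    @property
    def cds(self) -> str:
        return self.sequence[self.utr5_length : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    def region_of(self, pos: int) -> str:
        """Region label ('utr5' | 'cds' | 'utr3') of a 1-based position."""
        if not 1 <= pos <= len(self):
            raise ValidationError(
                f"position {pos} outside transcript {self.id!r} (1..{len(self)})"
            )
        if pos <= self.utr5_length:
            return "utr5"
        if pos <= self.cds_end:
            return "cds"
        return "utr3"

    def region_of_interval(self, start: int, end: int) -> str:
        """Label for a 1-based inclusive interval; 'spanning' if it crosses
        a region boundary."""
        if start > end:
            raise ValidationError(f"interval start {start} > end {end}")
        a, b = self.region_of(start), self.region_of(end)
        return a if a == b else "spanning"

    def to_region_local(self, pos: int) -> tuple[str, int]:
        """Convert a transcript-global 1-based position to (region, local
        1-based position within that region)."""
        region = self.region_of(pos)
        if region == "utr5":
            return region, pos
        if region == "cds":
            return region, pos - self.utr5_length
        return region, pos - self.cds_end

    def to_global(self, region: str, local_pos: int) -> int:
        """Inverse of :meth:`to_region_local`."""
        offsets = {"utr5": 0, "cds": self.utr5_length, "utr3": self.cds_end}
        if region not in offsets:
            raise ValidationError(f"unknown region {region!r}")
        pos = offsets[region] + local_pos
        if self.region_of(pos) != region:
            raise ValidationError(
                f"local position {local_pos} outside region {region!r} of "
                f"transcript {self.id!r}"
            )
        return pos

    def with_sequence(self, sequence: str) -> "Transcript":
        """Copy with a replacement sequence of identical length."""
        return Transcript(
            self.id, sequence, self.utr5_length, self.cds_length, self.utr3_length
        )
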