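"""Upstream open reading frame (uORF) detection in 5'UTRs.

Every occurrence of an active start codon whose first base lies in the
5'UTR opens a candidate ORF, extended in-frame to the first stop codon
(TAA/TAG/TGA).  A uORF whose stop lies before the main CDS is *contained*;
one whose stop falls inside the CDS is *overlapping*; one that never meets
an in-frame stop is *no_stop*.  Modes follow the two conventional ORF-finder
settings: ATG only, or ATG plus a configurable alternative initiation codon
set (default CTG/GTG/TTG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .transcripts import Transcript

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_ALT_CODONS = ("CTG", "GTG", "TTG")
MODES = ("atg_only", "atg_plus_alternatives")


@dataclass(frozen=True)
class UORFRecord:
    """One upstream ORF in 1-based inclusive transcript coordinates.

    ``end`` is the last base of the stop codon (or of the last complete
    codon scanned, for no_stop).  ``frame`` is the frame of the uORF start
    relative to the main CDS reading frame (0 = in frame with the CDS).
    """

    transcript_id: str
    start: int
    end: int
    start_codon: str
    frame: int
    classification: str


def find_uorfs(
    transcript: Transcript,
    mode: str = "atg_only",
    min_length_nt: int = 0,
    alt_codon_set: Sequence[str] = DEFAULT_ALT_CODONS,
) -> list[UORFRecord]:
    """All uORFs of a transcript under the chosen start-codon mode.

    ``min_length_nt`` filters on the nucleotide count between (and
    excluding) the start and stop codons.  Overlapping and nested uORFs are
    all reported independently.  A transcript with no 5'UTR yields an empty
    list.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    starts = {"ATG"}
    if mode == "atg_plus_alternatives":
        starts |= {c.upper() for c in alt_codon_set}
    if any(len(c) != 3 or set(c) - set("ACGT") for c in starts):
        raise ValidationError("start codons must be 3-letter ACGT strings")
    seq = transcript.sequence
    u5 = transcript.utr5_length
    records: list[UORFRecord] = []
    for i in range(min(u5, len(seq) - 2)):  # 0-based first base in the UTR
        codon = seq[i : i + 3]
        if codon not in starts:
            continue
        j = i + 3
        end = None
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOP_CODONS:
                end = j + 3  # 1-based inclusive end of the stop codon
                break
            j += 3
        if end is None:
            classification = "no_stop"
            end = j  # last complete in-frame codon scanned
        elif end <= u5:
            classification = "contained"
        else:
            classification = "overlapping"
        start = i + 1
        if classification != "no_stop" and (end - start + 1) - 6 < min_length_nt:
            continue
        records.append(
            UORFRecord(
                transcript.id, start, end, seq[i : i + 3],
                (start - transcript.cds_start) % 3, classification,
            )
        )
    return records


def uorf_prevalence_by_group(
    transcripts_by_group: Mapping,
    mode: str = "atg_only",
    min_length_nt: int = 0,
    alt_codon_set: Sequence[str] = DEFAULT_ALT_CODONS,
) -> tuple[pd.DataFrame, float, float]:
    """Fraction of transcripts with >= 1 uORF per group, plus a chi-square
    test of homogeneity across groups.

    Groups with n = 0 are reported but excluded from the test.  Returns
    (table, chi-square statistic, p-value); the statistic is NaN when fewer
    than two non-empty groups exist.
    """
    rows = []
    for gid, transcripts in sorted(transcripts_by_group.items()):
        n = len(transcripts)
        n_with = sum(
            bool(find_uorfs(t, mode, min_length_nt, alt_codon_set))
            for t in transcripts
        )
        rows.append(dict(group=gid, n=n, n_with_uorf=n_with,
                         fraction=(n_with / n if n else np.nan),
                         mode=mode))
    table = pd.DataFrame(rows).set_index("group")
    if table["n"].sum() == 0:
        raise ValidationError("all groups are empty")
    tested = table[table["n"] > 0]
    if len(tested) < 2:
        return table, float("nan"), float("nan")
    contingency = np.array([tested["n_with_uorf"],
                            tested["n"] - tested["n_with_uorf"]])
    if contingency.sum(axis=1).min() == 0:
        # degenerate: nobody (or everybody) has a uORF -> perfectly homogeneous
        return table, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(contingency.T)
    return table, float(chi2), float(p)
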