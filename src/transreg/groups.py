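"""The 27-cell regulation-group taxonomy and its algebra.

Each feature carries three calls: protein direction, total-mRNA direction
(each up/stable/down) and a ribosomal shift (m_to_p/stable/p_to_m).  The
group id enumerates the 3 x 3 x 3 grid as

    group = 9 * p + 3 * r + s + 1

with p, r in {up: 0, stable: 1, down: 2} for protein and RNA, and
s in {m_to_p: 0, stable: 1, p_to_m: 2}.  Anchors: group 1 = all up with an
M->P shift; group 4 = protein up, mRNA stable, M->P (translationally
upregulated); group 13 = only the shift; group 14 = fully stable; groups
19-27 are protein-down.  A feature with an ``other`` call in any layer is
unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

PROTEIN_INDEX = {"up": 0, "stable": 1, "down": 2}
RNA_INDEX = PROTEIN_INDEX
SHIFT_INDEX = {"m_to_p": 0, "stable": 1, "p_to_m": 2}

_PROT_REV = {v: k for k, v in PROTEIN_INDEX.items()}
_SHIFT_REV = {v: k for k, v in SHIFT_INDEX.items()}


def assign_group(protein_call: str, rna_call: str, shift_call: str):
    """Group id 1..27 for a call triple, or None if any call is ``other``.

    Unknown call tokens raise a validation error.
    """
    for call, vocab, label in (
        (protein_call, PROTEIN_INDEX, "protein"),
        (rna_call, RNA_INDEX, "rna"),
        (shift_call, SHIFT_INDEX, "shift"),
    ):
        if call != "other" and call not in vocab:
            raise ValidationError(f"unknown {label} call token {call!r}")
    if "other" in (protein_call, rna_call, shift_call):
        return None
    return (
        9 * PROTEIN_INDEX[protein_call]
        + 3 * RNA_INDEX[rna_call]
        + SHIFT_INDEX[shift_call]
        + 1
    )


def group_triple(group_id: int) -> tuple[str, str, str]:
    """Inverse of :func:`assign_group`: (protein, rna, shift) calls."""
    if not 1 <= group_id <= 27:
        raise ValidationError(f"group id {group_id} outside 1..27")
    g = group_id - 1
    return (_PROT_REV[g // 9], _PROT_REV[(g // 3) % 3], _SHIFT_REV[g % 3])


def mismatch_groups() -> frozenset[int]:
    """Group ids where the protein direction differs from the RNA direction
    (the protein/mRNA mismatch set: 4-12 and 16-24)."""
    return frozenset(
        gid for gid in range(1, 28)
        if PROTEIN_INDEX[group_triple(gid)[0]] != RNA_INDEX[group_triple(gid)[1]]
    )


def classify_dataset(
    protein_calls: pd.DataFrame,
    rna_calls: pd.DataFrame,
    shift_records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Join the three call layers and assign regulation groups.

    Returns one record per feature in the intersection of the three inputs,
    plus a summary Series of counts per group id and per unassigned reason.
    """
    common = protein_calls.index.intersection(rna_calls.index).intersection(
        shift_records.index
    )
    if len(common) == 0:
        raise ValidationError("no features shared by the three call layers")
    rows = []
    for feat in common:
        pc = protein_calls.at[feat, "call"]
        rc = rna_calls.at[feat, "call"]
        sc = shift_records.at[feat, "call"]
        gid = assign_group(pc, rc, sc)
        reason = ""
        if gid is None:
            layers = [
                name for name, c in (("protein", pc), ("rna", rc), ("shift", sc))
                if c == "other"
            ]
            reason = "other in " + "+".join(layers)
        rows.append(dict(feature=feat, protein_call=pc, rna_call=rc,
                         shift_call=sc, group_id=gid, reason=reason))
    records = pd.DataFrame(rows).set_index("feature")
    counts: dict = {}
    for gid in range(1, 28):
        counts[gid] = int((records["group_id"] == gid).sum())
    counts["unassigned"] = int(records["group_id"].isna().sum())
    summary = pd.Series(counts, name="n_features")
    return records, summary


def correlate_shift_protein(
    records: pd.DataFrame,
    shift_records: pd.DataFrame,
    protein_calls: pd.DataFrame,
    group_id: int = 4,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlate log X (PM-ratio shift) with log protein fold change within
    one regulation group.

    The default rank-based (Spearman) correlation is robust to the ratio
    scale; ``method="pearson"`` correlates the logs linearly.  Returns
    (coefficient, two-sided p, n); a constant input yields (nan, nan, n).
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError("method must be 'spearman' or 'pearson'")
    feats = records.index[records["group_id"] == group_id]
    feats = feats.intersection(shift_records.index).intersection(
        protein_calls.index
    )
    x = shift_records.loc[feats, "X"].to_numpy(dtype=float)
    y = protein_calls.loc[feats, "ratio"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = np.log(x[ok]), np.log(y[ok])
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 features with defined X and ratio, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"), n)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        r, p = stats.pearsonr(x, y)
    return (float(r), float(p), n)
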