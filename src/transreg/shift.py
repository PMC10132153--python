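"""Polysome/monosome (PM) ratio shifts between conditions.

For each transcript, a PM ratio (polysome abundance / monosome abundance)
is computed per sample, then compared between conditions with a t test.
For significantly changed transcripts the X statistic
``X = mean PM ratio (treated) / mean PM ratio (control)`` determines the
verdict: X > 1 is a monosome-to-polysome shift (``m_to_p``, increased
translation), X < 1 a polysome-to-monosome shift (``p_to_m``).
Non-significant transcripts are ``stable`` if the treated PM-ratio CI is
contained in the expanded control CI (same equivalence rule as the
direction calls), otherwise ``other``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import EquivalenceParams, _t_test, equivalence_contained, mean_ci
from .errors import SchemaError, UndefinedRatioError, ValidationError

logger = logging.getLogger(__name__)

SHIFT_CALLS = ("m_to_p", "p_to_m", "stable", "other")


@dataclass(frozen=True)
class PMShiftRecord:
    feature: str
    pm_control: tuple[float, ...]
    pm_treated: tuple[float, ...]
    p_value: float
    X: float
    call: str
    pseudocount: float = 0.0


def pm_ratio(monosome, polysome, pseudocount: float = 0.0) -> np.ndarray:
    """Elementwise (polysome + pseudocount) / (monosome + pseudocount).

    Vectors are aligned by sample.  A symmetric pseudocount keeps the ratio
    finite for sparse features while preserving ordering.
    """
    m = np.asarray(monosome, dtype=float)
    p = np.asarray(polysome, dtype=float)
    if m.shape != p.shape:
        raise ValidationError("monosome and polysome vectors differ in length")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    denom = m + pseudocount
    if np.any(denom <= 0):
        i = int(np.argmax(denom <= 0))
        raise UndefinedRatioError(
            f"zero monosome denominator at sample index {i} with pseudocount "
            f"{pseudocount}"
        )
    return (p + pseudocount) / denom


def shift_call(
    pm_control,
    pm_treated,
    alpha: float = 0.05,
    params: EquivalenceParams = EquivalenceParams(),
    feature: str = "",
    paired: bool = False,
    pseudocount: float = 0.0,
) -> PMShiftRecord:
    """Shift verdict for one feature from per-sample PM-ratio vectors."""
    c = np.asarray(pm_control, dtype=float)
    t = np.asarray(pm_treated, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValidationError(
            f"feature {feature!r}: need >= 2 PM ratios per condition"
        )
    if c.mean() == 0:
        raise UndefinedRatioError(f"feature {feature!r}: all-zero control PM ratios")
    p = _t_test(c, t, paired, False)
    x = t.mean() / c.mean()
    sig = p < alpha
    if sig and x > 1:
        call = "m_to_p"
    elif sig and x < 1:
        call = "p_to_m"
    elif not sig and equivalence_contained(
        mean_ci(c, params.ci_level), mean_ci(t, params.ci_level), params
    ):
        call = "stable"
    else:
        call = "other"
    return PMShiftRecord(
        feature, tuple(c), tuple(t), p, x, call, pseudocount
    )


def shift_layer(
    table,
    alpha: float = 0.05,
    params: EquivalenceParams = EquivalenceParams(),
    pseudocount: float = 0.5,
    paired: bool = False,
    scale_fractions: bool = False,
) -> pd.DataFrame:
    """Shift verdicts for every feature present in both fraction layers.

    The monosome and polysome layers of ``table`` are aligned by
    (condition, unit); features detected (non-missing) in only one fraction
    are excluded and logged.  ``scale_fractions`` optionally column-scales
    each fraction to equal depth before forming ratios.
    """
    mono = table.layer("monosome")
    poly = table.layer("polysome")
    key = lambda sub: {
        (sub.samples.at[c, "condition"], str(sub.samples.at[c, "unit"])): c
        for c in sub.data.columns
    }
    mono_key, poly_key = key(mono), key(poly)
    if set(mono_key) != set(poly_key):
        raise SchemaError(
            "monosome and polysome fractions have mismatched (condition, unit) "
            "sample metadata"
        )
    order = sorted(mono_key)
    mono_df = mono.data[[mono_key[k] for k in order]]
    poly_df = poly.data[[poly_key[k] for k in order]]
    if scale_fractions:
        mono_df = mono_df / mono_df.sum() * float(mono_df.sum().mean())
        poly_df = poly_df / poly_df.sum() * float(poly_df.sum().mean())
    is_control = np.array([k[0] == "control" for k in order])

    rows = []
    n_excluded = 0
    for feat in table.features:
        m = mono_df.loc[feat].to_numpy(dtype=float)
        p = poly_df.loc[feat].to_numpy(dtype=float)
        if np.isnan(m).any() or np.isnan(p).any():
            n_excluded += 1
            logger.info("feature %s: excluded from shift (missing fraction)", feat)
            continue
        try:
            pm = pm_ratio(m, p, pseudocount)
            rec = shift_call(
                pm[is_control], pm[~is_control], alpha, params,
                feature=str(feat), paired=paired, pseudocount=pseudocount,
            )
        except (UndefinedRatioError, ValidationError) as exc:
            logger.info("feature %s: call=other (%s)", feat, exc)
            rows.append(dict(feature=feat, p=np.nan, X=np.nan, call="other",
                             pseudocount=pseudocount,
                             pm_control="", pm_treated=""))
            continue
        rows.append(dict(
            feature=feat, p=rec.p_value, X=rec.X, call=rec.call,
            pseudocount=pseudocount,
            pm_control=",".join(f"{v:.6g}" for v in rec.pm_control),
            pm_treated=",".join(f"{v:.6g}" for v in rec.pm_treated),
        ))
    if n_excluded:
        logger.info("shift_layer: %d features excluded", n_excluded)
    frame = pd.DataFrame(
        rows, columns=["feature", "p", "X", "call", "pseudocount",
                       "pm_control", "pm_treated"]
    )
    frame.attrs["n_excluded"] = n_excluded
    return frame.set_index("feature")
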