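"""Per-feature direction calls: up / down / stable / other.

Each feature is compared between control and treated replicates with a
two-tailed t test.  Significant features are called by the direction of the
treated/control ratio of means (a linear fold change).  Non-significant
features are called *stable* only if they pass an equivalence test by
confidence-interval containment: the treated 95% CI must lie completely
within the control CI expanded to 70% of its low end and 130% of its high
end.  Everything else is *other*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientReplicatesError,
    SchemaError,
    UndefinedRatioError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CALLS = ("up", "down", "stable", "other")


@dataclass(frozen=True)
class EquivalenceParams:
    """Parameters of the CI-containment equivalence rule.

    ``upper_factor`` (default 1.30) scales the high end of the control CI,
    ``lower_factor`` (default 0.70) its low end; ``clamp_nonnegative`` clips
    a negative control low bound to 0 before scaling (abundances are
    nonnegative and a negative low would invert the band).
    """

    ci_level: float = 0.95
    upper_factor: float = 1.30
    lower_factor: float = 0.70
    clamp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if not 0 < self.lower_factor <= 1 <= self.upper_factor:
            raise ValidationError(
                "require 0 < lower_factor <= 1 <= upper_factor"
            )


@dataclass(frozen=True)
class DirectionCall:
    """Verdict for one feature in one layer."""

    feature: str
    p_value: float
    q_flag: bool
    ratio: float
    ci_control: tuple[float, float]
    ci_treated: tuple[float, float]
    call: str
    reason: str = ""


def mean_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t-based confidence interval for the mean.

    ``mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n)``.  Zero-variance input
    yields a zero-width interval at the mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 values for a CI, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite value in replicate vector")
    m = x.mean()
    half = stats.t.ppf((1 + level) / 2, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return (m - half, m + half)


def _ci_from_summary(mean: float, sd: float, n: int, level: float) -> tuple[float, float]:
    half = stats.t.ppf((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def equivalence_contained(
    ci_control: tuple[float, float],
    ci_treated: tuple[float, float],
    params: EquivalenceParams = EquivalenceParams(),
) -> bool:
    """True iff the treated CI lies completely within the expanded control
    band ``[lower_factor * max(low, 0), upper_factor * high]``."""
    lo_c, hi_c = ci_control
    lo_t, hi_t = ci_treated
    if lo_c > hi_c or lo_t > hi_t:
        raise ValidationError("interval low > high")
    if params.clamp_nonnegative:
        lo_c = max(lo_c, 0.0)
    band_lo = params.lower_factor * lo_c
    band_hi = params.upper_factor * hi_c
    return band_lo <= lo_t and hi_t <= band_hi


def bh_flags(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _t_test(control, treated, paired: bool, welch: bool) -> float:
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if paired:
        if c.size != t.size:
            raise ValidationError("paired test requires equal lengths")
        if np.allclose(c, t):
            return 1.0
        return float(stats.ttest_rel(t, c).pvalue)
    if c.std(ddof=1) == 0 and t.std(ddof=1) == 0:
        return 1.0 if c.mean() == t.mean() else 0.0
    res = stats.ttest_ind(t, c, equal_var=not welch)
    return float(res.pvalue)


def call_feature(
    control,
    treated,
    alpha: float = 0.05,
    params: EquivalenceParams = EquivalenceParams(),
    paired: bool = False,
    welch: bool = False,
    feature: str = "",
    significant: bool | None = None,
    q_flag: bool = False,
) -> DirectionCall:
    """Direction call for one feature from raw replicate vectors.

    ``significant`` overrides the default raw p < alpha gate (used by
    :func:`call_layer` when gating on BH-adjusted significance).  Two
    zero-variance vectors with equal means are called stable with p = 1.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if c.size < 2 or t.size < 2:
        raise InsufficientReplicatesError(
            f"feature {feature!r}: need >= 2 replicates per condition"
        )
    if c.mean() <= 0:
        raise UndefinedRatioError(
            f"feature {feature!r}: control mean {c.mean()} is not positive"
        )
    p = _t_test(c, t, paired, welch)
    ratio = t.mean() / c.mean()
    ci_c = mean_ci(c, params.ci_level)
    ci_t = mean_ci(t, params.ci_level)
    sig = (p < alpha) if significant is None else significant
    if sig and ratio > 1:
        call = "up"
    elif sig and ratio < 1:
        call = "down"
    elif not sig and equivalence_contained(ci_c, ci_t, params):
        call = "stable"
    else:
        call = "other"
    return DirectionCall(feature, p, q_flag, ratio, ci_c, ci_t, call)


def call_from_summary(
    mean_control: float,
    spread_control: float,
    n_control: int,
    mean_treated: float,
    spread_treated: float,
    n_treated: int,
    spread_is: str = "sd",
    alpha: float = 0.05,
    params: EquivalenceParams = EquivalenceParams(),
) -> DirectionCall:
    """Direction call from summary statistics (mean +/- sd or +/- SEM).

    Supports checking published "mean +/- spread" values under either
    reading of the spread.
    """
    if spread_is not in ("sd", "sem"):
        raise ValidationError("spread_is must be 'sd' or 'sem'")
    sd_c = spread_control * (np.sqrt(n_control) if spread_is == "sem" else 1.0)
    sd_t = spread_treated * (np.sqrt(n_treated) if spread_is == "sem" else 1.0)
    if mean_control <= 0:
        raise UndefinedRatioError("control mean must be positive")
    res = stats.ttest_ind_from_stats(
        mean_treated, sd_t, n_treated, mean_control, sd_c, n_control
    )
    p = float(res.pvalue)
    ratio = mean_treated / mean_control
    ci_c = _ci_from_summary(mean_control, sd_c, n_control, params.ci_level)
    ci_t = _ci_from_summary(mean_treated, sd_t, n_treated, params.ci_level)
    if p < alpha and ratio > 1:
        call = "up"
    elif p < alpha and ratio < 1:
        call = "down"
    elif p >= alpha and equivalence_contained(ci_c, ci_t, params):
        call = "stable"
    else:
        call = "other"
    return DirectionCall("", p, False, ratio, ci_c, ci_t, call)


def call_layer(
    table,
    layer: str,
    alpha: float = 0.05,
    params: EquivalenceParams = EquivalenceParams(),
    gate: str = "raw",
    q: float = 0.05,
    paired: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Direction calls for every feature of one layer of an AbundanceTable.

    ``gate`` selects the significance gate: ``"raw"`` uses p < alpha,
    ``"bh"`` uses Benjamini-Hochberg rejection at FDR q.  Features whose
    replicates cannot be tested (missing values, zero control mean) are
    emitted with call ``other`` and a reason, and logged.
    """
    if gate not in ("raw", "bh"):
        raise ValidationError("gate must be 'raw' or 'bh'")
    ctrl = table.condition_matrix(layer, "control")
    trt = table.condition_matrix(layer, "treated")
    rows = []
    stats_cache: dict[str, tuple] = {}
    for feat in table.features:
        c = ctrl.loc[feat].to_numpy(dtype=float)
        t = trt.loc[feat].to_numpy(dtype=float)
        c, t = c[~np.isnan(c)], t[~np.isnan(t)]
        reason = ""
        if c.size < 2 or t.size < 2:
            reason = "insufficient replicates"
        elif c.mean() <= 0:
            reason = "zero control mean"
        if reason:
            logger.info("feature %s: call=other (%s)", feat, reason)
            rows.append((feat, np.nan, np.nan, None, None, reason))
            continue
        p = _t_test(c, t, paired and c.size == t.size, welch)
        stats_cache[feat] = (c, t)
        rows.append((feat, p, t.mean() / c.mean(), mean_ci(c, params.ci_level),
                     mean_ci(t, params.ci_level), ""))

    p_tested = np.array([r[1] for r in rows if not r[5]], dtype=float)
    flags = bh_flags(p_tested, q) if p_tested.size else np.zeros(0, dtype=bool)
    flag_iter = iter(flags)

    out = []
    for feat, p, ratio, ci_c, ci_t, reason in rows:
        if reason:
            out.append(
                dict(feature=feat, layer=layer, p=np.nan, q_flag=False,
                     ratio=np.nan, ci_control_low=np.nan, ci_control_high=np.nan,
                     ci_treated_low=np.nan, ci_treated_high=np.nan,
                     call="other", gate=gate, reason=reason)
            )
            continue
        q_flag = bool(next(flag_iter))
        sig = q_flag if gate == "bh" else p < alpha
        if sig and ratio > 1:
            call = "up"
        elif sig and ratio < 1:
            call = "down"
        elif not sig and equivalence_contained(ci_c, ci_t, params):
            call = "stable"
        else:
            call = "other"
        out.append(
            dict(feature=feat, layer=layer, p=p, q_flag=q_flag, ratio=ratio,
                 ci_control_low=ci_c[0], ci_control_high=ci_c[1],
                 ci_treated_low=ci_t[0], ci_treated_high=ci_t[1],
                 call=call, gate=gate, reason=reason)
        )
    return pd.DataFrame(out).set_index("feature") if out else pd.DataFrame(
        columns=["layer", "p", "q_flag", "ratio", "ci_control_low",
                 "ci_control_high", "ci_treated_low", "ci_treated_high",
                 "call", "gate", "reason"]
    )
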