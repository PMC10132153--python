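"""Synthetic matched multi-omic datasets with known regulation groups.

The generator emulates the study design of paired fibroblast cell lines
treated with or without a cytokine: four units (cell lines), two conditions,
and five measurement layers per feature — protein intensity, total mRNA,
free mRNA, monosome-fraction mRNA and polysome-fraction mRNA — each with one
replicate column per unit per condition.

Each feature belongs to one of the 27 regulation groups; the group's triple
(protein direction, RNA direction, allocation shift) sets multiplicative
condition effects on a per-feature lognormal baseline:

* total mRNA: treated mean = baseline x RNA effect,
* monosome / polysome: the total pool times a fixed fractionation
  efficiency, split by a polysome allocation proportion theta that moves
  from its base value to a shifted value for translation-up (m_to_p)
  features and to ``1 - shifted`` for translation-down (p_to_m) features,
* protein: treated mean = baseline x protein effect; optionally the protein
  effect is coupled to the feature's realized allocation odds ratio,
* free mRNA: a fixed share of the total pool, carrying no effect template.

Replicate noise is multiplicative lognormal with a chosen coefficient of
variation (negative-binomial counts are available for RNA layers).  All
randomness flows from one seed: identical configurations reproduce the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .groups import group_triple
from .io import AbundanceTable
from .transcripts import Transcript

_EPS = 1e-12

#: Representative translation-upregulation motif used in planted-motif tests.
GROUP4_CONSENSUS = "GGAGGAGGAGGAGGAGGAGG"


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic dataset.

    Defaults mirror the emulated study design: 4 paired units, fold changes
    of 2 (up) and 0.5 (down), 10% replicate CV, and a polysome allocation
    moving from 0.5 to 0.8 for translation-up features (0.2 for
    translation-down).
    """

    n_units: int = 4
    features_per_group: Mapping[int, int] = field(default_factory=lambda: {4: 100, 14: 100})
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    effect_up: float = 2.0
    effect_down: float = 0.5
    replicate_cv: float = 0.1
    polysome_fraction_base: float = 0.5
    polysome_fraction_shifted: float = 0.8
    fractionation_efficiency: float = 0.8
    couple_protein_to_shift: bool = False
    coupling_logit_sd: float = 0.25
    library_size: float | None = None
    rna_noise: str = "lognormal"
    nb_dispersion: float = 10.0
    seed: int = 0
    utr5_range: tuple[int, int] = (60, 150)
    cds_codon_range: tuple[int, int] = (100, 300)
    utr3_range: tuple[int, int] = (80, 250)

    def validate(self) -> None:
        if self.n_units < 2:
            raise ConfigError("n_units must be >= 2")
        if not self.features_per_group:
            raise ConfigError("features_per_group must be non-empty")
        bad = set(self.features_per_group) - set(range(1, 28))
        if bad:
            raise ConfigError(f"features_per_group has ids outside 1..27: {sorted(bad)}")
        if any(n < 0 for n in self.features_per_group.values()):
            raise ConfigError("features_per_group counts must be >= 0")
        if not self.effect_up > 1:
            raise ConfigError("effect_up must be > 1")
        if not 0 < self.effect_down < 1:
            raise ConfigError("effect_down must be in (0, 1)")
        if self.replicate_cv <= 0:
            raise ConfigError("replicate_cv must be > 0")
        for name in ("polysome_fraction_base", "polysome_fraction_shifted",
                     "fractionation_efficiency"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.rna_noise not in ("lognormal", "nb"):
            raise ConfigError("rna_noise must be 'lognormal' or 'nb'")
        if self.library_size is not None and self.library_size <= 0:
            raise ConfigError("library_size must be > 0")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["features_per_group"] = dict(self.features_per_group)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset: one row per feature with the
    intended group and any planted motif / uORF, plus the seed used."""

    table: pd.DataFrame
    seed: int

    def group_of(self, feature: str) -> int:
        return int(self.table.at[feature, "group_id"])


@dataclass
class SyntheticDataset:
    abundance: AbundanceTable
    transcripts: list[Transcript]
    truth: SyntheticTruth
    config: SimulationConfig


def _theta_for(shift_call: str, config: SimulationConfig) -> float:
    if shift_call == "m_to_p":
        return config.polysome_fraction_shifted
    if shift_call == "p_to_m":
        return 1.0 - config.polysome_fraction_shifted
    return config.polysome_fraction_base


def _effect_for(direction: str, config: SimulationConfig) -> float:
    return {"up": config.effect_up, "down": config.effect_down, "stable": 1.0}[direction]


def expected_means(config: SimulationConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Noise-free per-feature expected abundances per layer and condition.

    Returns layer -> (control means, treated means) in the deterministic
    feature order used by :func:`generate_dataset`.  Useful for verifying
    the conservation property monosome + polysome = total x fractionation
    efficiency.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = _feature_groups(config)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             size=len(groups))
    return _means_from(baseline, groups, config, rng)[0]


def _feature_groups(config: SimulationConfig) -> list[int]:
    out: list[int] = []
    for gid in sorted(config.features_per_group):
        out.extend([gid] * config.features_per_group[gid])
    return out


def _means_from(baseline, groups, config, rng):
    n = len(groups)
    e_p = np.empty(n)
    e_r = np.empty(n)
    theta_c = np.full(n, config.polysome_fraction_base)
    theta_t = np.empty(n)
    for i, gid in enumerate(groups):
        p_dir, r_dir, s_dir = group_triple(gid)
        e_r[i] = _effect_for(r_dir, config)
        theta_t[i] = _theta_for(s_dir, config)
        e_p[i] = _effect_for(p_dir, config)
    if config.couple_protein_to_shift:
        shifted = theta_t != config.polysome_fraction_base
        jitter = rng.normal(0.0, config.coupling_logit_sd, size=n)
        logit = np.log(theta_t / (1 - theta_t)) + jitter * shifted
        theta_t = 1 / (1 + np.exp(-logit))
        odds_c = theta_c / (1 - theta_c)
        or_i = (theta_t / (1 - theta_t)) / odds_c
        # couple only where the protein template agrees in sign with the
        # allocation shift (e.g. group 4: protein up + m_to_p), so other
        # group templates keep their defining triple
        agree = shifted & (np.sign(e_p - 1) == np.sign(np.log(or_i)))
        template_or = (
            config.polysome_fraction_shifted
            / (1 - config.polysome_fraction_shifted)
        ) / odds_c
        # protein fold follows the realized allocation odds ratio, scaled so
        # the template odds ratio maps to effect_up
        kappa = np.log(config.effect_up) / np.log(template_or)
        e_p = np.where(agree, or_i**kappa, e_p)
    f = config.fractionation_efficiency
    means = {
        "protein": (baseline.copy(), baseline * e_p),
        "total": (baseline.copy(), baseline * e_r),
        "free": (baseline * (1 - f), baseline * e_r * (1 - f)),
        "monosome": (baseline * f * (1 - theta_c), baseline * e_r * f * (1 - theta_t)),
        "polysome": (baseline * f * theta_c, baseline * e_r * f * theta_t),
    }
    return means, e_p


def _noisy(mean: np.ndarray, config: SimulationConfig, rng, layer: str) -> np.ndarray:
    cv = config.replicate_cv
    if layer != "protein" and config.rna_noise == "nb":
        r = config.nb_dispersion
        p = r / (r + np.maximum(mean, _EPS))
        return rng.negative_binomial(r, p).astype(float)
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * rng.lognormal(-sigma**2 / 2, sigma, size=mean.shape)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate matched abundance tables, transcripts and ground truth.

    The same configuration (including seed) always reproduces identical
    output.  Features realize their group's direction/shift template in
    expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = _feature_groups(config)
    n = len(groups)
    features = [f"feat_{i:05d}" for i in range(n)]
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    means, e_p = _means_from(baseline, groups, config, rng)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for layer in ("protein", "total", "free", "monosome", "polysome"):
        for cond_idx, cond in enumerate(("control", "treated")):
            mean_vec = means[layer][cond_idx]
            for unit in range(1, config.n_units + 1):
                sid = f"{layer}_{cond}_u{unit}"
                columns[sid] = _noisy(mean_vec, config, rng, layer)
                meta_rows.append(dict(sample_id=sid, layer=layer,
                                      condition=cond, unit=f"u{unit}"))
    data = pd.DataFrame(columns, index=pd.Index(features, name="feature_id"))
    if config.library_size is not None:
        for layer in ("total", "free", "monosome", "polysome"):
            cols = [c for c in data.columns if c.startswith(layer + "_")]
            expected = float(np.mean([means[layer][0].sum(), means[layer][1].sum()]))
            data[cols] *= config.library_size / expected
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    table = AbundanceTable(data, samples)

    transcripts = _random_transcripts(features, config, rng)
    truth = pd.DataFrame(
        dict(
            feature=features,
            group_id=groups,
            protein_effect=e_p,
            motif_planted=False,
            motif_start=pd.array([pd.NA] * n, dtype="Int64"),
            motif_region="",
            uorf_planted=False,
            uorf_start=pd.array([pd.NA] * n, dtype="Int64"),
        )
    ).set_index("feature")
    return SyntheticDataset(table, transcripts, SyntheticTruth(truth, config.seed),
                            config)


def _random_transcripts(features, config, rng) -> list[Transcript]:
    bases = np.array(list("ACGT"))
    out = []
    for feat in features:
        u5 = int(rng.integers(*config.utr5_range))
        cds = 3 * int(rng.integers(*config.cds_codon_range))
        u3 = int(rng.integers(*config.utr3_range))
        body = "".join(rng.choice(bases, size=u5 + cds + u3))
        # keep the 5'UTR free of spurious ATGs so planted uORFs dominate
        seq = body[:u5].replace("ATG", "ACG") + body[u5:]
        out.append(Transcript(feat, seq, u5, cds, u3))
    return out


def plant_motif(
    transcripts: Sequence[Transcript],
    motif: str,
    target_features: Iterable[str] | None = None,
    region: str = "cds",
    rate: float = 1.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[Transcript], dict[str, int]]:
    """Insert ``motif`` verbatim into the named region of target transcripts.

    With ``rate`` < 1, exactly ``round(rate * n_targets)`` targets are chosen
    deterministically from the seed.  Returns the updated transcript list and
    a map feature -> 1-based transcript-global start of the planted copy.
    Raises if a target's region is shorter than the motif, naming the
    transcript.  Non-targets are returned unchanged.  When ``truth`` is
    given its motif columns are updated in place.
    """
    motif = motif.upper().replace("U", "T")
    if set(motif) - set("ACGT"):
        raise ValidationError("motif must be over ACGT")
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in transcripts}
    targets = list(target_features) if target_features is not None else [
        t.id for t in transcripts
    ]
    unknown = [t for t in targets if t not in by_id]
    if unknown:
        raise ValidationError(f"unknown target transcripts: {unknown[:3]}")
    if not 0 < rate <= 1:
        raise ValidationError("rate must be in (0, 1]")
    if rate < 1:
        k = int(round(rate * len(targets)))
        targets = list(rng.choice(np.array(targets, dtype=object), size=k,
                                  replace=False))
    positions: dict[str, int] = {}
    for tid in targets:
        t = by_id[tid]
        region_seq = {"utr5": t.utr5, "cds": t.cds, "utr3": t.utr3}.get(region)
        if region_seq is None:
            raise ValidationError(f"unknown region {region!r}")
        if len(region_seq) < len(motif):
            raise ValidationError(
                f"transcript {tid!r}: region {region} ({len(region_seq)} nt) "
                f"shorter than motif ({len(motif)} nt)"
            )
        local = int(rng.integers(0, len(region_seq) - len(motif) + 1))
        start = t.to_global(region, local + 1)
        seq = t.sequence
        new_seq = seq[: start - 1] + motif + seq[start - 1 + len(motif):]
        by_id[tid] = t.with_sequence(new_seq)
        positions[tid] = start
        if truth is not None and tid in truth.table.index:
            truth.table.at[tid, "motif_planted"] = True
            truth.table.at[tid, "motif_start"] = start
            truth.table.at[tid, "motif_region"] = region
    return [by_id[t.id] for t in transcripts], positions


_SAFE_CODONS = np.array(["GCA", "GCC", "GAA", "GGA", "CCA", "CTC", "TCA", "ACC"])


def plant_uorf(
    transcripts: Sequence[Transcript],
    target_features: Iterable[str] | None = None,
    start_codon: str = "ATG",
    n_codons: int = 3,
    rate: float = 1.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[Transcript], dict[str, int]]:
    """Write a short upstream ORF (start codon, ``n_codons`` stop-free
    codons, TAA) into the 5'UTR of target transcripts.

    Same targeting/determinism contract as :func:`plant_motif`.
    """
    rng = np.random.default_rng(seed)
    cassette_len = 3 * (n_codons + 2)
    by_id = {t.id: t for t in transcripts}
    targets = list(target_features) if target_features is not None else [
        t.id for t in transcripts
    ]
    if rate < 1:
        k = int(round(rate * len(targets)))
        targets = list(rng.choice(np.array(targets, dtype=object), size=k,
                                  replace=False))
    positions: dict[str, int] = {}
    for tid in targets:
        t = by_id[tid]
        if t.utr5_length < cassette_len:
            raise ValidationError(
                f"transcript {tid!r}: 5'UTR ({t.utr5_length} nt) shorter than "
                f"uORF cassette ({cassette_len} nt)"
            )
        body = "".join(rng.choice(_SAFE_CODONS, size=n_codons))
        cassette = start_codon + body + "TAA"
        local = int(rng.integers(0, t.utr5_length - cassette_len + 1))
        start = local + 1
        seq = t.sequence
        new_seq = seq[: start - 1] + cassette + seq[start - 1 + cassette_len:]
        by_id[tid] = t.with_sequence(new_seq)
        positions[tid] = start
        if truth is not None and tid in truth.table.index:
            truth.table.at[tid, "uorf_planted"] = True
            truth.table.at[tid, "uorf_start"] = start
    return [by_id[t.id] for t in transcripts], positions
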