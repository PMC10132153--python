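"""ZOOPS motif discovery, PWM scanning and exact score p-values.

The motif model is the classic "zero or one occurrence per sequence"
mixture: with prior probability gamma a sequence carries exactly one motif
site (uniform over eligible positions) emitted by a position probability
matrix, otherwise every position is background.  The model is fitted by
expectation-maximization; the observed-data log-likelihood is checked to be
non-decreasing at every iteration.

Scanning uses the log-odds score of each window and an *exact* p-value: the
null distribution of the integer-rescaled score of a background-generated
W-mer, computed by dynamic programming over per-column score distributions
(the standard lattice algorithm for PWM score significance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .transcripts import Transcript

BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(BASES)}

WIDTH_MIN_DEFAULT = 10
WIDTH_MAX_DEFAULT = 25


def encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return np.fromiter((_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def background_frequencies(sequences) -> np.ndarray:
    """0-order background frequencies of an input set (with a small floor)."""
    counts = np.zeros(4)
    for s in sequences:
        enc = s if isinstance(s, np.ndarray) else encode(s)
        counts += np.bincount(enc, minlength=4)
    freq = (counts + 1.0) / (counts.sum() + 4.0)
    return freq / freq.sum()


# ---------------------------------------------------------------------------
# fitted model (results object)
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A fitted ZOOPS motif: position probability matrix plus priors.

    Attributes
    ----------
    pwm : ndarray (4, W)
        Column-stochastic position probabilities (floored by the fit
        pseudocount).
    background : ndarray (4,)
        0-order background frequencies.
    gamma : float
        Occurrence prior: probability a sequence carries a site.
    loglik : float
        Observed-data log-likelihood of the fit.
    loglik_path : ndarray
        EM objective after each iteration (log-likelihood plus the
        Dirichlet-pseudocount log-prior on the PWM); non-decreasing.
    """

    pwm: np.ndarray
    background: np.ndarray
    gamma: float
    loglik: float
    loglik_path: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.shape[0] != 4:
            raise ValidationError("pwm must have 4 rows (A, C, G, T)")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValidationError("pwm columns must sum to 1")
        if np.any(self.background <= 0):
            raise ValidationError("background frequencies must be positive")
        if not 0 < self.gamma < 1:
            raise ValidationError("gamma must be in (0, 1)")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        return np.log(self.pwm) - np.log(self.background[:, None])


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence in 1-based inclusive transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    region: str
    score: float
    p_value: float


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

class ZoopsMotif:
    """ZOOPS motif estimator over a fixed width.

    Parameters
    ----------
    sequences : sequence of str
        Input sequences (DNA or RNA alphabet), each at least ``width`` long.
    width : int
        Motif width; the conventional discovery range is 10-25 nt but any
        positive width is accepted when set explicitly.
    background : array-like, optional
        0-order background; estimated from the input set by default.
    pseudocount : float
        Per-cell pseudocount added to expected counts at the M-step.
    """

    def __init__(self, sequences, width: int, background=None,
                 pseudocount: float = 0.01):
        if not sequences:
            raise ValidationError("empty sequence set")
        if width < 1:
            raise ValidationError("width must be >= 1")
        self.width = int(width)
        self.pseudocount = float(pseudocount)
        self._ids = []
        self._seqs: list[np.ndarray] = []
        for i, s in enumerate(sequences):
            enc = s if isinstance(s, np.ndarray) else encode(s)
            if enc.size < width:
                name = getattr(s, "id", f"sequence {i}")
                raise ValidationError(
                    f"{name} shorter ({enc.size}) than motif width {width}"
                )
            self._seqs.append(enc)
        self.background = (
            np.asarray(background, dtype=float)
            if background is not None
            else background_frequencies(self._seqs)
        )
        if np.any(self.background <= 0) or not np.isclose(self.background.sum(), 1.0):
            raise ValidationError("background must be positive and sum to 1")

    # -- internals ----------------------------------------------------------

    def _window_logodds(self, seq: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
        """Log-odds score of every window of one sequence; shape (L-W+1,)."""
        m = seq.size - self.width + 1
        scores = np.zeros(m)
        for w in range(self.width):
            scores += log_ratio[seq[w : w + m], w]
        return scores

    def _e_step(self, pwm: np.ndarray, gamma: float):
        """Posterior site probabilities and the observed-data log-likelihood.

        Also returns the penalized objective (log-likelihood plus the
        Dirichlet-pseudocount log-prior on the PWM), which MAP-EM makes
        exactly non-decreasing.
        """
        log_ratio = np.log(pwm) - np.log(self.background[:, None])
        z_list = []
        loglik = 0.0
        for seq in self._seqs:
            scores = self._window_logodds(seq, log_ratio)
            m = scores.size
            # mixture over {no site} u {site at j}; background factorizes out
            log_terms = np.concatenate(
                ([np.log1p(-gamma)], np.log(gamma / m) + scores)
            )
            top = log_terms.max()
            norm = top + np.log(np.exp(log_terms - top).sum())
            z = np.exp(log_terms - norm)
            z_list.append(z[1:])
            log_bg = np.log(self.background)[seq].sum()
            loglik += log_bg + norm
        penalized = loglik + self.pseudocount * float(np.log(pwm).sum())
        return z_list, loglik, penalized

    def _m_step(self, z_list):
        counts = np.full((4, self.width), self.pseudocount)
        occ = 0.0
        for seq, z in zip(self._seqs, z_list):
            m = z.size
            occ += z.sum()
            for w in range(self.width):
                np.add.at(counts[:, w], seq[w : w + m], z)
        pwm = counts / counts.sum(axis=0, keepdims=True)
        gamma = float(np.clip(occ / len(self._seqs), 1e-4, 1 - 1e-4))
        return pwm, gamma

    _MAX_CANDIDATES = 3000

    def _seed_starts(self, n_starts: int, rng) -> list[np.ndarray]:
        """MEME-like starting-point search, padded with random starts.

        Every data W-mer (subsampled above a cap) is evaluated as a
        candidate consensus: scored by the ZOOPS-style sum over sequences of
        the best-window log-odds it would achieve as a 0.7-match PWM.  With
        that PWM shape the window log-odds decomposes into a
        window-dependent base term plus log(0.7/0.1) per matching position,
        so all candidate scores reduce to one Hamming-similarity matrix
        (a one-hot matmul).  The top-scoring distinct W-mers seed EM.
        """
        W = self.width
        windows, seq_starts = [], [0]
        for seq in self._seqs:
            m = seq.size - W + 1
            for j in range(m):
                windows.append(seq[j : j + W])
            seq_starts.append(seq_starts[-1] + m)
        X = np.asarray(windows)  # (N, W)
        N = X.shape[0]
        cand_idx = np.arange(N)
        if N > self._MAX_CANDIDATES:
            cand_idx = np.sort(
                rng.choice(N, size=self._MAX_CANDIDATES, replace=False)
            )
        onehot = np.eye(4, dtype=np.float32)[X].reshape(N, 4 * W)
        matches = onehot[cand_idx] @ onehot.T  # (C, N) match counts
        base = W * np.log(0.1) - np.log(self.background)[X].sum(axis=1)
        scores = base[None, :] + np.log(7.0) * matches
        per_seq_best = np.maximum.reduceat(scores, seq_starts[:-1], axis=1)
        cand_scores = per_seq_best.sum(axis=1)
        order = np.argsort(-cand_scores, kind="stable")
        n_seeded = max(1, n_starts - max(1, n_starts // 3))
        starts: list[np.ndarray] = []
        seen: set[tuple] = set()
        for k in order:
            word = tuple(X[cand_idx[k]])
            if word in seen:
                continue
            seen.add(word)
            pwm = np.full((4, W), 0.1)
            pwm[list(word), np.arange(W)] = 0.7
            starts.append(pwm)
            if len(starts) >= n_seeded:
                break
        while len(starts) < n_starts:
            starts.append(rng.dirichlet(np.ones(4), size=W).T)
        return starts[:n_starts]

    # -- public fit ---------------------------------------------------------

    def fit(self, seed: int = 0, n_starts: int = 5, max_iter: int = 200,
            tol: float = 1e-6) -> MotifModel:
        """Fit by EM; best of ``n_starts`` initializations by log-likelihood.

        Deterministic given ``seed``.  Raises if the log-likelihood ever
        decreases beyond numerical noise.
        """
        rng = np.random.default_rng(seed)
        best: MotifModel | None = None
        for pwm0 in self._seed_starts(n_starts, rng):
            pwm, gamma = pwm0, 0.5
            path = []
            prev_pen = -np.inf
            loglik = -np.inf
            for _ in range(max_iter):
                z_list, loglik, pen = self._e_step(pwm, gamma)
                if pen < prev_pen - 1e-6 * max(1.0, abs(prev_pen)):
                    raise AssertionError(
                        f"EM objective decreased: {prev_pen} -> {pen}"
                    )
                path.append(pen)
                pwm, gamma = self._m_step(z_list)
                if pen - prev_pen < tol * max(1.0, abs(pen)):
                    prev_pen = pen
                    break
                prev_pen = pen
            model = MotifModel(pwm, self.background, gamma, loglik,
                               np.asarray(path))
            if best is None or model.loglik > best.loglik:
                best = model
        return best

    def null_loglik(self) -> float:
        """Log-likelihood of the background-only model (gamma -> 0)."""
        return float(sum(np.log(self.background)[s].sum() for s in self._seqs))


def zoops_em(sequences, width: int, background=None, max_iter: int = 200,
             tol: float = 1e-6, seed: int = 0, n_starts: int = 5) -> MotifModel:
    """Functional wrapper around :class:`ZoopsMotif`."""
    est = ZoopsMotif(sequences, width, background=background)
    return est.fit(seed=seed, n_starts=n_starts, max_iter=max_iter, tol=tol)


@dataclass
class DiscoveryResult:
    """Per-width fitted motifs plus the overall selection."""

    per_width: dict[int, MotifModel]
    scores: dict[int, float]
    best_width: int

    @property
    def best(self) -> MotifModel:
        return self.per_width[self.best_width]

    def table(self) -> pd.DataFrame:
        rows = [
            dict(width=w, consensus=m.consensus, gamma=m.gamma,
                 loglik=m.loglik, score=self.scores[w])
            for w, m in sorted(self.per_width.items())
        ]
        return pd.DataFrame(rows).set_index("width")


def discover(sequences, w_min: int = WIDTH_MIN_DEFAULT,
             w_max: int = WIDTH_MAX_DEFAULT, seed: int = 0,
             n_starts: int = 5, max_iter: int = 200,
             tol: float = 1e-6, background=None) -> DiscoveryResult:
    """Fit a ZOOPS motif at every width in [w_min, w_max] and select one.

    Selection is by the log-likelihood-ratio versus the background-only
    model, penalized BIC-style by the parameter count 3W + 1 with the total
    nucleotide count as the sample size (the usual convention for sequence
    models; it keeps chance flank columns from inflating the chosen width).
    """
    if w_min > w_max:
        raise ValidationError("w_min must be <= w_max")
    if not sequences:
        raise ValidationError("empty sequence set")
    per_width: dict[int, MotifModel] = {}
    scores: dict[int, float] = {}
    total_nt = sum(len(s) for s in sequences)
    for w in range(w_min, w_max + 1):
        est = ZoopsMotif(sequences, w, background=background)
        model = est.fit(seed=seed + w, n_starts=n_starts, max_iter=max_iter,
                        tol=tol)
        llr = model.loglik - est.null_loglik()
        scores[w] = llr - 0.5 * (3 * w + 1) * np.log(total_nt)
        per_width[w] = model
    best_width = max(scores, key=lambda w: (scores[w], -w))
    return DiscoveryResult(per_width, scores, best_width)


# ---------------------------------------------------------------------------
# exact score distribution
# ---------------------------------------------------------------------------

class ScoreDistribution:
    """Exact null distribution of integer-rescaled PWM log-odds scores.

    Scores are rescaled to an integer lattice with step ``precision`` and
    the distribution of the total score of a background W-mer is built by
    dynamic programming, one column at a time.  ``p_value`` is then the
    exact survival probability on that lattice.
    """

    def __init__(self, pwm, background, precision: float = 1e-3):
        pwm = np.asarray(pwm, dtype=float)
        background = np.asarray(background, dtype=float)
        if np.any(background <= 0):
            raise ValidationError("degenerate background: zero frequency")
        if np.any(pwm <= 0):
            raise ValidationError("pwm must be strictly positive (use a pseudocount)")
        self.precision = float(precision)
        log_odds = np.log(pwm) - np.log(background[:, None])
        self.int_scores = np.round(log_odds / precision).astype(np.int64)
        width = pwm.shape[1]
        lo = int(self.int_scores.min(axis=0).sum())
        hi = int(self.int_scores.max(axis=0).sum())
        size = hi - lo + 1
        if size > 50_000_000:
            raise ValidationError(
                "score lattice too large; use a coarser precision"
            )
        self.offset = lo
        # convolve per-column score distributions, point mass at 0 shifted so
        # the minimum attainable total lands at lattice index 0
        dist = np.zeros(size)
        dist[-lo] = 1.0
        for w in range(width):
            new = np.zeros(size)
            col = self.int_scores[:, w]
            nz = np.nonzero(dist)[0]
            for b in range(4):
                new[nz + int(col[b])] += dist[nz] * background[b]
            dist = new
        self.pmf = dist
        sf = np.cumsum(dist[::-1])[::-1]
        self.sf = np.minimum(sf, 1.0)
        self.width = width

    def int_score(self, word: np.ndarray) -> int:
        return int(self.int_scores[word, np.arange(self.width)].sum())

    def p_value_int(self, score: int) -> float:
        idx = score - self.offset
        if idx < 0:
            return 1.0
        if idx >= self.sf.size:
            return 0.0
        return float(self.sf[idx])

    def p_value(self, score: float) -> float:
        """P(background W-mer scores >= score), score in log-odds units."""
        if score == -np.inf:
            return 1.0
        return self.p_value_int(int(np.round(score / self.precision)))


def exact_score_pvalue(model: MotifModel, score: float,
                       background=None, precision: float = 1e-3) -> float:
    """Exact p-value of a log-odds score under the background model."""
    bg = model.background if background is None else np.asarray(background)
    return ScoreDistribution(model.pwm, bg, precision).p_value(score)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _select_nonoverlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy selection by ascending p-value, ties broken leftmost."""
    chosen: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (h.p_value, h.start)):
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def log_odds_scan(model: MotifModel, transcript: Transcript,
                  p_threshold: float = 1e-4,
                  precision: float = 1e-3,
                  dist: ScoreDistribution | None = None) -> list[MotifHit]:
    """Scan a transcript (sense strand only) with a fitted PWM.

    Windows with exact score p-value <= ``p_threshold`` are reported, made
    non-overlapping greedily by ascending p-value, and labeled with the
    annotated region they fall in ('spanning' across a boundary).
    """
    w = model.width
    if len(transcript) < w:
        return []
    if dist is None:
        dist = ScoreDistribution(model.pwm, model.background, precision)
    seq = encode(transcript.sequence)
    m = seq.size - w + 1
    scores = np.zeros(m, dtype=np.int64)
    for k in range(w):
        scores += dist.int_scores[seq[k : k + m], k]
    hits = []
    for j in range(m):
        p = dist.p_value_int(int(scores[j]))
        if p <= p_threshold:
            start, end = j + 1, j + w
            hits.append(MotifHit(
                transcript.id, start, end,
                transcript.region_of_interval(start, end),
                float(scores[j]) * dist.precision, p,
            ))
    return _select_nonoverlapping(hits)


def exact_scan(pattern: str, transcript: Transcript) -> list[MotifHit]:
    """Exact-substring search mode; hits carry score 0 and p-value 0."""
    pat = pattern.upper().replace("U", "T")
    seq = transcript.sequence
    hits = []
    j = seq.find(pat)
    while j != -1:
        start, end = j + 1, j + len(pat)
        hits.append(MotifHit(transcript.id, start, end,
                             transcript.region_of_interval(start, end), 0.0, 0.0))
        j = seq.find(pat, j + 1)
    return hits


def region_occurrence_table(
    model_or_consensus,
    transcripts_by_group: dict,
    p_threshold: float = 1e-4,
    precision: float = 1e-3,
) -> pd.DataFrame:
    """Per-group motif occurrence: fraction of transcripts with >= 1 hit and
    the region breakdown of hits.

    ``model_or_consensus`` is either a fitted :class:`MotifModel` (scanned
    with exact p-values) or a consensus string (exact-substring mode).
    Empty groups are reported with n = 0 and NaN fractions.
    """
    exact = isinstance(model_or_consensus, str)
    dist = None
    if not exact:
        dist = ScoreDistribution(model_or_consensus.pwm,
                                 model_or_consensus.background, precision)
    rows = []
    for gid, transcripts in sorted(transcripts_by_group.items()):
        n = len(transcripts)
        n_with = 0
        region_counts = {"utr5": 0, "cds": 0, "utr3": 0, "spanning": 0}
        for t in transcripts:
            hits = (exact_scan(model_or_consensus, t) if exact
                    else log_odds_scan(model_or_consensus, t, p_threshold,
                                       dist=dist))
            if hits:
                n_with += 1
            for h in hits:
                region_counts[h.region] += 1
        total_hits = sum(region_counts.values())
        row = dict(group=gid, n=n,
                   fraction_with_hit=(n_with / n if n else np.nan),
                   n_hits=total_hits)
        for region, c in region_counts.items():
            row[f"frac_{region}"] = c / total_hits if total_hits else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
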