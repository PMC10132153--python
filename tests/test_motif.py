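"""ZOOPS EM discovery, exact score p-values, and PWM scanning."""

import itertools

import numpy as np
import pytest

from transreg import Transcript, exact_scan, log_odds_scan, zoops_em
from transreg.errors import ValidationError
from transreg.motif import (
    MotifModel,
    ScoreDistribution,
    ZoopsMotif,
    discover,
    region_occurrence_table,
)
from transreg.simulate import GROUP4_CONSENSUS


def _consensus_model(consensus, match=0.97, background=None):
    w = len(consensus)
    idx = {b: i for i, b in enumerate("ACGT")}
    pwm = np.full((4, w), (1 - match) / 3)
    for k, b in enumerate(consensus):
        pwm[idx[b], k] = match
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return MotifModel(pwm, bg, gamma=0.5, loglik=0.0)


class TestZoopsEM:
    def test_recovers_planted_20mer(self, planted_sequences):
        model = zoops_em(planted_sequences, 20, seed=0)
        assert model.consensus == GROUP4_CONSENSUS
        assert model.gamma > 0.9

    def test_objective_nondecreasing(self, planted_sequences):
        model = zoops_em(planted_sequences, 20, seed=0)
        assert np.all(np.diff(model.loglik_path) >= -1e-9)

    def test_sequence_shorter_than_width_errors(self):
        with pytest.raises(ValidationError):
            zoops_em(["ACGTACGTACGT", "ACGTA"], 10)

    def test_null_background_gives_small_gain(self):
        # on pure i.i.d. background the fitted motif should add little
        # likelihood over the background-only model, across seeds
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(20)]
        est = ZoopsMotif(seqs, 10)
        null = est.null_loglik()
        gains = []
        for seed in range(5):
            model = est.fit(seed=seed, n_starts=3, max_iter=50)
            gains.append(model.loglik - null)
        # a real planted 10-mer would add hundreds of nats; noise adds a
        # bounded overfitting gain
        planted = zoops_em(
            [s[:45] + "GGAGGAGGAG" + s[55:] for s in seqs], 10, seed=0
        )
        assert max(gains) < 0.3 * (planted.loglik - ZoopsMotif(
            [s[:45] + "GGAGGAGGAG" + s[55:] for s in seqs], 10).null_loglik())


class TestDiscover:
    def test_width_selection_picks_planted_width(self, planted_sequences):
        res = discover(planted_sequences, 10, 25, seed=0)
        assert res.best_width == 20
        assert res.best.consensus == GROUP4_CONSENSUS

    def test_empty_sequence_set_errors(self):
        with pytest.raises(ValidationError):
            discover([], 10, 12)

    def test_two_planted_motifs_both_in_per_width_table(self):
        rng = np.random.default_rng(23)
        m12, m20 = "ACGTACGTACGT", GROUP4_CONSENSUS
        seqs = []
        for i in range(24):
            s = "".join(rng.choice(list("ACGT"), size=90))
            motif = m12 if i < 12 else m20
            j = int(rng.integers(0, 90 - len(motif) + 1))
            seqs.append(s[:j] + motif + s[j + len(motif):])
        res = discover(seqs, 12, 20, seed=0)
        assert res.per_width[12].consensus == m12
        assert res.per_width[20].consensus == m20


class TestExactScorePValue:
    def test_single_column_analytic(self):
        model = _consensus_model("G", match=0.97)
        dist = ScoreDistribution(model.pwm, model.background)
        best = int(dist.int_scores.max())
        assert dist.p_value_int(best) == pytest.approx(0.25)

    def test_minus_infinity_scores_p_one(self):
        model = _consensus_model("GATTAC")
        dist = ScoreDistribution(model.pwm, model.background)
        assert dist.p_value(-np.inf) == 1.0

    @pytest.mark.parametrize("width", [4, 6])
    def test_dp_equals_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        for _ in range(3):
            pwm = rng.dirichlet(np.ones(4), size=width).T
            pwm = np.clip(pwm, 1e-3, None)
            pwm /= pwm.sum(axis=0)
            bg = rng.dirichlet(np.ones(4) * 5)
            dist = ScoreDistribution(pwm, bg, precision=1e-3)
            words = np.array(list(itertools.product(range(4), repeat=width)))
            ints = dist.int_scores[words, np.arange(width)].sum(axis=1)
            probs = bg[words].prod(axis=1)
            for s in np.unique(ints):
                brute = probs[ints >= s].sum()
                assert dist.p_value_int(int(s)) == pytest.approx(
                    brute, abs=1e-9)

    def test_zero_background_frequency_rejected(self):
        with pytest.raises(ValidationError):
            ScoreDistribution(np.full((4, 3), 0.25), [0.5, 0.5, 0.0, 0.0])


class TestScan:
    def test_consensus_scans_against_own_model(self):
        cons = GROUP4_CONSENSUS
        model = _consensus_model(cons)
        t = Transcript("t", cons + "ATATATATAT", 0, len(cons) + 10, 0)
        hits = log_odds_scan(model, t, 1e-4)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].region) == (1, len(cons),
                                                                "cds")

    def test_poly_a_has_no_hits_for_g_rich_model(self):
        model = _consensus_model(GROUP4_CONSENSUS)
        t = Transcript("a", "A" * 80, 20, 45, 15)
        assert log_odds_scan(model, t, 1e-4) == []

    def test_hits_are_nonoverlapping_and_sorted(self):
        cons = "GGAGGAGGAG"
        model = _consensus_model(cons)
        seq = cons + "TTTT" + cons + "TTTT" + cons
        t = Transcript("m", seq, 0, len(seq), 0)
        hits = log_odds_scan(model, t, 1e-3)
        assert len(hits) == 3
        for a, b in zip(hits, hits[1:]):
            assert a.end < b.start

    def test_reverse_complement_loses_sense_hits(self):
        # sense-strand-only scanning: a non-palindromic motif disappears
        # when the transcript is reverse-complemented
        from Bio.Seq import Seq

        cons = GROUP4_CONSENSUS
        model = _consensus_model(cons)
        seq = "ATAT" + cons + "CGCG"
        t = Transcript("s", seq, 0, len(seq), 0)
        rc = Transcript("rc", str(Seq(seq).reverse_complement()), 0, len(seq), 0)
        assert len(log_odds_scan(model, t, 1e-4)) == 1
        assert log_odds_scan(model, rc, 1e-4) == []

    def test_exact_scan_reports_printed_coordinates(self):
        # an exact instance placed at CDS-local 315 must be reported there
        rng = np.random.default_rng(8)
        instance = "CCTGAAGCCACTGATGGAAG"
        utr5 = 50
        cds = "".join(rng.choice(list("ACT"), size=1200))
        cds = cds[:314] + instance + cds[314 + 20:]
        seq = "".join(rng.choice(list("ACT"), size=utr5)) + cds
        t = Transcript("neu3_synthetic", seq, utr5, 1200, 0)
        hits = exact_scan(instance, t)
        assert len(hits) == 1
        region, local = t.to_region_local(hits[0].start)
        assert region == "cds" and local == 315
        assert hits[0].end - hits[0].start + 1 == 20

    def test_coordinate_roundtrip(self):
        t = Transcript("r", "ACGT" * 30, 25, 60, 35)
        for pos in (1, 25, 26, 85, 86, 120):
            region, local = t.to_region_local(pos)
            assert t.to_global(region, local) == pos


class TestRegionOccurrence:
    def test_planted_group_dominates(self, small_dataset):
        from transreg import plant_motif

        truth = small_dataset.truth.table
        g4 = list(truth.index[truth["group_id"] == 4])
        transcripts, _ = plant_motif(
            small_dataset.transcripts, GROUP4_CONSENSUS, g4, "cds",
            rate=0.9, seed=3,
        )
        by_group = {}
        for t in transcripts:
            by_group.setdefault(int(truth.at[t.id, "group_id"]), []).append(t)
        table = region_occurrence_table(GROUP4_CONSENSUS, by_group)
        assert table.at[4, "fraction_with_hit"] == pytest.approx(0.9, abs=0.02)
        assert table.at[14, "fraction_with_hit"] < 0.05
        assert table.at[4, "frac_cds"] > 0.9

    def test_utr3_planting_concentrates_in_utr3(self, small_dataset):
        from transreg import plant_motif

        targets = list(small_dataset.truth.table.index[:20])
        transcripts, _ = plant_motif(
            small_dataset.transcripts, GROUP4_CONSENSUS, targets, "utr3",
            seed=5,
        )
        chosen = [t for t in transcripts if t.id in targets]
        table = region_occurrence_table(GROUP4_CONSENSUS, {0: chosen})
        assert table.at[0, "frac_utr3"] == 1.0

    def test_empty_group_reported_not_divided(self):
        table = region_occurrence_table(GROUP4_CONSENSUS, {5: []})
        assert table.at[5, "n"] == 0
        assert np.isnan(table.at[5, "fraction_with_hit"])
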