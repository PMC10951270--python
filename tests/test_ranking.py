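"""Isomer rescoring: candidate generation, ranking, summaries, explanation."""

import numpy as np
import pytest

from glycospec.fragments import FragmentIndex, GlycopeptidePrecursor
from glycospec.glycans import parse_glycan_struct, serialize_canonical
from glycospec.network import GlycoSpectrumNetwork, ModelConfig
from glycospec.peptides import PeptideSequence
from glycospec.ranking import (
    CandidateResult,
    explain_candidate,
    generate_candidates,
    rank_candidates,
    summarize_recognition,
)
from glycospec.simulate import SimConfig, glycan_space_for, to_peak_list
from glycospec.spectra import AnnotatedSpectrum, Spectrum

ISOMER_A = "(N(N(H(H(N)(N))(H))))"  # both antennae on one arm
ISOMER_B = "(N(N(H(H(N))(H(N)))))"  # one antenna per arm


@pytest.fixture(scope="module")
def net():
    return GlycoSpectrumNetwork(ModelConfig(hidden_size=16, with_B=True), seed=5)


@pytest.fixture(scope="module")
def trained_net():
    # a lightly trained model so predicted spectra are structure-sensitive
    from glycospec.simulate import generate_dataset
    from glycospec.training import TrainConfig, train

    obs, _t, _ = generate_dataset(SimConfig(seed=77, n_precursors=60))
    n = GlycoSpectrumNetwork(ModelConfig(hidden_size=16, dropout=0.0), seed=5)
    train(n, obs, [], TrainConfig(seed=5, max_epochs=12))
    return n


def predicted_query(net, precursor, noise_cv=0.0, rng=None):
    """A peak-list query generated from the model's own prediction."""
    index = FragmentIndex(precursor, with_B=net.config.with_B)
    pred = net.predict(index)
    rec = AnnotatedSpectrum(
        index,
        pred.full[: index.n_pep].copy(),
        pred.full[index.n_pep : index.n_pep + index.n_y].copy(),
        pred.full[index.n_pep + index.n_y :].copy(),
    )
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        for v in (rec.s_pep, rec.s_y, rec.s_b):
            nz = np.flatnonzero(v)
            v[nz] *= rng.lognormal(-sigma * sigma / 2, sigma, nz.size)
    return to_peak_list(rec)


class TestCandidateGeneration:
    def test_isomers_only(self):
        pep = PeptideSequence("LNSTAVK", 1)
        prec = GlycopeptidePrecursor(pep, parse_glycan_struct(ISOMER_A), 2)
        space = [parse_glycan_struct(s) for s in (ISOMER_A, ISOMER_B, "(N)")]
        cands = generate_candidates(prec, space)
        assert len(cands) == 2
        comp = str(prec.glycan.composition())
        for c in cands:
            assert str(c.glycan.composition()) == comp
            assert c.peptide is pep and c.charge == 2

    def test_single_isomer(self):
        pep = PeptideSequence("LNSTAVK", 1)
        prec = GlycopeptidePrecursor(pep, parse_glycan_struct(ISOMER_A), 2)
        cands = generate_candidates(prec, [parse_glycan_struct(ISOMER_A)])
        assert len(cands) == 1


class TestRanking:
    def _candidates(self, charge=2):
        pep = PeptideSequence("LNSTAVK", 1)
        return [
            GlycopeptidePrecursor(pep, parse_glycan_struct(s), charge)
            for s in (ISOMER_A, ISOMER_B)
        ]

    def test_self_prediction_ranks_first(self, trained_net):
        cands = self._candidates()
        for true in cands:
            q = predicted_query(trained_net, true)
            results = rank_candidates(q, cands, trained_net)
            assert results[0].glycan_string == serialize_canonical(true.glycan)
            assert results[0].rank == 1
            assert results[0].sa_Y == pytest.approx(0.0, abs=1e-6)
            assert results[0].score == pytest.approx(1.0, abs=1e-6)

    def test_scores_follow_similarity(self):
        # synthetic results: score = alpha(1-SA_Y)+beta(1-SA_B), rank by score
        pep = PeptideSequence("LNSTAVK", 1)
        prec = GlycopeptidePrecursor(pep, parse_glycan_struct(ISOMER_A), 2)
        good = CandidateResult(prec, "a", 0.1, 0.1, None, 0.9, 0, False, False)
        bad = CandidateResult(prec, "b", 0.3, 0.3, None, 0.7, 0, False, False)
        assert good.score > bad.score

    def test_ranking_invariant_to_query_scaling(self, trained_net):
        cands = self._candidates()
        q = predicted_query(trained_net, cands[0])
        scaled = Spectrum(q.mz, q.intensity * 1234.5,
                          precursor_mz=q.precursor_mz,
                          precursor_charge=q.precursor_charge)
        r1 = rank_candidates(q, cands, trained_net)
        r2 = rank_candidates(scaled, cands, trained_net)
        assert [r.glycan_string for r in r1] == [r.glycan_string for r in r2]
        assert np.allclose([r.score for r in r1], [r.score for r in r2])

    def test_discard_rule_is_score_neutral(self, trained_net):
        cands = self._candidates()
        q = predicted_query(trained_net, cands[0])
        # add peaks far from every theoretical fragment of any candidate
        noisy = Spectrum(
            np.concatenate([q.mz, [3999.0, 3999.5]]),
            np.concatenate([q.intensity, [99.0, 99.0]]),
        )
        r1 = rank_candidates(q, cands, trained_net)
        r2 = rank_candidates(noisy, cands, trained_net)
        for a, b in zip(r1, r2):
            assert a.score == pytest.approx(b.score, abs=1e-12)

    def test_unmatchable_query_rejected(self, net):
        cands = self._candidates()
        q = Spectrum([5000.0], [1.0])
        with pytest.raises(ValueError):
            rank_candidates(q, cands, net)

    def test_deterministic_tie_break(self, net):
        results = [
            CandidateResult(None, s, 0.5, None, None, 0.5, 0, False, False)
            for s in ("(B)", "(A)")
        ]
        results.sort(key=lambda r: (-r.score, r.glycan_string))
        assert [r.glycan_string for r in results] == ["(A)", "(B)"]


class TestSummaries:
    def _mk(self, glycan_string, rank, fuc=False, bis=False):
        return CandidateResult(
            None, glycan_string, 0.1, None, None, 1.0 - 0.1 * rank, rank,
            fuc, bis,
        )

    def test_all_correct_top1(self):
        trees = [parse_glycan_struct(ISOMER_A)] * 4
        key = serialize_canonical(trees[0])
        ranked = [
            [self._mk(key, 1), self._mk("(N)", 2), self._mk("(H)", 3),
             self._mk("(F)", 4), self._mk("(A)", 5)]
        ] * 4
        s = summarize_recognition(ranked, trees)
        assert s["rank1_rate"] == 1.0 and s["top3_rate"] == 1.0

    def test_denominators_follow_candidate_counts(self):
        trees = [parse_glycan_struct(ISOMER_A)] * 3
        key = serialize_canonical(trees[0])
        two = [self._mk(key, 1), self._mk("(N)", 2)]
        five = [self._mk(key, 4)] + [
            self._mk(f"({c})", i) for i, c in zip((1, 2, 3, 5), "NHFA")
        ]
        ranked = [two, two, five]
        s = summarize_recognition(ranked, trees)
        assert s["n_rank1"] == 3  # all have > 1 candidate
        assert s["n_top3"] == 1  # only the 5-candidate case counts
        assert s["top3_rate"] == 0.0  # rank 4 there

    def test_confusion_excludes_uniform_categories(self):
        trees = [parse_glycan_struct(ISOMER_A)] * 2
        key = serialize_canonical(trees[0])
        uniform = [self._mk(key, 1, fuc=True), self._mk("(N)", 2, fuc=True)]
        mixed = [self._mk("(N)", 1, fuc=True), self._mk(key, 2, fuc=False)]
        s = summarize_recognition([uniform, mixed], trees)
        cm = s["core_fucose_confusion"]
        assert cm.to_numpy().sum() == 1  # only the mixed case counted
        assert cm.loc["true_neg", "pred_pos"] == 1


class TestExplanation:
    def test_weights_partition(self, net):
        pep = PeptideSequence("LNSTAVK", 1)
        prec = GlycopeptidePrecursor(pep, parse_glycan_struct(ISOMER_A), 2)
        g = explain_candidate(prec, net)
        for node, d in g.nodes(data=True):
            if d["layer"] == "composition":
                ws = [g.edges[e]["weight"] for e in g.in_edges(node)]
                assert sum(ws) == pytest.approx(1.0, abs=1e-9)
            elif d["layer"] == "structure":
                ws = [g.edges[e]["weight"] for e in g.in_edges(node)]
                assert sum(ws) == pytest.approx(1.0, abs=1e-9)

    def test_single_member_composition_weight_one(self, net):
        pep = PeptideSequence("LNSTAVK", 1)
        prec = GlycopeptidePrecursor(pep, parse_glycan_struct("(N(N(H)))"), 2)
        g = explain_candidate(prec, net)
        for node, d in g.nodes(data=True):
            if d["layer"] == "composition":
                (edge,) = list(g.in_edges(node))
                assert g.edges[edge]["weight"] == pytest.approx(1.0)
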