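import numpy as np
import pytest

from peptinfer.io_encoding import (
    DataError,
    PeptideObservation,
    ProteinRecord,
    ProteomeLayout,
    build_encoding,
)
from peptinfer.evaluation import (
    EvaluationReport,
    LabeledRanking,
    decoy_augment,
    degenerate_precision,
    f1_at_k,
    make_decoys,
    pr_auc,
    roc_auc,
    target_decoy_eval,
)
from peptinfer.scoring import ProteinScore
from peptinfer.synthetic import tryptic_digest


def ranking_from(scores, labels):
    ids = [f"X{i}" for i in range(len(scores))]
    ranked = [ProteinScore(i, s, 1) for i, s in zip(ids, scores)]
    positives = {i for i, l in zip(ids, labels) if l}
    return LabeledRanking.from_scores(ranked, positives)


def roc_auc_pair_oracle(scores, labels):
    """O(n^2) probability-of-correct-ordering with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def pr_auc_sweep_oracle(scores, labels):
    """Exhaustive threshold sweep: sum of precision gains at each positive."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], not labels[i]))
    # break score ties exactly as the step-wise interpolation does: average
    # precision over the tie group
    n_pos = sum(labels)
    tp = fp = 0
    area = 0.0
    i = 0
    while i < len(order):
        j = i
        tie_tp = tie_fp = 0
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]]:
                tie_tp += 1
            else:
                tie_fp += 1
            j += 1
        tp += tie_tp
        fp += tie_fp
        if tie_tp:
            area += tie_tp * tp / (tp + fp)
        i = j
    return area / n_pos


class TestRocAuc:
    def test_perfect_ranking(self):
        r = ranking_from([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc_auc(r) == 1.0

    def test_all_tied_scores_give_half(self):
        r = ranking_from([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc_auc(r) == 0.5

    def test_four_item_against_pair_oracle(self):
        scores = [0.9, 0.4, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        r = ranking_from(scores, labels)
        assert roc_auc(r) == pytest.approx(roc_auc_pair_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(ranking_from([0.1, 0.2], [1, 1]))

    def test_random_instances_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n).tolist()
            labels = rng.integers(0, 2, size=n).tolist()
            if sum(labels) in (0, n):
                continue
            r = ranking_from(scores, labels)
            assert roc_auc(r) == pytest.approx(
                roc_auc_pair_oracle(scores, labels), abs=1e-12
            )


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc(ranking_from([0.9, 0.8, 0.2], [1, 1, 0])) == 1.0

    def test_single_positive_ranked_last(self):
        n = 10
        scores = list(np.linspace(1.0, 0.1, n))
        labels = [0] * (n - 1) + [1]
        assert pr_auc(ranking_from(scores, labels)) == pytest.approx(1 / n)

    def test_random_instances_match_sweep_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 50))
            scores = rng.choice([0.2, 0.4, 0.6, 0.8], size=n).tolist()
            labels = rng.integers(0, 2, size=n).tolist()
            if sum(labels) == 0:
                continue
            r = ranking_from(scores, labels)
            assert pr_auc(r) == pytest.approx(
                pr_auc_sweep_oracle(scores, labels), abs=1e-12
            )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc(ranking_from([0.5, 0.4], [0, 0]))


class TestF1AtK:
    def test_perfect_topk(self):
        r = ranking_from([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        f1_pos, f1_neg = f1_at_k(r, 2)
        assert f1_pos == 1.0 and f1_neg == 1.0

    def test_k_equals_n_boundary(self):
        # everything called positive: recall 1, precision = prevalence
        labels = [1, 1, 0, 0, 0]
        r = ranking_from([0.9, 0.8, 0.7, 0.6, 0.5], labels)
        f1_pos, f1_neg = f1_at_k(r, 5)
        prevalence = 2 / 5
        assert f1_pos == pytest.approx(2 * prevalence / (1 + prevalence))
        assert f1_neg == 0.0

    def test_six_item_toy_hand_computed(self):
        # top-3 call with 2 true positives inside: P=2/3, R=2/3 -> F1=2/3
        labels = [1, 0, 1, 1, 0, 0]
        r = ranking_from([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], labels)
        f1_pos, f1_neg = f1_at_k(r, 3)
        assert f1_pos == pytest.approx(2 / 3)
        assert f1_neg == pytest.approx(2 / 3)

    @pytest.mark.parametrize("k", [0, 7])
    def test_k_out_of_range(self, k):
        r = ranking_from([0.5] * 6, [1, 0, 1, 0, 1, 0])
        with pytest.raises(ValueError):
            f1_at_k(r, k)


class TestDegeneratePrecision:
    def _encoding(self, shared):
        prots = [
            ProteinRecord("T", "W" * 30 + "AKAKCCDD" + "W" * 30),
            ProteinRecord("F", "H" * 30 + ("AKAKCCDD" if shared else "MMNNQQSS") + "H" * 30),
        ]
        peps = [PeptideObservation("AKAKCCDD", 0.9)]
        if not shared:
            peps.append(PeptideObservation("MMNNQQSS", 0.3))
        return build_encoding(ProteomeLayout(prots), peps)

    def test_no_shared_peptide_reports_absent(self):
        enc = self._encoding(shared=False)
        r = ranking_from([0.9, 0.1], [1, 0])
        assert degenerate_precision(r, enc, 1) is None

    def test_topk_only_true_degenerate(self):
        enc = self._encoding(shared=True)
        ranked = [ProteinScore("T", 0.9, 1), ProteinScore("F", 0.1, 1)]
        r = LabeledRanking.from_scores(ranked, {"T"})
        assert degenerate_precision(r, enc, 1) == 1.0

    def test_topk_contains_both(self):
        enc = self._encoding(shared=True)
        ranked = [ProteinScore("T", 0.9, 1), ProteinScore("F", 0.8, 1)]
        r = LabeledRanking.from_scores(ranked, {"T"})
        assert degenerate_precision(r, enc, 2) == 0.5


class TestDecoys:
    DB = [
        ProteinRecord("P1", "AAKGGRPLLKMM"),
        ProteinRecord("P2", "MNQRSTVWYCDE"),
    ]

    def test_length_and_composition_preserved(self):
        decoys = make_decoys(self.DB, seed=11)
        for target, decoy in zip(self.DB, decoys):
            assert len(decoy.sequence) == len(target.sequence)
            assert sorted(decoy.sequence) == sorted(target.sequence)
            assert decoy.id == "DECOY_" + target.id

    def test_cleavage_residues_held_fixed(self):
        (decoy,) = make_decoys([ProteinRecord("P1", "AAKGGR")], seed=3)
        # tryptic peptides AAK + GGR keep K at index 2 and R at index 5
        assert decoy.sequence[2] == "K"
        assert decoy.sequence[5] == "R"
        assert sorted(decoy.sequence[:2]) == ["A", "A"]
        assert sorted(decoy.sequence[3:5]) == ["G", "G"]

    def test_decoy_digest_peptide_lengths_match(self):
        decoys = make_decoys(self.DB, seed=7)
        for target, decoy in zip(self.DB, decoys):
            assert [len(p) for p in tryptic_digest(target.sequence)] == [
                len(p) for p in tryptic_digest(decoy.sequence)
            ]

    def test_peptide_order_mode_concatenates_same_peptides(self):
        (decoy,) = make_decoys(
            [ProteinRecord("P1", "AAKGGRPLLKMM")], seed=5, mode="peptide"
        )
        target_peps = sorted(tryptic_digest("AAKGGRPLLKMM"))
        assert len(decoy.sequence) == 12
        assert sorted(decoy.sequence) == sorted("AAKGGRPLLKMM")
        # the decoy is a concatenation of the same whole peptides
        remaining = decoy.sequence
        used = []
        while remaining:
            for pep in target_peps:
                if pep not in used and remaining.startswith(pep):
                    used.append(pep)
                    remaining = remaining[len(pep):]
                    break
            else:
                pytest.fail("decoy is not a permutation of whole tryptic peptides")

    def test_augment_doubles_database(self):
        augmented = decoy_augment(self.DB, seed=1)
        assert len(augmented) == 2 * len(self.DB)
        assert len({p.id for p in augmented}) == 2 * len(self.DB)


class TestTargetDecoyEval:
    def test_targets_above_decoys_gives_auc_one(self):
        ranked = [
            ProteinScore("A", 0.9, 1), ProteinScore("B", 0.8, 1),
            ProteinScore("DECOY_A", 0.2, 1), ProteinScore("DECOY_B", 0.1, 1),
        ]
        report = target_decoy_eval(ranked)
        assert report.auc_roc == 1.0
        assert report.auc_pr == 1.0

    def test_random_scores_near_half(self, rng):
        ids = [f"T{i}" for i in range(300)] + [f"DECOY_T{i}" for i in range(300)]
        ranked = [ProteinScore(i, float(rng.random()), 1) for i in ids]
        report = target_decoy_eval(ranked)
        # permutation null: sd of AUC ~ sqrt((n+m+1)/(12 n m)) ~ 0.024
        assert abs(report.auc_roc - 0.5) < 0.12

    def test_missing_decoys_rejected(self):
        with pytest.raises(DataError):
            target_decoy_eval([ProteinScore("A", 0.5, 1)])

    def test_report_roundtrips(self, tmp_path):
        report = EvaluationReport(0.9, 0.8, 0.7, 0.6, None, 5)
        report.write_tsv(tmp_path / "r.tsv")
        report.to_json(tmp_path / "r.json")
        text = (tmp_path / "r.tsv").read_text()
        assert "auc_roc\t0.9" in text and "degenerate_precision\tNA" in text
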