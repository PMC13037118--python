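"""Percent identity, peptide censuses, strategy tables and permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pheroscan.compare import (MATING_STRATEGIES, pairwise_identity,
                               percent_identity, permutation_association,
                               read_strategy_table, summarize_by_strategy,
                               unique_peptides)
from pheroscan.config import AlignConfig
from pheroscan.seqio import SequenceRecord

BLOSUM62 = None


def _blosum():
    global BLOSUM62
    if BLOSUM62 is None:
        import biotite.sequence.align as balign
        m = balign.SubstitutionMatrix.std_protein_matrix()
        alph = m.get_alphabet1()
        BLOSUM62 = {(a, b): m.get_score(a, b) for a in alph for b in alph}
    return BLOSUM62


def oracle_alignments(a: str, b: str, gap_open=10.0, gap_ext=0.5):
    """Enumerate every global alignment; return (max score, set of identity
    fractions among score-optimal alignments). Terminal gaps are penalised."""
    scores = _blosum()
    best = [-np.inf, set()]

    def walk(i, j, score, matches, cols, last):
        if i == len(a) and j == len(b):
            if score > best[0] + 1e-9:
                best[0], best[1] = score, {(matches, cols)}
            elif abs(score - best[0]) <= 1e-9:
                best[1].add((matches, cols))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + scores[(a[i], b[j])],
                 matches + (a[i] == b[j]), cols + 1, "m")
        if i < len(a):
            pen = gap_ext if last == "a" else gap_open
            walk(i + 1, j, score - pen, matches, cols + 1, "a")
        if j < len(b):
            pen = gap_ext if last == "b" else gap_open
            walk(i, j + 1, score - pen, matches, cols + 1, "b")

    walk(0, 0, 0.0, 0, 0, None)
    return best[0], {100.0 * m / c for m, c in best[1]}


class TestPercentIdentity:
    def test_identical_sequences(self):
        assert percent_identity("WGQEPGQP", "WGQEPGQP") == pytest.approx(100.0)

    def test_single_mismatch_gapless(self):
        assert percent_identity("AAAA", "AAAT") == pytest.approx(75.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "AAAA")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_alignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        la, lb = rng.integers(3, 7, size=2)
        a = "".join(alphabet[i] for i in rng.integers(20, size=la))
        b = "".join(alphabet[i] for i in rng.integers(20, size=lb))
        from pheroscan.compare import align_global
        import biotite.sequence.align as balign
        alignment = align_global(a, b)
        max_score, identities = oracle_alignments(a, b)
        assert alignment.score / 2 == pytest.approx(max_score)
        got = 100.0 * balign.get_sequence_identity(alignment, mode="all")
        assert any(got == pytest.approx(x) for x in identities)


class TestIdentityMatrix:
    def test_symmetric_with_diagonal_100(self):
        rng = np.random.default_rng(0)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        records = [SequenceRecord(id=f"p{i}",
                                  seq="".join(alphabet[k] for k in
                                              rng.integers(20, size=10)),
                                  alphabet="protein") for i in range(5)]
        matrix = pairwise_identity(records)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 100.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity([SequenceRecord(id="p", seq="MK",
                                              alphabet="protein")])


class TestUniquePeptides:
    def test_census(self):
        census, n = unique_peptides(["WGQEPGQP", "WGQEPGQP", "WGQAPGQP"])
        assert n == 2
        assert census == {"WGQAPGQP": 1, "WGQEPGQP": 2}
        assert list(census) == sorted(census)

    def test_empty(self):
        assert unique_peptides([]) == ({}, 0)


class TestStrategySummary:
    def test_same_strategy_mean(self):
        features = pd.DataFrame({"species": ["s1", "s2"],
                                 "n_peptides": [2, 4]})
        strategies = {"s1": "heterothallic", "s2": "heterothallic"}
        summary = summarize_by_strategy(features, strategies)
        assert summary.loc["heterothallic", ("n_peptides", "mean")] == 3.0

    def test_single_species_echoed(self):
        features = pd.DataFrame({"species": ["s1"], "n_peptides": [5]})
        summary = summarize_by_strategy(features, {"s1": "unisexual"})
        cell = summary.loc["unisexual", "n_peptides"]
        assert cell["min"] == cell["max"] == cell["mean"] == 5

    def test_unknown_species_rejected(self):
        features = pd.DataFrame({"species": ["s1"], "n_peptides": [5]})
        with pytest.raises(ValueError, match="s1"):
            summarize_by_strategy(features, {"other": "unisexual"})

    def test_strategy_table_reader_validates(self, tmp_path):
        path = tmp_path / "strategies.tsv"
        path.write_text("s1\theterothallic\ns2\tselfing\n")
        with pytest.raises(ValueError, match="selfing"):
            read_strategy_table(path)


class TestPermutationTest:
    def _labels(self, n_per=6):
        return [s for s in MATING_STRATEGIES for _ in range(n_per)]

    def test_constant_feature_gives_p_one(self):
        labels = self._labels()
        p, obs = permutation_association([1.0] * len(labels), labels, 99, 0)
        assert p == 1.0 and obs == pytest.approx(0.0)

    def test_large_effect_detected(self):
        rng = np.random.default_rng(42)
        labels = self._labels(12)
        feature = [rng.normal(5.0 * MATING_STRATEGIES.index(l), 1.0)
                   for l in labels]
        p, _ = permutation_association(feature, labels, 999, 42)
        assert p <= 0.05

    def test_same_seed_is_bit_identical(self):
        rng = np.random.default_rng(1)
        labels = self._labels()
        feature = list(rng.normal(size=len(labels)))
        r1 = permutation_association(feature, labels, 199, 7)
        r2 = permutation_association(feature, labels, 199, 7)
        assert r1 == r2

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            permutation_association([1, 2, 3], ["a", "a", "b"], 99, 0)
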