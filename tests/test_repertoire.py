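"""Entropy, mutual information, clustering and subset statistics."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vhhkit as vk
from vhhkit.errors import DegenerateMatrix, EmptySubset, InvalidDistribution, UnknownMotif
from vhhkit.repertoire import ALPHABET, LOG2_21, AlignmentMatrix, entropy_profile


def matrix_from_columns(*cols):
    """Build a small AlignmentMatrix from explicit column strings."""
    n = len(cols[0])
    data = np.array([[col[i] for col in cols] for i in range(n)], dtype="U1")
    return AlignmentMatrix([f"s{i}" for i in range(n)], tuple(range(1, len(cols) + 1)), data)


def brute_force_mi(colx, coly):
    """Independent oracle: MI in bits from explicit joint counts."""
    n = len(colx)
    joint = Counter(zip(colx, coly))
    px = Counter(colx)
    py = Counter(coly)
    mi = 0.0
    for (x, y), c in joint.items():
        p = c / n
        mi += p * math.log2(p / ((px[x] / n) * (py[y] / n)))
    return mi


def brute_force_entropy(col):
    n = len(col)
    return -sum((c / n) * math.log2(c / n) for c in Counter(col).values())


class TestEntropy:
    def test_constant_column_has_zero_entropy(self):
        assert vk.shannon_entropy([1.0] + [0.0] * 20) == 0.0
        assert vk.normalized_entropy([1.0] + [0.0] * 20) == 0.0

    def test_uniform_21_has_normalized_entropy_one(self):
        p = [1 / 21] * 21
        assert vk.shannon_entropy(p) == pytest.approx(LOG2_21, abs=1e-12)
        assert vk.normalized_entropy(p) == pytest.approx(1.0, abs=1e-12)

    def test_fair_coin_is_one_bit(self):
        assert vk.shannon_entropy([0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)
        assert vk.normalized_entropy([0.5, 0.5]) == pytest.approx(1 / LOG2_21, abs=1e-12)

    def test_invalid_distribution_raises(self):
        with pytest.raises(InvalidDistribution):
            vk.shannon_entropy([0.5, 0.6])

    def test_profile_bounds_and_constant_iff_zero(self, repertoire):
        seqs, _ = repertoire
        m = vk.build_alignment(seqs[:500])
        prof = entropy_profile(m)
        assert ((prof.NH >= 0) & (prof.NH <= 1)).all()
        for pos in m.columns:
            constant = len(set(m.column(pos))) == 1
            assert (prof.loc[pos, "NH"] == 0) == constant


class TestColumnProbabilities:
    def test_examples(self):
        m = matrix_from_columns("AAAA", "AACC", "AAA-")
        probs = vk.column_probabilities(m)
        assert probs.loc["A", 1] == 1.0
        assert probs.loc["A", 2] == probs.loc["C", 2] == 0.5
        assert probs.loc["A", 3] == 0.75 and probs.loc["-", 3] == 0.25
        assert np.allclose(probs.sum(axis=0), 1.0)


class TestMutualInformation:
    def test_identical_partitions_share_one_bit(self):
        m = matrix_from_columns("AAGG", "CCDD")
        assert vk.mutual_information(m, 1, 2) == pytest.approx(1.0, abs=1e-12)
        assert vk.nmi(m, 1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_independent_partitions_share_nothing(self):
        m = matrix_from_columns("AAGG", "CDCD")
        assert vk.mutual_information(m, 1, 2) == pytest.approx(0.0, abs=1e-12)

    def test_known_joint_value(self):
        m = matrix_from_columns("AAAG", "CCDD")
        expected = brute_force_mi("AAAG", "CCDD")
        assert expected == pytest.approx(0.31127812, abs=1e-6)
        assert vk.mutual_information(m, 1, 2) == pytest.approx(expected, abs=1e-12)
        hx, hy = brute_force_entropy("AAAG"), brute_force_entropy("CCDD")
        assert vk.nmi(m, 1, 2) == pytest.approx(2 * expected / (hx + hy), abs=1e-12)
        assert vk.nmi(m, 1, 2) == pytest.approx(0.3437110, abs=1e-6)

    def test_constant_columns_have_nmi_zero_by_convention(self):
        m = matrix_from_columns("AAAA", "GGGG")
        assert vk.nmi(m, 1, 2) == 0.0

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(2, 6).flatmap(
            lambda n: st.lists(
                st.lists(st.sampled_from("ACDG-"), min_size=n, max_size=n).map("".join),
                min_size=2,
                max_size=6,
            )
        )
    )
    def test_oracle_equivalence_on_small_alignments(self, cols):
        m = matrix_from_columns(*cols)
        for i in range(len(cols)):
            for j in range(len(cols)):
                x, y = m.columns[i], m.columns[j]
                mi = vk.mutual_information(m, x, y)
                assert mi == pytest.approx(brute_force_mi(cols[i], cols[j]), abs=1e-12)
                hx, hy = brute_force_entropy(cols[i]), brute_force_entropy(cols[j])
                expected_nmi = 0.0 if hx + hy == 0 else 2 * mi / (hx + hy)
                assert vk.nmi(m, x, y) == pytest.approx(expected_nmi, abs=1e-12)
                assert mi <= min(hx, hy) + 1e-9

    def test_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        cols = ["AACGGD", "ACCGDD", "AAAAG-"]
        m = matrix_from_columns(*cols)
        for i in range(3):
            for j in range(3):
                ours = vk.mutual_information(m, i + 1, j + 1)
                theirs = sklearn_metrics.mutual_info_score(list(cols[i]), list(cols[j]))
                assert ours == pytest.approx(theirs / math.log(2), abs=1e-12)

    def test_independent_random_columns_have_only_plug_in_bias(self):
        # plug-in MI bias for independent k-symbol columns is about
        # (k-1)^2/(2 N ln 2) bits, i.e. NMI ~ 0.066 at N=1000 for k=21,
        # shrinking ~1/N; the estimator must not exceed that bias level
        rng = np.random.default_rng(5)
        for n, bound in ((1000, 0.08), (4000, 0.025)):
            cols = ["".join(rng.choice(list(ALPHABET), size=n)) for _ in range(6)]
            m = matrix_from_columns(*cols)
            assert vk.nmi_matrix(m).mean_offdiagonal() < bound


class TestNMIMatrix:
    def test_symmetry_range_and_diagonal(self, repertoire):
        seqs, _ = repertoire
        m = vk.build_alignment(seqs[:300])
        nm = vk.nmi_matrix(m)
        assert np.allclose(nm.values, nm.values.T, atol=1e-12)
        assert (nm.values >= 0).all() and (nm.values <= 1 + 1e-9).all()
        for k, pos in enumerate(nm.positions):
            expected = 1.0 if nm.entropies[k] > 0 else 0.0
            assert nm.values[k, k] == expected


class TestClustering:
    def block_matrix(self):
        vals = np.full((4, 4), 0.0)
        vals[:2, :2] = 0.9
        vals[2:, 2:] = 0.9
        np.fill_diagonal(vals, 1.0)
        return vk.NMIMatrix((1, 2, 3, 4), vals, vals.copy(), np.ones(4))

    def test_two_blocks_give_two_clusters_at_cutoff(self):
        # hand linkage: within-block merges at height 0.1; the cross merge
        # follows the Ward recurrence d(ab,cd)^2 = ((2+2)*d(ab,c)^2*... > 1.1
        ca = vk.cluster_positions(self.block_matrix(), cutoff=1.1)
        assert ca.n_clusters == 2
        assert ca.cluster_of(1) == ca.cluster_of(2) != ca.cluster_of(3) == ca.cluster_of(4)

    def test_cutoff_limits(self):
        nm = self.block_matrix()
        assert vk.cluster_positions(nm, cutoff=1e-9).n_clusters == 4
        assert vk.cluster_positions(nm, cutoff=100.0).n_clusters == 1

    def test_permutation_equivariance(self):
        nm = self.block_matrix()
        perm = [2, 0, 3, 1]
        vals = nm.values[np.ix_(perm, perm)]
        nm_p = vk.NMIMatrix(tuple(nm.positions[i] for i in perm), vals, vals.copy(), np.ones(4))
        ca, ca_p = vk.cluster_positions(nm), vk.cluster_positions(nm_p)
        for pos in nm.positions:
            for other in nm.positions:
                assert (ca.cluster_of(pos) == ca.cluster_of(other)) == (
                    ca_p.cluster_of(pos) == ca_p.cluster_of(other)
                )

    def test_single_column_is_degenerate(self):
        nm = vk.NMIMatrix((1,), np.ones((1, 1)), np.ones((1, 1)), np.ones(1))
        with pytest.raises(DegenerateMatrix):
            vk.cluster_positions(nm)


class TestSubsets:
    def test_motif_fraction(self, repertoire):
        seqs, truth = repertoire
        members, fraction = vk.subset_filter(seqs, vk.SubsetSpec("hallmark_motif", "FERG"))
        expected = (truth.records.motif == "FERG").mean()
        assert fraction == pytest.approx(expected, abs=1e-12)
        assert all(vk.hallmark_motif(s) == "FERG" for s in members)

    def test_cys_subset_matches_truth(self, repertoire):
        seqs, truth = repertoire
        members, fraction = vk.subset_filter(seqs, vk.SubsetSpec("noncanonical_cys"))
        assert fraction == pytest.approx(truth.cys_fraction, abs=1e-12)

    def test_motif_subsets_are_disjoint(self, repertoire):
        seqs, _ = repertoire
        seen = set()
        for motif in ("FERG", "VGLW", "YQRL", "FERF"):
            members, _ = vk.subset_filter(seqs, vk.SubsetSpec("hallmark_motif", motif))
            ids = {s.id for s in members}
            assert not ids & seen
            seen |= ids

    def test_bad_motif_rejected(self):
        with pytest.raises(UnknownMotif):
            vk.SubsetSpec("hallmark_motif", "FE1G")


class TestLogosAndDivergence:
    def test_subset_equal_to_all_flags_nothing(self, repertoire):
        seqs, _ = repertoire
        m = vk.build_alignment(seqs[:200])
        assert vk.divergent_positions(m, m) == []

    def test_vglw_subset_diverges_at_position_40(self, repertoire):
        seqs, _ = repertoire
        all_m = vk.build_alignment(seqs)
        members, _ = vk.subset_filter(seqs, vk.SubsetSpec("hallmark_motif", "VGLW"))
        sub_m = vk.build_alignment(members)
        assert 40 in vk.divergent_positions(sub_m, all_m)

    def test_logo_matrix_rows_sum_to_one(self, repertoire):
        seqs, _ = repertoire
        logo = vk.frequency_logo_matrix(vk.build_alignment(seqs[:100]))
        assert np.allclose(logo.sum(axis=1), 1.0)


class TestCdr3Stats:
    def test_mean_of_two(self, ferg, db):
        short = vk.NumberedSequence(
            "short", [r for r in ferg.residues if not (108 <= r.position <= 110)]
        )
        mean, sd, hist = vk.cdr3_length_stats([ferg, short])
        assert mean == 11.5 and hist == {13: 1, 10: 1}

    def test_single_member_sd_zero(self, ferg):
        mean, sd, _ = vk.cdr3_length_stats([ferg])
        assert sd == 0.0

    def test_empty_subset_raises(self):
        with pytest.raises(EmptySubset):
            vk.cdr3_length_stats([])

    def test_ferg_subset_mean_within_3se_of_truth(self, repertoire):
        seqs, truth = repertoire
        mean, sd, _ = vk.cdr3_length_stats(seqs, vk.SubsetSpec("hallmark_motif", "FERG"))
        sub = truth.records[truth.records.motif == "FERG"]
        se = sub.cdr3_length.std() / np.sqrt(len(sub))
        assert abs(mean - 18.4) < 3 * se + 1e-9


def test_mixed_cdr3_lengths_share_column_count(repertoire):
    seqs, _ = repertoire
    m = vk.build_alignment(seqs[:50])
    assert m.data.shape == (50, 128)
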