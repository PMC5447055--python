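import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from sklearn.metrics import normalized_mutual_info_score, silhouette_score

from cbparc.io import LabelVolume
from cbparc.parcellate import Parcellation
from cbparc.validity import (
    ContactMatrix,
    FrequencyTable,
    ValidityReport,
    contact_matrix,
    continuity_index,
    cramers_v,
    dice,
    hierarchy_index,
    information_summary,
    leave_one_out,
    nmi,
    overlap_table,
    pairwise,
    silhouette,
    split_half,
    stability_profile,
    suggest_k,
    topological_distance,
    validity_report,
    vi,
)


def table(rows) -> FrequencyTable:
    t = np.asarray(rows, dtype=np.int64)
    return FrequencyTable(t, np.arange(1, t.shape[0] + 1),
                          np.arange(1, t.shape[1] + 1))


def vol_parcellation(labels_3d):
    return Parcellation.from_volume(
        LabelVolume(np.asarray(labels_3d, dtype=np.int32)))


def random_labelings(seed, n=40, kmax=4):
    rng = np.random.default_rng(seed)
    ka = int(rng.integers(2, kmax + 1))
    kb = int(rng.integers(2, kmax + 1))
    a = rng.integers(1, ka + 1, size=n)
    b = rng.integers(1, kb + 1, size=n)
    a[:ka] = np.arange(1, ka + 1)
    b[:kb] = np.arange(1, kb + 1)
    return a, b


class TestOverlapTable:
    def test_self_overlap_is_diagonal(self):
        a = np.array([1] * 6 + [2] * 4)
        t = overlap_table(a, a)
        np.testing.assert_array_equal(t.t, np.diag([6, 4]))

    def test_disjoint_supports_rejected(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="common"):
            overlap_table(a, b)

    def test_matches_hand_count(self, rng):
        a = rng.integers(0, 4, size=50)
        b = rng.integers(0, 3, size=50)
        a[:6] = [1, 2, 3, 1, 2, 3]
        b[:6] = [1, 2, 1, 2, 1, 2]
        t = overlap_table(a, b)
        for i, la in enumerate(t.a_labels):
            for j, lb in enumerate(t.b_labels):
                expected = sum(
                    1 for x, y in zip(a, b) if x == la and y == lb and x and y
                )
                assert t.t[i, j] == expected
        assert t.n_total == int(((a > 0) & (b > 0)).sum())


class TestCramersV:
    def test_identical_is_one(self):
        assert cramers_v(table(np.diag([6, 4, 5]))) == pytest.approx(1.0)

    def test_independent_is_zero(self):
        assert cramers_v(table([[4, 4], [4, 4]])) == pytest.approx(0.0)

    def test_hand_value(self):
        # chi2 of [[8,2],[2,8]]: expected all 5 -> chi2 = 4*(9/5) = 7.2
        # V = sqrt(7.2 / (20 * 1)) = 0.6
        assert cramers_v(table([[8, 2], [2, 8]])) == pytest.approx(0.6)

    def test_single_cluster_both_is_one(self):
        assert cramers_v(table([[7]])) == 1.0

    def test_single_vs_multi_rejected(self):
        with pytest.raises(ValueError, match="single"):
            cramers_v(table([[3, 4]]))

    @pytest.mark.parametrize("seed", range(20))
    def test_against_scipy_chi2(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 12, size=(int(rng.integers(2, 5)),
                                      int(rng.integers(2, 5))))
        chi2 = chi2_contingency(t, correction=False).statistic
        expected = math.sqrt(
            chi2 / (t.sum() * (min(t.shape) - 1)))
        assert cramers_v(table(t)) == pytest.approx(expected, abs=1e-12)


class TestDice:
    def test_identical_is_one(self, rng):
        a = rng.integers(1, 4, size=30)
        a[:3] = [1, 2, 3]
        assert dice(a, a) == pytest.approx(1.0)

    def test_disjoint_correspondence_is_zero(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([2, 2, 1, 1])
        assert dice(a, b) == pytest.approx(0.0)

    def test_hand_enumeration(self):
        a = np.array([1] * 6 + [2] * 4)
        b = np.array([1] * 5 + [2] * 5)
        # cluster 1: 2*5/(6+5); cluster 2: 2*4/(4+5)
        assert dice(a, b) == pytest.approx(0.5 * (10 / 11 + 8 / 9))

    def test_empty_cluster_conventions(self):
        a = np.array([1, 1, 3, 3])  # cluster 2 empty in both
        b = np.array([1, 1, 3, 3])
        assert dice(a, b, k=3) == pytest.approx(1.0)
        c = np.array([1, 2, 3, 3])  # cluster 2 empty in a only -> 0 term
        # cluster 1: 2*1/(2+1); cluster 2: 0; cluster 3: 2*2/(2+2)
        assert dice(a, c, k=3) == pytest.approx((2 / 3 + 0 + 1) / 3)


class TestInformationIndices:
    def test_diagonal_table_mi_equals_entropy(self):
        s = information_summary(table(np.diag([3, 5, 2])))
        assert s.mi == pytest.approx(s.h_a)
        assert s.h_a == pytest.approx(s.h_b)

    def test_independent_table_zero_mi(self):
        s = information_summary(table([[4, 4], [4, 4]]))
        assert s.mi == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula(self):
        t = np.array([[3, 1], [1, 3]], dtype=float)
        n = t.sum()
        p = t / n
        pa, pb = p.sum(1), p.sum(0)
        mi = sum(
            p[i, j] * math.log(p[i, j] / (pa[i] * pb[j]))
            for i in range(2) for j in range(2) if p[i, j] > 0
        )
        s = information_summary(table(t.astype(int)))
        assert s.mi == pytest.approx(mi, abs=1e-12)
        assert s.h_a == pytest.approx(-sum(q * math.log(q) for q in pa))

    def test_nmi_identical_one_independent_zero(self):
        assert nmi(table(np.diag([4, 2, 6]))) == pytest.approx(1.0)
        assert nmi(table([[4, 4], [4, 4]])) == pytest.approx(0.0, abs=1e-12)

    def test_nmi_both_single_cluster_convention(self):
        assert nmi(table([[9]])) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_nmi_against_sklearn(self, seed):
        a, b = random_labelings(seed)
        got = nmi(overlap_table(a, b))
        expected = normalized_mutual_info_score(a, b,
                                                average_method="arithmetic")
        assert got == pytest.approx(expected, abs=1e-10)

    def test_vi_identical_zero(self):
        assert vi(table(np.diag([5, 5]))) == pytest.approx(0.0, abs=1e-12)

    def test_vi_independent_equal_margins(self):
        # equal-margin independent 2x2: H(A)=H(B)=ln2, I=0 -> VI = 2 ln 2
        assert vi(table([[4, 4], [4, 4]])) == pytest.approx(2 * math.log(2))

    @pytest.mark.parametrize("seed", range(20))
    def test_vi_nmi_identity(self, seed):
        """VI = (H_A + H_B)(1 - NMI), an algebraic identity."""
        a, b = random_labelings(seed)
        t = overlap_table(a, b)
        s = information_summary(t)
        assert vi(t) == pytest.approx(
            (s.h_a + s.h_b) * (1 - nmi(t)), abs=1e-12)


class TestSilhouette:
    def test_perfectly_separated_clusters(self):
        x = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        out = silhouette(x, np.array([1, 1, 2, 2]))
        assert out.mean == pytest.approx(1.0)

    def test_singleton_cluster_zero(self):
        x = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0]])
        out = silhouette(x, np.array([1, 1, 2]))
        assert out.s[2] == 0.0

    def test_four_row_toy_matches_direct_formula(self):
        x = np.array([[1.0, 0.0, 0.0],
                      [0.8, 0.2, 0.0],
                      [0.0, 1.0, 0.5],
                      [0.1, 0.9, 0.4]])
        labels = np.array([1, 1, 2, 2])

        def cos_d(u, v):
            return 1 - (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))

        out = silhouette(x, labels)
        for i in range(4):
            own = [j for j in range(4) if labels[j] == labels[i] and j != i]
            other = [j for j in range(4) if labels[j] != labels[i]]
            a = np.mean([cos_d(x[i], x[j]) for j in own])
            b = np.mean([cos_d(x[i], x[j]) for j in other])
            assert out.s[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 1.0, size=(20, 6))
        labels = rng.integers(1, 4, size=20)
        labels[:6] = [1, 1, 2, 2, 3, 3]  # no singletons
        got = silhouette(x, labels).mean
        expected = silhouette_score(x, labels, metric="cosine")
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.ones((3, 2)), np.array([1, 1, 1]))


class TestContinuity:
    def test_connected_slabs_are_one(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[:2] = 1
        labels[2:4] = 2
        labels[4:] = 3
        for conn in (6, 18, 26):
            assert continuity_index(labels, conn) == pytest.approx(1.0)

    def test_split_cluster_contributes_half(self):
        labels = np.zeros((6, 3, 3), dtype=np.int32)
        labels[0, :, :2] = 1  # 6 voxels
        labels[2, :, :2] = 1  # disconnected 6 more -> 5+5 style split
        labels[4:, :, :] = 2  # intact
        got = continuity_index(labels, 6)
        assert got == pytest.approx((0.5 + 1.0) / 2)

    def test_wider_connectivity_never_lower(self, rng):
        labels = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int32)
        labels[0, 0, 0] = 1
        c6 = continuity_index(labels, 6)
        c18 = continuity_index(labels, 18)
        c26 = continuity_index(labels, 26)
        assert c6 <= c18 <= c26


class TestHierarchyIndex:
    def test_strict_refinement_is_one(self):
        parent = np.array([1] * 6 + [2] * 6)
        child = np.array([1] * 3 + [3] * 3 + [2] * 6)
        assert hierarchy_index(child, parent) == pytest.approx(1.0)

    def test_split_parentage(self):
        # k=3 where one cluster draws equally from two parents
        parent = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        child = np.array([1, 1, 2, 2, 3, 3, 1, 1])
        # child 1: 2 from parent1 + 2 from parent2 -> 0.5; children 2,3 pure
        assert hierarchy_index(child, parent) == pytest.approx(
            (0.5 + 1 + 1) / 3)

    def test_label_permutation_invariant(self, rng):
        a, b = random_labelings(7)
        relabel_a = np.array([0, 3, 1, 2, 4])[a]
        relabel_b = np.array([0, 2, 1, 4, 3])[b]
        assert hierarchy_index(a, b) == pytest.approx(
            hierarchy_index(relabel_a, relabel_b))


class TestContactMatrixAndTpD:
    def test_touching_slabs(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0] = 1
        labels[1] = 2
        cm = contact_matrix(labels)
        # every voxel of each slab touches the other slab
        np.testing.assert_array_equal(cm.raw, [[0, 4], [4, 0]])
        np.testing.assert_array_equal(cm.normalized, [[0, 1], [1, 0]])

    def test_isolated_cluster_zero_row(self):
        labels = np.zeros((7, 3, 3), dtype=np.int32)
        labels[0] = 1
        labels[3] = 2  # separated by background from both
        labels[6] = 3
        cm = contact_matrix(labels)
        assert (cm.raw[1] == 0).all()
        assert (cm.normalized[1] == 0).all()

    def test_translation_invariant(self, rng):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[1:4, 1:4, 1:4] = rng.integers(1, 4, size=(3, 3, 3))
        shifted = np.roll(labels, (2, 1, 3), axis=(0, 1, 2))
        np.testing.assert_array_equal(contact_matrix(labels).raw,
                                      contact_matrix(shifted, k=3).raw)

    def test_tpd_identical_zero(self):
        labels = np.zeros((4, 2, 2), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        assert topological_distance(labels, labels) == pytest.approx(0.0)

    def test_tpd_orthogonal_patterns_one(self):
        a = ContactMatrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        b = ContactMatrix(np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0]]))
        # row-normalized vectors share no nonzero position except row2/row0
        assert topological_distance(a, b) == pytest.approx(
            1 - (a.normalized.ravel() @ b.normalized.ravel())
            / (np.linalg.norm(a.normalized) * np.linalg.norm(b.normalized)))

    def test_tpd_empty_contact_convention(self):
        a = ContactMatrix(np.zeros((2, 2), dtype=int))
        b = ContactMatrix(np.array([[0, 1], [1, 0]]))
        assert topological_distance(a, b) == 1.0


def identical_subject_parcellations(n=6):
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[:2, :2] = 1
    labels[:2, 2:] = 2
    labels[2:] = 3
    return [vol_parcellation(labels) for _ in range(n)]


class TestResamplingDrivers:
    def test_identical_subjects_perfect_indices(self):
        parcs = identical_subject_parcellations()
        for scheme, kwargs in [(split_half, dict(n_reps=5, seed=0)),
                               (pairwise, {}), (leave_one_out, {})]:
            values = scheme(parcs, **kwargs)
            np.testing.assert_allclose(values["cv"], 1.0)
            np.testing.assert_allclose(values["dice"], 1.0)
            np.testing.assert_allclose(values["nmi"], 1.0)
            np.testing.assert_allclose(values["vi"], 0.0, atol=1e-12)

    def test_replicate_counts(self, small_cohort):
        parcs = [
            Parcellation(small_cohort.seed_set,
                         small_cohort.truth_labels[s],
                         small_cohort.spec.k_true)
            for s in range(small_cohort.n_subjects)
        ]
        n = len(parcs)
        assert len(split_half(parcs, n_reps=7, seed=1)["dice"]) == 7
        assert len(pairwise(parcs)["dice"]) == n * (n - 1) // 2
        assert len(leave_one_out(parcs)["dice"]) == n

    def test_two_subject_pairwise_is_direct_comparison(self):
        a = np.zeros((3, 3, 3), dtype=np.int32)
        a[:2] = 1
        a[2:] = 2
        b = a.copy()
        b[1] = 2
        pa, pb = vol_parcellation(a), vol_parcellation(b)
        values = pairwise([pa, pb])
        t = overlap_table(a, b)
        assert values["cv"][0] == pytest.approx(cramers_v(t))
        assert values["dice"][0] == pytest.approx(dice(a, b))
        assert values["nmi"][0] == pytest.approx(nmi(t))
        assert values["vi"][0] == pytest.approx(vi(t))

    def test_too_few_subjects(self):
        parcs = identical_subject_parcellations(2)
        with pytest.raises(ValueError):
            split_half(parcs)
        with pytest.raises(ValueError):
            leave_one_out(parcs)


class TestStabilityRule:
    def test_flat_series_no_flags(self):
        flags, _ = stability_profile([2, 3, 4, 5], [0.3, 0.3, 0.3, 0.3])
        assert flags == []

    def test_jump_flagged(self):
        flags, dvi = stability_profile([2, 3, 4, 5], [0.1, 0.1, 0.12, 0.5])
        assert flags == [4]
        np.testing.assert_allclose(dvi, [0.0, 0.02, 0.38])

    def test_shift_invariant(self):
        base = np.array([0.2, 0.25, 0.27, 0.8, 0.82])
        f1, _ = stability_profile(list(range(2, 7)), base)
        f2, _ = stability_profile(list(range(2, 7)), base + 5.0)
        assert f1 == f2

    def test_short_range_rejected(self):
        with pytest.raises(ValueError):
            stability_profile([2, 3], [0.1, 0.2])


def report_from_curves(curves: dict[str, list[float]], ks: list[int]
                       ) -> ValidityReport:
    rows = [
        dict(index=name, k=k, scheme="split_half", mean=v, sd=0.0, n=10)
        for name, values in curves.items()
        for k, v in zip(ks, values)
    ]
    return ValidityReport(pd.DataFrame(rows))


class TestSuggestK:
    def test_unanimous_peak(self):
        ks = [2, 3, 4, 5, 6]
        curve = [0.5, 0.7, 0.9, 0.6, 0.5]
        report = report_from_curves(
            {"cv": curve, "dice": curve, "nmi": curve}, ks)
        out = suggest_k(report)
        assert out.k == 4
        assert out.votes["cv"] == [4]

    def test_mode_wins(self):
        ks = [2, 3, 4, 5, 6, 7]
        peak4 = [0.1, 0.2, 0.9, 0.3, 0.2, 0.1]
        peak6 = [0.1, 0.2, 0.3, 0.2, 0.9, 0.1]
        report = report_from_curves(
            {"cv": peak4, "dice": peak4, "nmi": peak6}, ks)
        assert suggest_k(report).k == 4

    def test_tie_takes_smallest(self):
        ks = [2, 3, 4, 5, 6, 7]
        peak4 = [0.1, 0.2, 0.9, 0.3, 0.2, 0.1]
        peak6 = [0.1, 0.2, 0.3, 0.2, 0.9, 0.1]
        report = report_from_curves({"cv": peak4, "dice": peak6}, ks)
        assert suggest_k(report).k == 4


class TestPermutationInvariance:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_cv_nmi_vi_invariant_dice_not(self, seed):
        a, b = random_labelings(seed, n=30, kmax=3)
        ka, kb = a.max(), b.max()
        rng = np.random.default_rng(seed + 1)
        pa = np.concatenate([[0], rng.permutation(ka) + 1])
        pb = np.concatenate([[0], rng.permutation(kb) + 1])
        t1 = overlap_table(a, b)
        t2 = overlap_table(pa[a], pb[b])
        assert cramers_v(t1) == pytest.approx(cramers_v(t2), abs=1e-12)
        assert nmi(t1) == pytest.approx(nmi(t2), abs=1e-12)
        assert vi(t1) == pytest.approx(vi(t2), abs=1e-12)

    def test_dice_is_label_sensitive(self):
        a = np.array([1, 1, 1, 2])
        b = np.array([1, 1, 2, 2])
        swapped = np.array([0, 2, 1])[b]
        assert dice(a, b) != pytest.approx(dice(a, swapped))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_index_ranges(self, seed):
        a, b = random_labelings(seed, n=25, kmax=4)
        t = overlap_table(a, b)
        assert 0.0 <= cramers_v(t) <= 1.0
        assert 0.0 <= nmi(t) <= 1.0
        assert vi(t) >= 0.0
        assert 0.0 <= dice(a, b, k=int(max(a.max(), b.max()))) <= 1.0


class TestValidityReport:
    def test_report_structure_and_suggestion(self, small_cohort):
        k_true = small_cohort.spec.k_true
        canonical = small_cohort.canonical_labels
        rng = np.random.default_rng(5)
        relabeled_by_k = {}
        for k in range(2, 6):
            parcs = []
            for s in range(small_cohort.n_subjects):
                if k == k_true:
                    labels = canonical
                else:
                    # independent random labelings are irreproducible
                    labels = rng.integers(1, k + 1,
                                          size=len(canonical))
                    labels[:k] = np.arange(1, k + 1)
                parcs.append(Parcellation(small_cohort.seed_set, labels, k))
            relabeled_by_k[k] = parcs
        report = validity_report(relabeled_by_k, n_reps=5, seed=2)
        assert set(report.table["index"]) >= {"cv", "dice", "nmi", "vi",
                                              "continuity_26", "hi"}
        out = suggest_k(report)
        assert out.k == k_true
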