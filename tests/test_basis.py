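import dataclasses

import numpy as np
import pandas as pd
import pytest

from capdyn.basis import (BasisCapSet, basis_similarity, build_basis_set,
                          exhaustive_match, label_basis_set, match_caps,
                          matched_metrics_table, occurrence_stats)
from capdyn.cap_estimation import (CapSet, KScanResult, PermutationLedger,
                                   PermutationRecord, SplitResult)


def _zpat(rng, k, p):
    X = rng.standard_normal((k, p))
    return (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)


def _basis(patterns, labels=None):
    k = patterns.shape[0]
    return BasisCapSet(patterns=patterns,
                       labels=labels or [f"BC{i+1}" for i in range(k)],
                       k=k, n_contributing_permutations=1,
                       cluster_sizes=np.ones(k, dtype=int))


def _fake_ledger(centroid_sets, subject_sets=None, k_hats=None, metrics=None):
    """Assemble a PermutationLedger from raw centroid arrays (one per split)."""
    records = []
    for p, per_perm in enumerate(centroid_sets):
        splits = []
        for s, cents in enumerate(per_perm):
            k = cents.shape[0]
            capset = CapSet(centroids=cents, k=k, provenance=(p, s, 0),
                            inertia=0.0, frame_counts=np.ones(k, dtype=int))
            scan = KScanResult(capsets={k: capset}, silhouettes={k: 0.5}, k_hat=k)
            m = (metrics[p][s] if metrics is not None
                 else pd.DataFrame({"subject_id": [], "day": [], "state": [],
                                    "fo": [], "mean_dt": [], "var_dt": [],
                                    "n_segments": [], "permutation": [],
                                    "split": [], "k_hat": []}))
            sids = subject_sets[p][s] if subject_sets else [f"x{p}{s}"]
            splits.append(SplitResult(subject_ids=sids, scan=scan, metrics=m))
        records.append(PermutationRecord(p, splits))
    return PermutationLedger(records=records, k_range=(2, 8), base_seed=0)


class TestBuildBasisSet:
    def test_identical_centroids_aggregate_to_their_zscores(self, rng):
        pats = rng.standard_normal((3, 20))
        ledger = _fake_ledger([[pats.copy(), pats.copy()] for _ in range(4)])
        basis = build_basis_set(ledger, 3)
        want = (pats - pats.mean(1, keepdims=True)) / pats.std(1, keepdims=True)
        for w in want:
            best = max(abs(np.corrcoef(b, w)[0, 1]) for b in basis.patterns)
            assert best > 1 - 1e-12
        assert basis.n_contributing_permutations == 4
        assert basis.cluster_sizes.sum() == 8 * 3

    def test_noisy_copies_of_planted_patterns_recovered(self, rng):
        planted = 3.0 * _zpat(rng, 4, 40)
        sets = []
        for _ in range(10):
            per = [planted + 0.1 * rng.standard_normal(planted.shape)
                   for _ in range(2)]
            sets.append(per)
        basis = build_basis_set(_fake_ledger(sets), 4)
        for pat in planted:
            best = max(np.corrcoef(b, pat)[0, 1] for b in basis.patterns)
            assert best >= 0.99

    def test_patterns_are_zscored_across_parcels(self, rng):
        sets = [[rng.standard_normal((3, 30)) for _ in range(2)] for _ in range(3)]
        basis = build_basis_set(_fake_ledger(sets), 3)
        assert np.abs(basis.patterns.mean(1)).max() < 1e-8
        assert np.abs(basis.patterns.std(1) - 1).max() < 1e-8

    def test_shuffling_ledger_order_gives_same_patterns(self, rng):
        planted = 2.0 * _zpat(rng, 3, 25)
        sets = [[planted + 0.05 * rng.standard_normal(planted.shape)
                 for _ in range(2)] for _ in range(6)]
        a = build_basis_set(_fake_ledger(sets), 3)
        b = build_basis_set(_fake_ledger(sets[::-1]), 3)
        # identical up to row permutation
        R = np.abs(np.corrcoef(a.patterns, b.patterns)[:3, 3:])
        assert np.allclose(R.max(axis=1), 1.0, atol=1e-9)

    def test_fewer_than_two_qualifying_permutations_rejected(self, rng):
        ledger = _fake_ledger([[rng.standard_normal((3, 10))]])
        with pytest.raises(ValueError, match="need >= 2"):
            build_basis_set(ledger, 3)


class TestMatchCaps:
    def test_identity_matching(self, rng):
        pats = _zpat(rng, 4, 30)
        labeling, R, best_r = match_caps(pats, _basis(pats))
        assert labeling == {i: i for i in range(4)}
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(best_r, 1.0)

    def test_sign_flipped_pattern_matches_its_anticorrelated_partner(self, rng):
        base = _zpat(rng, 1, 30)[0]
        basis = _basis(np.vstack([base, -base]), labels=["I+", "I-"])
        est = np.vstack([-base])  # estimated CAP is the sign-flip of basis[0]
        labeling, R, _ = match_caps(est, basis)
        assert labeling == {0: 1}
        assert R[0, 0] == pytest.approx(-1.0)
        assert R[0, 1] == pytest.approx(1.0)

    def test_unmatched_basis_pattern_is_the_planted_extra(self, rng):
        pats = _zpat(rng, 5, 40)
        basis = _basis(pats, labels=["I+", "I-", "II+", "II-", "III"])
        est = pats[:4] + 0.05 * rng.standard_normal((4, 40))
        labeling, _, _ = match_caps(est, basis)
        assert set(labeling.values()) == {0, 1, 2, 3}  # index 4 (III) unmatched

    def test_more_estimated_than_basis_rejected(self, rng):
        with pytest.raises(ValueError):
            match_caps(_zpat(rng, 5, 20), _basis(_zpat(rng, 4, 20)))

    def test_greedy_agrees_with_exhaustive_on_random_noisy_instances(self, rng):
        # estimated CAPs are noisy, order-shuffled copies of the basis CAPs —
        # the instance class the matcher actually faces
        agree = 0
        trials = 200
        for _ in range(trials):
            pats = _zpat(rng, 4, 12)
            basis = _basis(pats)
            order = rng.permutation(4)
            est = pats[order] + 0.5 * rng.standard_normal((4, 12))
            if match_caps(est, basis)[0] == exhaustive_match(est, basis):
                agree += 1
        assert agree / trials >= 0.95


class TestLabelBasisSet:
    def test_anticorrelated_pairs_get_pair_labels(self, rng):
        a, b = _zpat(rng, 1, 50)[0], _zpat(rng, 1, 50)[0]
        extra = _zpat(rng, 1, 50)[0]
        basis = _basis(np.vstack([a, -a, b, -b, extra]))
        labeled = label_basis_set(basis)
        pair_of = dict(zip(range(5), labeled.labels))
        assert {pair_of[0], pair_of[1]} in ({"I+", "I-"}, {"II+", "II-"})
        assert {pair_of[2], pair_of[3]} in ({"I+", "I-"}, {"II+", "II-"})
        assert pair_of[4] == "III"

    def test_four_pattern_set_has_no_extra_label(self, rng):
        a, b = _zpat(rng, 1, 50)[0], _zpat(rng, 1, 50)[0]
        labeled = label_basis_set(_basis(np.vstack([a, -a, b, -b])))
        assert sorted(labeled.labels) == ["I+", "I-", "II+", "II-"]


class TestOccurrenceStats:
    def _ledger_with_khats(self, khats, members):
        sets, subject_sets = [], []
        rng = np.random.default_rng(0)
        for (k1, k2), (m1, m2) in zip(khats, members):
            sets.append([rng.standard_normal((k1, 6)),
                         rng.standard_normal((k2, 6))])
            subject_sets.append([m1, m2])
        return _fake_ledger(sets, subject_sets=subject_sets)

    def test_single_permutation_unit_count(self):
        ledger = self._ledger_with_khats([(5, 4)], [(["a"], ["b"])])
        out = occurrence_stats(ledger).set_index("subject_id")
        assert out.loc["a", "occ5_s1"] == 1
        assert out.loc["a", "occ4_s1"] == 0
        assert out.loc["a", "delta_mean"] == pytest.approx(0.5)  # split 2 empty
        assert out.loc["b", "occ4_s2"] == 1

    def test_all_k4_gives_zero_variance_warning(self):
        ledger = self._ledger_with_khats([(4, 4), (4, 4)],
                                         [(["a"], ["b"]), (["a"], ["b"])])
        with pytest.warns(UserWarning, match="zero variance"):
            out = occurrence_stats(ledger)
        assert (out["delta_z"] == 0).all()

    def test_delta_z_is_standardized(self):
        khats = [(5, 4), (4, 5), (5, 5), (4, 4)]
        members = [(["a"], ["b"]), (["b"], ["a"]), (["a"], ["b"]), (["b"], ["a"])]
        out = occurrence_stats(self._ledger_with_khats(khats, members))
        assert out["delta_z"].mean() == pytest.approx(0.0, abs=1e-8)
        assert out["delta_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_other_khat_values_count_toward_neither(self):
        ledger = self._ledger_with_khats([(7, 5)], [(["a"], ["b"])])
        out = occurrence_stats(ledger).set_index("subject_id")
        assert out.loc["a", ["occ4_s1", "occ5_s1"]].sum() == 0
        assert out.loc["b", "occ5_s2"] == 1


class TestMatchedMetricsTable:
    def test_cluster_indices_replaced_by_basis_labels(self, rng):
        pats = _zpat(rng, 3, 20)
        m = pd.DataFrame({"subject_id": ["a", "a", "a"], "day": [1, 1, 1],
                          "state": [0, 1, 2], "fo": [0.5, 0.3, 0.2],
                          "mean_dt": [2, 1, 1], "var_dt": [0, 0, 0],
                          "n_segments": [1, 1, 1], "permutation": [0] * 3,
                          "split": [0] * 3, "k_hat": [3] * 3})
        ledger = _fake_ledger([[pats.copy(), pats.copy()]],
                              metrics=[[m, m.assign(split=1)]])
        basis = _basis(pats, labels=["X", "Y", "Z"])
        tidy = matched_metrics_table(ledger, basis)
        assert set(tidy["cap_label"]) == {"X", "Y", "Z"}
        assert tidy[tidy["cap_label"] == "X"]["fo"].iloc[0] == 0.5


def test_basis_similarity_is_identity_for_self(rng):
    pats = _zpat(rng, 3, 15)
    b = _basis(pats, labels=["a", "b", "c"])
    sim = basis_similarity(b, b)
    assert np.allclose(np.diag(sim.to_numpy()), 1.0)
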