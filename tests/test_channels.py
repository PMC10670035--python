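"""Channel sets, PCA compression, Fisher criterion, and SFFS behavior."""

import itertools

import numpy as np
import pytest

from rsvpweak.channels import (
    FIXED_SETS,
    compress_features,
    fisher_criterion,
    fixed_sets,
    scatter_matrices,
    selection_frequency,
    sffs_select,
)
from rsvpweak.montage import MONTAGE_62, PARIETAL
from rsvpweak.preprocess import EpochSet
from rsvpweak.simulate import erp_template


def _epochset(data, labels):
    n, nch = data.shape[:2]
    return EpochSet(data=data, labels=np.asarray(labels, dtype=bool),
                    condition=np.array(["C1"] * n, dtype=object), rate=125.0,
                    channels=tuple(f"CH{i}" for i in range(nch)))


class TestFixedSets:
    def test_sizes_and_montage_membership(self):
        sizes = {s.name: len(s.channels) for s in fixed_sets()}
        assert sizes == {"1": 62, "2": 32, "3": 16, "4": 8, "5": 8}
        for s in fixed_sets():
            assert set(s.channels) <= set(MONTAGE_62)
            assert len(set(s.channels)) == len(s.channels)

    def test_full_set_is_whole_montage(self):
        assert FIXED_SETS["1"] == MONTAGE_62

    def test_midline_set(self):
        assert FIXED_SETS["4"] == ("FPz", "Fz", "FCz", "Cz", "CPz", "Pz",
                                   "POz", "Oz")
        assert all(c.endswith("z") for c in FIXED_SETS["4"])

    def test_sixteen_channel_set_leads_with_frontocentral_row(self):
        assert FIXED_SETS["3"][:3] == ("Fz", "FC1", "FC2")
        assert len(FIXED_SETS["3"]) == 16


class TestCompressFeatures:
    def test_rank_limited_data(self, rng):
        basis = rng.normal(size=(3, 40))
        X = rng.normal(size=(60, 3)) @ basis
        _, p = compress_features(X, 0.99)
        assert p == 3

    def test_var_target_one_keeps_full_rank(self, rng):
        X = rng.normal(size=(30, 5))
        Z, p = compress_features(X, 1.0)
        assert p == 5
        assert Z.shape == (30, 5)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(80, 10)) * np.linspace(3.0, 0.3, 10)
        _, p = compress_features(X, 0.99)
        C = np.cov(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        cum = np.cumsum(evals) / evals.sum()
        p_oracle = int(np.searchsorted(cum, 0.99, side="right")) + 1
        assert p == p_oracle

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_variance_target(self, bad, rng):
        with pytest.raises(ValueError):
            compress_features(rng.normal(size=(10, 4)), bad)


class TestFisherCriterion:
    def test_identical_classes_score_near_zero(self, rng):
        data = rng.normal(size=(200, 2, 10))
        labels = np.arange(200) < 100
        score = fisher_criterion(data, labels)
        strong = data.copy()
        strong[labels] += 1.0
        assert score < 0.1 * fisher_criterion(strong, labels)

    def test_one_dimensional_closed_form(self, rng):
        x = np.concatenate([rng.normal(-1, 1, 300), rng.normal(1, 1, 300)])
        labels = np.arange(600) < 300
        data = x.reshape(-1, 1, 1)
        score = fisher_criterion(data, labels, var_target=1.0)
        # hand-computed scatter ratio on the same numbers
        m1, m0, m = x[labels].mean(), x[~labels].mean(), x.mean()
        sb = 300 * (m1 - m) ** 2 + 300 * (m0 - m) ** 2
        sw = ((x[labels] - m1) ** 2).sum() + ((x[~labels] - m0) ** 2).sum()
        assert score == pytest.approx(sb / sw, rel=1e-4)

    def test_invariant_to_channel_order(self, rng):
        data = rng.normal(size=(100, 4, 8))
        labels = np.arange(100) < 50
        data[labels, 2] += 0.8
        perm = data[:, [3, 1, 0, 2], :]
        assert fisher_criterion(data, labels) == pytest.approx(
            fisher_criterion(perm, labels), rel=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fisher_criterion(rng.normal(size=(10, 2, 5)), np.ones(10, bool))

    def test_bias_correction_formula(self, rng):
        data = rng.normal(size=(100, 3, 10))
        labels = np.arange(100) < 50
        raw = fisher_criterion(data, labels)
        corr = fisher_criterion(data, labels, corrected=True)
        X = data.reshape(100, -1)
        _, p = compress_features(X, 0.99)
        nu = 100 - 2
        assert corr == pytest.approx(((nu - p - 1) * raw - p) / nu)
        assert corr < raw

    def test_scatter_matrices_are_symmetric_psd(self, rng):
        Z = rng.normal(size=(60, 5))
        labels = np.arange(60) < 30
        Sw, Sb = scatter_matrices(Z, labels)
        for M in (Sw, Sb):
            np.testing.assert_allclose(M, M.T)
            assert np.linalg.eigvalsh(M).min() > -1e-9


def _planted(seed=0, n=120, nch=8, ns=40, chans=(1, 4, 6), amp=1.5):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 1, (n, nch, ns))
    labels = np.arange(n) < n // 3
    bump = erp_template(amp, 160, 100, 320, 125)
    for ch in chans:
        data[labels, ch, :] += bump
    return _epochset(data, labels)


class TestSffs:
    def test_recovers_planted_channels_and_exhaustive_optimum(self):
        ep = _planted()
        sel = sffs_select(ep, k=3)
        assert sorted(sel.channels) == ["CH1", "CH4", "CH6"]
        best = max(
            fisher_criterion(ep.data[:, list(s), :], ep.labels, corrected=True)
            for s in itertools.combinations(range(8), 3))
        assert sel.score == pytest.approx(best)

    def test_k_equal_to_channel_count_returns_everything(self):
        ep = _planted()
        sel = sffs_select(ep, k=8)
        assert set(sel.channels) == set(ep.channels)

    def test_never_worse_than_plain_greedy(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            data = rng.normal(size=(90, 6, 12))
            labels = np.arange(90) < 45
            data[labels, rng.integers(0, 6)] += rng.uniform(0.3, 0.7)
            ep = _epochset(data, labels)
            sel = sffs_select(ep, k=3)
            cur = []
            for _ in range(3):
                scores = {
                    c: fisher_criterion(
                        ep.data[:, [ep.channels.index(x) for x in cur + [c]], :],
                        labels, corrected=True)
                    for c in ep.channels if c not in cur
                }
                cur.append(max(sorted(scores), key=lambda c: scores[c]))
            greedy = fisher_criterion(
                ep.data[:, [ep.channels.index(c) for c in cur], :],
                labels, corrected=True)
            assert sel.score >= greedy - 1e-9

    def test_deterministic(self):
        ep = _planted(seed=3)
        a = sffs_select(ep, k=4)
        b = sffs_select(ep, k=4)
        assert a.channels == b.channels and a.score == b.score

    @pytest.mark.parametrize("k", [0, -1, 99])
    def test_invalid_k(self, k):
        with pytest.raises(ValueError):
            sffs_select(_planted(), k=k)

    def test_single_class_rejected(self):
        ep = _planted()
        with pytest.raises(ValueError):
            sffs_select(ep, labels=np.ones(len(ep.labels), bool), k=2)


class TestSelectionFrequency:
    def test_single_subset(self):
        counts = selection_frequency([("Pz",)])
        assert counts["Pz"] == 1
        assert sum(counts.values()) == 1

    def test_counts_conserved(self):
        subsets = [("Pz", "Cz"), ("Pz", "Oz", "P3"), ("Fz",)]
        counts = selection_frequency(subsets)
        assert sum(counts.values()) == sum(len(s) for s in subsets)
        assert counts["Pz"] == 2

    def test_parietal_montage_channels_present(self):
        counts = selection_frequency([])
        assert set(counts) == set(MONTAGE_62)
        assert set(PARIETAL) <= set(counts)
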