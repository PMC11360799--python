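"""Tests for multi-class SMOTE/ADASYN oversampling to the majority count."""

import numpy as np
import pytest

from halfwave.balance import (
    BalanceConfig,
    MajorityADASYN,
    MajoritySMOTE,
    adasyn_oversample,
    balance,
    smote_oversample,
)


def imbalanced_blobs(rng, counts=(30, 12, 5)):
    X, y = [], []
    for c, n in enumerate(counts):
        X.append(rng.normal(loc=2.0 * c, scale=1.0, size=(n, 3)))
        y += [f"c{c}"] * n
    return np.vstack(X), np.asarray(y, dtype=object)


def class_counts(y):
    labels, counts = np.unique(y.astype(str), return_counts=True)
    return dict(zip(labels, counts))


@pytest.mark.parametrize("fn", [smote_oversample, adasyn_oversample])
class TestCommonContract:
    def test_counts_equalized_to_majority(self, fn, rng):
        X, y = imbalanced_blobs(rng)
        Xo, yo, flags = fn(X, y, random_state=0)
        assert set(class_counts(yo).values()) == {30}
        assert flags.sum() == (30 - 12) + (30 - 5)

    def test_originals_preserved_verbatim(self, fn, rng):
        X, y = imbalanced_blobs(rng)
        Xo, yo, flags = fn(X, y, random_state=0)
        assert np.array_equal(Xo[~flags], X)
        assert np.array_equal(yo[~flags], y)

    def test_already_balanced_input_unchanged(self, fn, rng):
        X, y = imbalanced_blobs(rng, counts=(10, 10, 10))
        Xo, yo, flags = fn(X, y, random_state=0)
        assert np.array_equal(Xo, X) and not flags.any()

    def test_bit_reproducible_under_seed(self, fn, rng):
        X, y = imbalanced_blobs(rng)
        a = fn(X, y, random_state=42)
        b = fn(X, y, random_state=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_singleton_class_duplicated_with_warning(self, fn, rng):
        X, y = imbalanced_blobs(rng, counts=(6, 1))
        with pytest.warns(UserWarning, match="single sample"):
            Xo, yo, _ = fn(X, y, random_state=0)
        assert class_counts(yo)["c1"] == 6


class TestSmoteGeometry:
    def test_synthetic_points_lie_on_seed_neighbor_segments(self, rng):
        X, y = imbalanced_blobs(rng, counts=(25, 8))
        Xo, yo, flags = smote_oversample(X, y, random_state=3)
        minority = X[y == "c1"]
        for p in Xo[flags]:
            # p = x + lam*(nb - x) for some same-class pair and one lam
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    r = p - minority[i]
                    nz = np.abs(d) > 1e-12
                    if not nz.any():
                        continue
                    lam = r[nz] / d[nz]
                    if (
                        np.allclose(lam, lam[0], atol=1e-9)
                        and -1e-9 <= lam[0] <= 1 + 1e-9
                        and np.allclose(r[~nz], 0.0, atol=1e-9)
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_synthetic_labels_are_minority_labels(self, rng):
        X, y = imbalanced_blobs(rng)
        _, yo, flags = smote_oversample(X, y, random_state=1)
        assert set(yo[flags]) <= {"c1", "c2"}


class TestAdasynWeighting:
    def test_interior_samples_with_zero_ri_get_no_budget(self):
        # minority samples A=[0,0] and B=[10,0] only see same-class nearest
        # neighbours (r=0); C=[10.6,0] sits against the majority cloud
        # (r=1), so the whole synthetic budget goes to C: with sigma=0 the
        # generated point lies on the C-B segment, never near A.
        maj = np.array([[11.0, 0.0], [11.5, 0.0], [12.0, 0.0], [12.5, 0.0]])
        minority = np.array([[0.0, 0.0], [10.0, 0.0], [10.6, 0.0]])
        X = np.vstack([maj, minority])
        y = np.array(["M"] * 4 + ["m"] * 3, dtype=object)
        Xo, yo, flags = adasyn_oversample(
            X, y, k_neighbors=1, sigma=0.0, random_state=0
        )
        assert class_counts(yo)["m"] == 4
        syn = Xo[flags]
        assert syn.shape == (1, 2)
        assert 10.0 - 1e-9 <= syn[0, 0] <= 10.6 + 1e-9
        assert syn[0, 1] == pytest.approx(0.0)

    def test_boundary_samples_receive_the_budget(self):
        # k=3: minority sample near the majority cloud sees 3 foreign
        # neighbours, the remote one sees its own class first
        maj = np.array([[5.0, 0.0], [5.5, 0.0], [6.0, 0.0]])
        minority = np.array([[4.5, 0.0], [-10.0, 0.0], [-10.5, 0.0], [-11.0, 0.0]])
        X = np.vstack([maj, minority])
        y = np.array(["M"] * 3 + ["m"] * 4, dtype=object)
        # capture allocation via the synthetic points' nearest originals
        Xo, yo, flags = adasyn_oversample(X, y, k_neighbors=3, random_state=5)
        assert class_counts(yo)["m"] == class_counts(yo)["M"] == 4

    def test_isolated_class_falls_back_to_uniform_with_warning(self):
        a = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [0.5]])
        b = np.array([[100.0], [100.1]])
        X = np.vstack([a, b])
        y = np.array(["a"] * 6 + ["b"] * 2, dtype=object)
        with pytest.warns(UserWarning, match="isolated"):
            Xo, yo, _ = adasyn_oversample(X, y, k_neighbors=1, random_state=0)
        assert class_counts(yo)["b"] == 6

    def test_jitter_stays_within_inflated_bounding_box(self, rng):
        X, y = imbalanced_blobs(rng)
        Xo, yo, flags = adasyn_oversample(X, y, sigma=0.01, random_state=2)
        margin = 3 * 0.01 * X.std(axis=0)
        for c in ("c1", "c2"):
            orig = X[y == c]
            syn = Xo[flags][yo[flags] == c]
            lo = orig.min(axis=0) - margin - 1e-12
            hi = orig.max(axis=0) + margin + 1e-12
            assert np.all(syn >= lo) and np.all(syn <= hi)


class TestConfigAndEstimators:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BalanceConfig(method="undersample")
        with pytest.raises(ValueError):
            BalanceConfig(k_neighbors=0)

    def test_balance_dispatch(self, rng):
        X, y = imbalanced_blobs(rng)
        for method in ("smote", "adasyn"):
            Xo, yo, _ = balance(X, y, BalanceConfig(method=method, seed=1))
            assert len(set(class_counts(yo).values())) == 1

    def test_fit_resample_estimators(self, rng):
        X, y = imbalanced_blobs(rng)
        for cls in (MajoritySMOTE, MajorityADASYN):
            sampler = cls(random_state=9)
            Xo, yo = sampler.fit_resample(X, y)
            assert len(set(class_counts(yo).values())) == 1
            assert sampler.synthetic_mask_.shape[0] == Xo.shape[0]
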