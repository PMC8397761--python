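"""Random-forest OOB accuracy and permutation (MDA) importance."""

import numpy as np
import pytest

from rhizodiel import (
    AbundanceMatrix,
    SampleMetadata,
    circadian_indicator_overlap,
    fit_phase_forest,
    mean_decrease_accuracy,
    top_indicators,
)
from rhizodiel.indicators import ImportanceRecord
from rhizodiel.rhythm import RhythmCall


def make_dataset(X, n_reps=None):
    """Wrap a feature matrix into an alternating AM/PM design (LD)."""
    n, p = X.shape
    assert n % 6 == 0
    n_reps = n // 6
    sids, meta = [], []
    k = 0
    for t in range(1, 7):
        for r in range(1, n_reps + 1):
            sid = f"s{k}"
            k += 1
            sids.append(sid)
            meta.append(
                SampleMetadata(sid, "LD", "rhizosphere", t, "AM" if t % 2 else "PM", r)
            )
    abund = AbundanceMatrix(
        sids, [f"g{j}" for j in range(p)], np.abs(X), "normalized_counts"
    )
    return abund, meta


def informative_matrix(rng, n=36, p=10):
    """One genus tracks the phase perfectly; the rest are noise."""
    X = rng.uniform(1, 2, size=(n, p))
    phase_pm = np.array([(t % 2 == 0) for t in np.repeat(np.arange(1, 7), n // 6)])
    X[:, 0] = np.where(phase_pm, 10.0, 1.0) + rng.normal(0, 0.1, n)
    return X, phase_pm


class TestForest:
    def test_null_features_give_chance_oob(self, rng):
        X = rng.uniform(size=(36, 8))
        abund, meta = make_dataset(X)
        forest = fit_phase_forest(abund, meta, "LD", n_trees=300, seed=0)
        assert abs(forest.oob_accuracy - 0.5) < 0.2

    def test_perfect_feature_gives_high_oob(self, rng):
        X, _ = informative_matrix(rng)
        abund, meta = make_dataset(X)
        forest = fit_phase_forest(abund, meta, "LD", n_trees=300, seed=0)
        assert forest.oob_accuracy >= 0.95

    def test_seeded_determinism(self, rng):
        X, _ = informative_matrix(rng)
        abund, meta = make_dataset(X)
        f1 = fit_phase_forest(abund, meta, "LD", n_trees=100, seed=5)
        f2 = fit_phase_forest(abund, meta, "LD", n_trees=100, seed=5)
        assert np.array_equal(f1.oob_predictions, f2.oob_predictions)
        m1 = mean_decrease_accuracy(f1)
        m2 = mean_decrease_accuracy(f2)
        assert [r.mda for r in m1] == [r.mda for r in m2]

    def test_single_class_rejected(self, rng):
        X = rng.uniform(size=(36, 4))
        abund, meta = make_dataset(X)
        with pytest.raises(ValueError, match="single class"):
            fit_phase_forest(abund, meta, "LD", labels="regime")

    def test_oob_centered_at_half_under_label_permutation(self, rng):
        """Shuffling the phase labels destroys all signal."""
        X, _ = informative_matrix(rng)
        abund, meta = make_dataset(X)
        perm = rng.permutation(len(meta))
        shuffled = [
            SampleMetadata(
                m.sample_id, m.regime, m.compartment,
                meta[j].timepoint, meta[j].phase, m.replicate,
            )
            for m, j in zip(meta, perm)
        ]
        accs = [
            fit_phase_forest(abund, shuffled, "LD", n_trees=200, seed=s).oob_accuracy
            for s in range(3)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.25


class TestMda:
    def test_noise_feature_mda_within_permutation_error(self, rng):
        X, _ = informative_matrix(rng)
        abund, meta = make_dataset(X)
        forest = fit_phase_forest(abund, meta, "LD", n_trees=400, seed=2)
        records = {r.genus_id: r for r in mean_decrease_accuracy(forest)}
        for g in ("g3", "g5", "g7"):
            rec = records[g]
            assert abs(rec.mda) < max(3 * rec.mda_se, 1e-9)

    def test_sole_informative_feature_mda_near_oob_minus_chance(self, rng):
        """With every feature considered per split, each tree splits once on
        the informative genus; permuting it drops that tree to chance, so
        MDA ≈ OOB accuracy − 0.5."""
        X, _ = informative_matrix(rng)
        abund, meta = make_dataset(X)
        forest = fit_phase_forest(
            abund, meta, "LD", n_trees=400, seed=2, max_features=None
        )
        records = {r.genus_id: r for r in mean_decrease_accuracy(forest)}
        assert records["g0"].mda == pytest.approx(forest.oob_accuracy - 0.5, abs=0.1)
        assert records["g0"].rank == 1

    def test_duplicated_feature_splits_importance(self, rng):
        X, _ = informative_matrix(rng)
        abund, meta = make_dataset(X)
        forest = fit_phase_forest(abund, meta, "LD", n_trees=400, seed=3)
        solo = {r.genus_id: r.mda for r in mean_decrease_accuracy(forest)}["g0"]
        X_dup = np.column_stack([X, X[:, 0]])
        abund2, meta2 = make_dataset(X_dup)
        forest2 = fit_phase_forest(abund2, meta2, "LD", n_trees=400, seed=3)
        dup = {r.genus_id: r.mda for r in mean_decrease_accuracy(forest2)}
        assert dup["g0"] < solo
        assert dup[f"g{X.shape[1]}"] < solo

    def test_constant_feature_changes_nothing_without_subsampling(self, rng):
        """With all features considered at each split, a constant column can
        never be chosen, so MDA of the others is unchanged."""
        X, _ = informative_matrix(rng, p=5)
        abund, meta = make_dataset(X)
        kw = dict(n_trees=150, seed=4, max_features=None)
        base = mean_decrease_accuracy(fit_phase_forest(abund, meta, "LD", **kw))
        X_const = np.column_stack([X, np.full(X.shape[0], 3.0)])
        abund2, meta2 = make_dataset(X_const)
        with_const = mean_decrease_accuracy(fit_phase_forest(abund2, meta2, "LD", **kw))
        assert [r.mda for r in with_const[:5]] == pytest.approx(
            [r.mda for r in base], abs=1e-12
        )


class TestTopAndOverlap:
    def records(self, mdas):
        ranked = sorted(range(len(mdas)), key=lambda i: (-mdas[i], f"g{i}"))
        ranks = {i: r + 1 for r, i in enumerate(ranked)}
        return [
            ImportanceRecord(f"g{i}", mda, 0.0, ranks[i]) for i, mda in enumerate(mdas)
        ]

    def call(self, gid, circ):
        return RhythmCall(gid, "LD", 0.01, "day_high", circ, circ, np.ones(6))

    def test_top_n_selection_and_error(self):
        recs = self.records([0.1, 0.5, 0.3])
        top = top_indicators(recs, 2)
        assert [r.genus_id for r in top] == ["g1", "g2"]
        assert [r.genus_id for r in top_indicators(recs, 3)] == ["g1", "g2", "g0"]
        with pytest.raises(ValueError):
            top_indicators(recs, 4)

    def test_mda_ties_break_lexicographically(self):
        recs = self.records([0.2, 0.2, 0.5])
        assert [r.genus_id for r in top_indicators(recs, 3)] == ["g2", "g0", "g1"]

    def test_overlap_trivial_cases(self):
        recs = self.records([0.1, 0.2])
        none = [self.call("g9", True)]
        assert circadian_indicator_overlap(recs, none) == ([], 0.0)
        both = [self.call("g0", True), self.call("g1", True)]
        shared, total = circadian_indicator_overlap(recs, both)
        assert shared == ["g0", "g1"]
        assert total == pytest.approx(0.3)
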