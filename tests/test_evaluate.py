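"""Global Dice, confusion matrices, refinement and score aggregation."""

import numpy as np
import pandas as pd
import pytest

from rildseg import evaluate as ev
from conftest import random_label_volume


def brute_force_dice(preds, gts, masks, c):
    tp = fp = fn = 0
    for p, g, m in zip(preds, gts, masks):
        for idx in np.ndindex(p.shape):
            if not m[idx]:
                continue
            pi, gi = p[idx] == c, g[idx] == c
            tp += pi and gi
            fp += pi and not gi
            fn += gi and not pi
    return None if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)


class TestGlobalDice:
    def test_perfect_prediction(self, rng):
        labels, mask = random_label_volume(rng)
        d = ev.global_dice([labels], [labels], masks=[mask])
        present = set(np.unique(labels[mask]))
        for c in range(1, 6):
            assert d[c] == 1.0 if c in present else d[c] is None

    def test_disjoint_supports_zero(self):
        g = np.full((2, 4, 4), 1, dtype=np.int16)
        p = np.full((2, 4, 4), 2, dtype=np.int16)
        m = np.ones_like(g, dtype=bool)
        d = ev.global_dice([p], [g], masks=[m])
        assert d[1] == 0.0 and d[2] == 0.0

    def test_pooled_differs_from_per_scan_average(self):
        """Two-scan fixture: pooled Dice 200/220, per-scan mean 0.545."""
        # scan A: 10 true / 10 predicted class-2 voxels, overlap 1
        #   -> TP=1, FP+FN=18, per-scan Dice 2/20 = 0.1
        a_gt = np.full((1, 5, 8), 1, dtype=np.int16).ravel()
        a_pred = a_gt.copy()
        a_gt[:10] = 2
        a_pred[9:19] = 2
        # scan B: 100 true / 100 predicted, overlap 99
        #   -> TP=99, FP+FN=2, per-scan Dice 198/200 = 0.99
        b_gt = np.full((1, 10, 20), 1, dtype=np.int16).ravel()
        b_pred = b_gt.copy()
        b_gt[:100] = 2
        b_pred[1:101] = 2
        scans = ([a_pred.reshape(1, 5, 8), b_pred.reshape(1, 10, 20)],
                 [a_gt.reshape(1, 5, 8), b_gt.reshape(1, 10, 20)])
        masks = [np.ones((1, 5, 8), bool), np.ones((1, 10, 20), bool)]
        pooled = ev.global_dice(scans[0], scans[1], class_id=2, masks=masks)
        assert pooled == pytest.approx(200 / 220)
        per_scan_mean = (0.1 + 0.99) / 2
        assert per_scan_mean == pytest.approx(0.545)
        assert abs(pooled - per_scan_mean) > 0.3  # pooled != averaged

    def test_matches_bruteforce_voxel_loop(self, rng):
        for _ in range(10):
            g, m = random_label_volume(rng, shape=(3, 5, 6))
            p, _ = random_label_volume(rng, shape=(3, 5, 6))
            p = np.where(m, np.where(p == 0, 1, p), 0)
            d = ev.global_dice([p], [g], masks=[m])
            for c in range(1, 6):
                bf = brute_force_dice([p], [g], [m], c)
                if bf is None:
                    assert d[c] is None
                else:
                    assert abs(d[c] - bf) < 1e-12

    def test_symmetry(self, rng):
        g, m = random_label_volume(rng)
        p, _ = random_label_volume(rng)
        p = np.where(m, np.where(p == 0, 1, p), 0)
        assert ev.global_dice([p], [g], masks=[m]) == ev.global_dice([g], [p], masks=[m])


class TestConfusion:
    def test_identity_when_perfect(self, rng):
        labels, mask = random_label_volume(rng)
        M = ev.confusion_matrix([labels], [labels], masks=[mask])
        assert np.all(M == np.diag(np.diag(M)))
        N = ev.normalise_confusion(M)
        for i in range(5):
            if M[i].sum():
                assert N[i, i] == 1.0

    def test_total_conserves_lung_voxels(self, rng):
        g, m = random_label_volume(rng)
        p = np.where(m, 2, 0).astype(np.int16)
        M = ev.confusion_matrix([p], [g], masks=[m])
        assert M.sum() == int(m.sum())
        assert M[:, [0, 2, 3, 4]].sum() == 0  # all predictions in column 2

    def test_dice_recomputed_from_confusion(self, rng):
        g, m = random_label_volume(rng)
        p, _ = random_label_volume(rng)
        p = np.where(m, np.where(p == 0, 1, p), 0)
        M = ev.confusion_matrix([p], [g], masks=[m])
        d_direct = ev.global_dice([p], [g], masks=[m])
        d_conf = ev.dice_from_confusion(M)
        for c in range(1, 6):
            if d_direct[c] is None:
                assert d_conf[c] is None
            else:
                assert abs(d_direct[c] - d_conf[c]) < 1e-12


class TestFoldSummary:
    def test_summary_formula(self):
        dices = [0.8, 0.9, 0.85, 0.95, 0.7]
        reports = [
            ev.EvalReport("validation", {c: d for c in range(1, 6)}, np.zeros((5, 5), int), fold=k)
            for k, d in enumerate(dices)
        ]
        s = ev.summarise_folds(reports)
        row = s[s["class"] == 3].iloc[0]
        assert row["mean"] == pytest.approx(np.mean(dices))
        assert row["std"] == pytest.approx(np.std(dices, ddof=1))
        half = 1.96 * row["std"] / np.sqrt(5)
        assert row["ci95_hi"] - row["ci95_lo"] == pytest.approx(2 * half)

    def test_undefined_folds_excluded_with_warning(self):
        dice_ok = {c: 0.5 for c in range(1, 6)}
        dice_missing = dice_ok | {4: None}
        reports = [
            ev.EvalReport("validation", dice_ok, np.zeros((5, 5), int), fold=0),
            ev.EvalReport("validation", dice_missing, np.zeros((5, 5), int), fold=1),
        ]
        with pytest.warns(UserWarning, match="class 4"):
            s = ev.summarise_folds(reports)
        assert s[s["class"] == 4].iloc[0]["n_folds"] == 1


class TestDisagreement:
    def test_identical_maps(self, rng):
        g, m = random_label_volume(rng)
        _, frac, hist = ev.disagreement_map(g, g, m)
        assert frac == 0.0 and hist == {}

    def test_uniform_offset_by_one_class(self):
        a = np.full((2, 3, 3), 2, dtype=np.int16)
        b = a + 1
        _, frac, hist = ev.disagreement_map(a, b, np.ones_like(a, bool))
        assert frac == 1.0 and list(hist) == [1]

    def test_fraction_matches_counting_oracle(self, rng):
        a, m = random_label_volume(rng)
        b, _ = random_label_volume(rng)
        b = np.where(m, np.where(b == 0, 1, b), 0)
        _, frac, _ = ev.disagreement_map(a, b, m)
        manual = sum(
            1 for idx in np.ndindex(a.shape) if m[idx] and a[idx] != b[idx]
        )
        assert frac == pytest.approx(manual / int(m.sum()))

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            ev.disagreement_map(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestRefinementReport:
    def test_all_automatic(self):
        recs = [ev.RefinementRecord(f"s{i}", "automatic", 0.1, "training") for i in range(4)]
        rep = ev.refinement_report(recs)
        assert rep.loc["training", "manual"] == 0.0
        assert rep.loc["training", "automatic"] == 100.0

    def test_seven_of_ten_manual(self):
        recs = [
            ev.RefinementRecord(f"s{i}", "manual" if i < 7 else "automatic", 0.0, "validation")
            for i in range(10)
        ]
        rep = ev.refinement_report(recs)
        assert rep.loc["validation", "manual"] == pytest.approx(70.0)
        assert rep.loc["validation"].sum() == pytest.approx(100.0)

    def test_invalid_choice_rejected(self):
        with pytest.raises(ValueError):
            ev.RefinementRecord("s", "neither", 0.0, "training")


class TestQualitativeSummary:
    def _grid(self, rng, n_scans=6):
        return pd.DataFrame(
            rng.integers(1, 4, (n_scans, 5)),
            columns=[f"class_{c}" for c in range(1, 6)],
        )

    def test_all_acceptable(self):
        scores = pd.DataFrame(np.ones((4, 5), int), columns=list("abcde"))
        s = ev.qualitative_summary(scores)
        assert np.allclose(s["acceptable"], 100.0)
        assert np.allclose(s[["minor_disagreement", "major_disagreement"]], 0.0)

    def test_rows_sum_to_hundred_and_avg_is_mean(self, rng):
        s = ev.qualitative_summary(self._grid(rng))
        assert np.allclose(s.sum(axis=1), 100.0)
        body = s.drop(index="AVG")
        assert np.allclose(s.loc["AVG"], body.mean(axis=0))

    def test_missing_cells_rejected(self, rng):
        grid = self._grid(rng).astype(float)
        grid.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            ev.qualitative_summary(grid)
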