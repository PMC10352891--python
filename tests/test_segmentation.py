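"""Winner-take-all hippocampal segmentation and partial correlation."""

import numpy as np
import pytest
from dataclasses import replace

from hippnet.cohort import CohortConfig, generate_cohort
from hippnet.extraction import BoldVolume, DegenerateInputError, EigenSeries, RoiMask, confine_to_gray_matter
from hippnet.segmentation import (
    ANTERIOR,
    POSTERIOR,
    HippocampalDivision,
    PartialCorrelationMaps,
    SubtractionMap,
    TargetPair,
    compute_partial_maps,
    division_volume_compare,
    group_division,
    partial_correlation,
    subject_division,
)
from hippnet.simulations import make_target_pair, segmentation_accuracy


class TestPartialCorrelation:
    def test_orthogonal_control_reduces_to_pearson(self, rng):
        t = 200
        x = rng.standard_normal(t)
        y = 0.6 * x + rng.standard_normal(t)
        c = rng.standard_normal(t)
        # orthogonalize control against x and y exactly
        A = np.column_stack([np.ones(t), x, y])
        c = c - A @ np.linalg.lstsq(A, c, rcond=None)[0]
        r_plain = np.corrcoef(x, y)[0, 1]
        assert partial_correlation(x, y, c) == pytest.approx(r_plain, abs=1e-10)

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        c = rng.standard_normal(50)
        assert partial_correlation(x, x, c) == pytest.approx(1.0, abs=1e-10)

    def test_recursive_formula_matches_residual_regression(self, rng):
        for _ in range(10):
            x, y, c = rng.standard_normal((3, 50))
            # residual-regression oracle
            A = np.column_stack([np.ones(50), c])
            rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
            ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert partial_correlation(x, y, c) == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x, y, c = rng.standard_normal((3, 60))
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        expected = float(pingouin.partial_corr(df, x="x", y="y", covar="c")["r"].iloc[0])
        assert partial_correlation(x, y, c) == pytest.approx(expected, abs=1e-8)

    def test_degenerate_inputs_raise(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(DegenerateInputError):
            partial_correlation(x, np.ones(20), rng.standard_normal(20))
        with pytest.raises(DegenerateInputError):
            partial_correlation(x, rng.standard_normal(20), x)  # collinear control


def _maps(r1, r2, valid=None):
    n = len(r1)
    mask = np.zeros((n, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    return PartialCorrelationMaps(
        r1=np.asarray(r1, float),
        r2=np.asarray(r2, float),
        mask=RoiMask(mask, "hipp"),
        valid=np.ones(n, bool) if valid is None else valid,
    )


class TestSubjectDivision:
    def test_anterior_wins_when_r1_larger(self):
        div, sub = subject_division(_maps([0.5], [0.2]))
        assert div.labels[0] == ANTERIOR
        assert sub.values[0] == pytest.approx(0.3)

    def test_tie_goes_posterior(self):
        div, _ = subject_division(_maps([0.4], [0.4]))
        assert div.labels[0] == POSTERIOR

    def test_matches_elementwise_comparison(self, rng):
        r1, r2 = rng.uniform(-1, 1, (2, 40))
        div, _ = subject_division(_maps(r1, r2))
        expected = np.where(r1 > r2, ANTERIOR, POSTERIOR)
        assert np.array_equal(div.labels, expected)


class TestGroupDivision:
    def test_single_subject_consistent_with_subject_division(self, rng):
        r1, r2 = rng.uniform(-1, 1, (2, 30))
        maps = _maps(r1, r2)
        div_subject, sub = subject_division(maps)
        div_group = group_division([sub])
        assert np.array_equal(div_subject.labels, div_group.labels)

    def test_cancellation_gives_all_posterior(self, rng):
        r1, r2 = rng.uniform(-1, 1, (2, 30))
        _, sub = subject_division(_maps(r1, r2))
        neg = SubtractionMap(values=-sub.values, mask=sub.mask, subject_id="neg")
        div = group_division([sub, neg])
        assert (div.labels == POSTERIOR).all()

    def test_mismatched_support_raises(self, rng):
        _, sub_a = subject_division(_maps(rng.uniform(-1, 1, 10), rng.uniform(-1, 1, 10)))
        _, sub_b = subject_division(_maps(rng.uniform(-1, 1, 12), rng.uniform(-1, 1, 12)))
        with pytest.raises(ValueError):
            group_division([sub_a, sub_b])

    def test_all_subject_division_equals_concatenated_groups(self, rng):
        """Group-unbiased division == division from both groups' maps pooled."""
        subs_a = [subject_division(_maps(*rng.uniform(-1, 1, (2, 25))))[1] for _ in range(3)]
        subs_b = [subject_division(_maps(*rng.uniform(-1, 1, (2, 25))))[1] for _ in range(4)]
        pooled = group_division(subs_a + subs_b)
        again = group_division(list(reversed(subs_b)) + list(reversed(subs_a)))
        assert np.array_equal(pooled.labels, again.labels)


class TestPartialMaps:
    def test_swapping_targets_exchanges_r1_r2(self, tiny_cohort):
        cohort = tiny_cohort
        targets = make_target_pair(cohort)
        hipp = confine_to_gray_matter(cohort.masks["hippocampus"], cohort.gm, 0.2)
        vol = cohort.volume(cohort.subject_ids()[0])
        maps = compute_partial_maps(vol, hipp, targets)
        swapped = compute_partial_maps(
            vol, hipp, TargetPair(anterior_target=targets.posterior_target,
                                  posterior_target=targets.anterior_target)
        )
        assert np.allclose(maps.r1, swapped.r2, atol=1e-10)
        assert np.allclose(maps.r2, swapped.r1, atol=1e-10)

    def test_planted_anterior_voxels_prefer_anterior_target(self):
        """High-SNR recovery: r1 > r2 on nearly all anterior-truth voxels."""
        cfg = CohortConfig(n_controls=1, n_patients=0, snr=4.0, seed=1)
        cohort = generate_cohort(cfg)
        targets = make_target_pair(cohort)
        hipp = confine_to_gray_matter(cohort.masks["hippocampus"], cohort.gm, 0.2)
        vol = cohort.volume("con001")
        maps = compute_partial_maps(vol, hipp, targets)
        truth = cohort.truth.voxel_labels[hipp.data]
        anterior = truth == 1
        assert np.mean(maps.r1[anterior] > maps.r2[anterior]) >= 0.99

    def test_pure_noise_maps_near_zero(self, rng):
        t = 144
        data = rng.standard_normal((10, 3, 3, t))
        vol = BoldVolume(data=data)
        hipp = RoiMask(np.zeros((10, 3, 3), bool), "hipp")
        hipp.data[:6] = True
        e1 = EigenSeries(values=rng.standard_normal(t), source_label="a")
        e2 = EigenSeries(values=rng.standard_normal(t), source_label="p")
        ta = RoiMask(np.zeros((10, 3, 3), bool), "ta"); ta.data[7, 0, 0] = True
        tp = RoiMask(np.zeros((10, 3, 3), bool), "tp"); tp.data[8, 0, 0] = True
        maps = compute_partial_maps(vol, hipp, TargetPair(ta, tp), target_series=(e1, e2))
        assert abs(maps.r1.mean()) < 2 / np.sqrt(t)
        assert abs(maps.r2.mean()) < 2 / np.sqrt(t)


class TestRecoveryExperiments:
    def test_group_recovery_at_moderate_snr(self):
        cfg = CohortConfig(n_controls=10, n_patients=10, n_timepoints=100, snr=1.0, seed=23)
        res = segmentation_accuracy(cfg)
        assert res["group_accuracy"] >= 0.95

    def test_recovery_monotone_in_snr_and_n(self):
        accs = {}
        for snr in (0.25, 1.0):
            for n in (4, 10):
                cfg = CohortConfig(n_controls=n, n_patients=n, n_timepoints=80, snr=snr, seed=31)
                accs[(snr, n)] = segmentation_accuracy(cfg)["group_accuracy"]
        assert accs[(0.25, 4)] <= accs[(1.0, 4)] + 1e-12
        assert accs[(0.25, 10)] <= accs[(1.0, 10)] + 1e-12
        assert accs[(0.25, 4)] <= accs[(0.25, 10)] + 1e-12


class TestDivisionCompare:
    def _division(self, labels):
        n = len(labels)
        mask = np.zeros((n, 1, 1), bool)
        mask[:, 0, 0] = True
        return HippocampalDivision(labels=np.asarray(labels, np.uint8), mask=RoiMask(mask, "h"))

    def test_identical_divisions_dice_one(self):
        d = self._division([1, 1, 2, 2])
        cmp = division_volume_compare(d, d)
        assert cmp["anterior"]["dice"] == 1.0 and cmp["posterior"]["dice"] == 1.0

    def test_complementary_divisions_dice_zero(self):
        a = self._division([1, 1, 2, 2])
        b = self._division([2, 2, 1, 1])
        cmp = division_volume_compare(a, b)
        assert cmp["anterior"]["dice"] == 0.0 and cmp["posterior"]["dice"] == 0.0

    def test_dice_matches_set_arithmetic(self, rng):
        la = rng.choice([1, 2], 50)
        lb = rng.choice([1, 2], 50)
        cmp = division_volume_compare(self._division(la), self._division(lb))
        for name, code in (("anterior", 1), ("posterior", 2)):
            A, B = set(np.flatnonzero(la == code)), set(np.flatnonzero(lb == code))
            expected = 2 * len(A & B) / (len(A) + len(B))
            assert cmp[name]["dice"] == pytest.approx(expected)
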