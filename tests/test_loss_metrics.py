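"""Loss values against hand computations and metric agreement with
exhaustive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from safnet.loss_metrics import (
    ScoreTable,
    aggregate,
    categorical_ce_tensor,
    dsc,
    msd,
    one_hot,
    pixelwise_ce,
    pixelwise_ce_tensor,
)
from safnet.nn import Tensor


# -- independent oracles ------------------------------------------------------

def brute_dsc(pred, truth, cls):
    a = {tuple(i) for i in np.argwhere(pred == cls)}
    b = {tuple(i) for i in np.argwhere(truth == cls)}
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return 2 * len(a & b) / (len(a) + len(b))


def brute_surface(mask):
    pts = []
    for idx in np.argwhere(mask):
        for ax in range(3):
            for dlt in (-1, 1):
                nb = idx.copy()
                nb[ax] += dlt
                if (nb < 0).any() or (nb >= np.array(mask.shape)).any() \
                        or not mask[tuple(nb)]:
                    pts.append(tuple(idx))
                    break
            else:
                continue
            break
    return pts


def brute_msd(pred, truth, cls, spacing=(1.0, 1.0, 1.0)):
    a = pred == cls
    b = truth == cls
    if not a.any() or not b.any():
        return None
    sa = np.array(brute_surface(a), float) * spacing
    sb = np.array(brute_surface(b), float) * spacing
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
    return (sum(d_ab) + sum(d_ba)) / (len(d_ab) + len(d_ba))


# -- loss ---------------------------------------------------------------------

class TestPixelwiseCE:
    def test_uniform_half_probability_gives_ln2(self, rng):
        y = one_hot(rng.integers(0, 2, size=(3, 4, 5)), 2)
        p = np.full_like(y, 0.5)
        assert abs(pixelwise_ce(p, y).value - np.log(2)) < 1e-6

    def test_perfect_prediction_limit(self, rng):
        y = one_hot(rng.integers(0, 3, size=(3, 4, 5)), 3)
        assert pixelwise_ce(y, y).value < 1e-5

    def test_hand_computed_single_voxel_two_classes(self):
        # Y=(1,0), P=(0.8,0.2): -(ln 0.8 + ln 0.8)/2 = -ln 0.8
        y = np.array([1.0, 0.0]).reshape(2, 1, 1, 1)
        p = np.array([0.8, 0.2]).reshape(2, 1, 1, 1)
        assert abs(pixelwise_ce(p, y).value - 0.22314355) < 1e-6

    def test_loss_decreases_toward_the_labels(self, rng):
        y = one_hot(rng.integers(0, 3, size=(4, 4, 4)), 3)
        logits = rng.normal(size=y.shape)
        p = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        losses = [pixelwise_ce((1 - t) * p + t * y, y).value
                  for t in np.linspace(0, 0.95, 8)]
        assert all(b < a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_rejects_non_binary_labels(self, rng):
        p = np.full((2, 2, 2, 2), 0.5)
        with pytest.raises(ValueError, match="binary"):
            pixelwise_ce(p, np.full_like(p, 0.3))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pixelwise_ce(np.full((2, 2, 2, 2), 0.5), np.ones((2, 2, 2, 3)))

    def test_gradient_flows_to_probabilities(self, rng):
        y = one_hot(rng.integers(0, 2, size=(2, 2, 2)), 2)
        p = Tensor(np.full(y.shape, 0.5), requires_grad=True)
        loss = pixelwise_ce_tensor(p, y)
        loss.backward()
        assert p.grad is not None and np.abs(p.grad).max() > 0

    def test_categorical_variant_on_hand_example(self):
        y = np.array([1.0, 0.0]).reshape(2, 1, 1, 1)
        p = np.array([0.8, 0.2]).reshape(2, 1, 1, 1)
        out = categorical_ce_tensor(Tensor(p), y)
        assert abs(out.item() - (-np.log(0.8))) < 1e-6


# -- DSC ----------------------------------------------------------------------

class TestDSC:
    def test_identity_and_disjoint(self, rng):
        lab = rng.integers(0, 3, size=(4, 4, 4))
        assert dsc(lab, lab, 1) == 1.0
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[:2], b[2:] = 1, 1
        assert dsc(a, b, 1) == 0.0

    def test_constructed_overlap(self):
        # |A|=4, |B|=6, overlap 3 -> 2*3/10 = 0.6
        a = np.zeros((3, 3, 3), int)
        b = np.zeros((3, 3, 3), int)
        a.reshape(-1)[:4] = 1
        b.reshape(-1)[1:7] = 1
        assert dsc(a, b, 1) == pytest.approx(0.6)

    def test_empty_mask_policy(self):
        empty = np.zeros((3, 3, 3), int)
        full = np.ones((3, 3, 3), int)
        assert dsc(empty, empty, 1) == 1.0
        assert dsc(empty, full, 1) == 0.0

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.integers(0, 3, size=(4, 4, 4))
        b = rng.integers(0, 3, size=(4, 4, 4))
        assert dsc(a, b, 1) == dsc(b, a, 1)
        perm = rng.permutation(64)
        ap = a.reshape(-1)[perm].reshape(4, 4, 4)
        bp = b.reshape(-1)[perm].reshape(4, 4, 4)
        assert dsc(a, b, 2) == pytest.approx(dsc(ap, bp, 2))


# -- MSD ----------------------------------------------------------------------

class TestMSD:
    def test_identical_masks_have_zero_distance(self, rng):
        lab = rng.integers(0, 2, size=(5, 5, 5))
        lab[2, 2, 2] = 1
        assert msd(lab, lab, 1) == 0.0

    def test_offset_unit_cubes_match_brute_force(self):
        a = np.zeros((6, 6, 6), int)
        b = np.zeros((6, 6, 6), int)
        a[2:4, 2:4, 2:4] = 1
        b[2:4, 2:4, 3:5] = 1  # shifted one voxel along width
        assert msd(a, b, 1) == pytest.approx(brute_msd(a, b, 1))

    def test_spacing_scales_linearly(self):
        a = np.zeros((6, 6, 6), int)
        b = np.zeros((6, 6, 6), int)
        a[1:3, 1:3, 1:3] = 1
        b[3:5, 3:5, 3:5] = 1
        one = msd(a, b, 1, spacing=(1, 1, 1))
        two = msd(a, b, 1, spacing=(2, 2, 2))
        assert two == pytest.approx(2 * one)

    def test_absent_class_reported_missing(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        b[1, 1, 1] = 1
        assert msd(a, b, 1) is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metrics_agree_with_brute_force_on_random_maps(seed):
    rng = np.random.default_rng(seed)
    pred = rng.integers(0, 3, size=(6, 6, 6))
    truth = rng.integers(0, 3, size=(6, 6, 6))
    for cls in (1, 2):
        assert dsc(pred, truth, cls) == pytest.approx(
            brute_dsc(pred, truth, cls))
        got = msd(pred, truth, cls)
        want = brute_msd(pred, truth, cls)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)


# -- aggregation --------------------------------------------------------------

def rows(dscs, cls=1):
    return [{"sample_id": f"s{i}", "class_id": cls, "class_name": "c",
             "dsc": v} for i, v in enumerate(dscs)]


class TestAggregate:
    def test_equal_rows_zero_spread(self):
        table = aggregate(rows([0.8, 0.8]))
        mean, sd = table.overall()
        assert (mean, sd) == (0.8, 0.0)
        assert table.format_percent() == "80.00 ± 0.00 %"

    def test_sample_standard_deviation_of_two_values(self):
        mean, sd = aggregate(rows([0.7, 0.9])).overall()
        assert mean == pytest.approx(0.8)
        assert sd == pytest.approx(np.std([0.7, 0.9], ddof=1))
        assert aggregate(rows([0.7, 0.9])).format_percent() == "80.00 ± 14.14 %"

    def test_single_row_degenerate_sd(self):
        mean, sd = aggregate(rows([0.75])).overall()
        assert (mean, sd) == (0.75, 0.0)

    def test_overall_mean_equals_mean_of_rows(self, rng):
        vals = rng.uniform(0, 1, size=37)
        mean, _ = aggregate(rows(list(vals))).overall()
        assert abs(mean - vals.mean()) < 1e-10

    def test_rejects_out_of_range_dsc(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            aggregate(rows([1.2]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_csv_json_round_trip(self, tmp_path):
        import pandas as pd
        table = aggregate(rows([0.5, 0.75]))
        table.to_csv(tmp_path / "t.csv")
        table.to_json(tmp_path / "t.json")
        back = pd.read_csv(tmp_path / "t.csv")
        assert list(back.columns) == ["sample_id", "class_id", "class_name",
                                      "dsc", "msd"]
        np.testing.assert_allclose(back["dsc"], [0.5, 0.75])
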