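"""Platform cutoffs, per-segment calling, and cutoff calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from armcall import (
    calibrate_amp_cutoff,
    calibrate_gain_loss,
    call_segment,
    default_platform_model,
    mycn_call,
    mycn_concordance,
)
from armcall.calling import CALL_LABELS, _density_intersection
from armcall.errors import CallingError
from conftest import make_segments

# hand-enumerated truth table spanning every cutoff boundary
TRUTH_TABLE = [
    # affymetrix_snp: gain +0.15, loss -0.25, amp 1.5, homdel < -2
    ("affymetrix_snp", -2.5, "homozygous_deletion"),
    ("affymetrix_snp", -2.0, "loss"),  # boundary: not strictly below -2
    ("affymetrix_snp", -0.25, "loss"),
    ("affymetrix_snp", -0.24, "normal"),
    ("affymetrix_snp", 0.0, "normal"),
    ("affymetrix_snp", 0.149, "normal"),
    ("affymetrix_snp", 0.15, "gain"),
    ("affymetrix_snp", 1.49, "gain"),
    ("affymetrix_snp", 1.5, "amplification"),
    # illumina_snp: same gain/loss, amp 0.7
    ("illumina_snp", 0.7, "amplification"),
    ("illumina_snp", 0.69, "gain"),
    ("illumina_snp", 0.18, "gain"),
    ("illumina_snp", -0.3, "loss"),
    # agilent_acgh: gain +0.2, loss -0.3, amp 2
    ("agilent_acgh", 0.18, "normal"),
    ("agilent_acgh", 0.2, "gain"),
    ("agilent_acgh", 0.8, "gain"),
    ("agilent_acgh", 1.99, "gain"),
    ("agilent_acgh", 2.0, "amplification"),
    ("agilent_acgh", -0.29, "normal"),
    ("agilent_acgh", -0.3, "loss"),
    ("agilent_acgh", -2.01, "homozygous_deletion"),
    # nimblegen_acgh: aCGH gain/loss, amp 1.5
    ("nimblegen_acgh", 1.5, "amplification"),
    ("nimblegen_acgh", 1.49, "gain"),
    ("nimblegen_acgh", 0.2, "gain"),
    ("nimblegen_acgh", -0.31, "loss"),
]


def test_default_cutoff_table():
    """The 12 published cutoffs: +0.15/-0.25 SNP, +0.2/-0.3 aCGH; amp 1.5
    (Affymetrix, NimbleGen), 2 (Agilent), 0.7 (Illumina); homdel -2."""
    expected = {
        "affymetrix_snp": (0.15, -0.25, 1.5),
        "illumina_snp": (0.15, -0.25, 0.7),
        "agilent_acgh": (0.20, -0.30, 2.0),
        "nimblegen_acgh": (0.20, -0.30, 1.5),
    }
    for family, (gain, loss, amp) in expected.items():
        m = default_platform_model(family)
        assert (m.gain_cutoff, m.loss_cutoff, m.amp_cutoff) == (gain, loss, amp)
        assert m.homdel_cutoff == -2.0
        assert m.loss_cutoff < 0 < m.gain_cutoff < m.amp_cutoff
        assert m.homdel_cutoff < m.loss_cutoff


def test_unknown_family_rejected():
    with pytest.raises(CallingError):
        default_platform_model("cytoscan")


@pytest.mark.parametrize("family,log2,expected", TRUTH_TABLE)
def test_call_segment_truth_table(family, log2, expected):
    assert call_segment(log2, default_platform_model(family)) == expected


def test_nonfinite_rejected():
    with pytest.raises(CallingError):
        call_segment(float("nan"), default_platform_model("agilent_acgh"))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(["affymetrix_snp", "illumina_snp", "agilent_acgh", "nimblegen_acgh"]),
    log2=st.floats(-4, 4, allow_nan=False),
    bump=st.floats(0, 2, allow_nan=False),
)
def test_call_monotone_in_log2(family, log2, bump):
    """Raising log2 never moves the label toward deletion."""
    model = default_platform_model(family)
    rank = {label: i for i, label in enumerate(CALL_LABELS)}
    assert rank[call_segment(log2 + bump, model)] >= rank[call_segment(log2, model)]


class TestGainLossCalibration:
    def test_equal_mixture_intersects_at_midpoints(self):
        """Equal-weight equal-sd Gaussians at -0.5/0/+0.5 cross midway."""
        assert _density_intersection(0.0, 0.1, 1 / 3, 0.5, 0.1, 1 / 3) == pytest.approx(0.25, abs=1e-9)
        assert _density_intersection(-0.5, 0.1, 1 / 3, 0.0, 0.1, 1 / 3) == pytest.approx(-0.25, abs=1e-9)
        rng = np.random.default_rng(0)
        comp = rng.choice(3, 6000)
        x = rng.normal(np.array([-0.5, 0.0, 0.5])[comp], 0.1)
        gain, loss = calibrate_gain_loss(x, np.ones_like(x), default_platform_model("agilent_acgh"))
        assert gain == pytest.approx(0.25, abs=0.03)
        assert loss == pytest.approx(-0.25, abs=0.03)

    def test_unequal_weights_match_numeric_root(self):
        rng = np.random.default_rng(4)
        w, mu, sd = (0.15, 0.6, 0.25), (-0.55, 0.0, 0.4), (0.12, 0.08, 0.15)
        comp = rng.choice(3, 8000, p=w)
        x = rng.normal(np.array(mu)[comp], np.array(sd)[comp])
        gain, loss = calibrate_gain_loss(x, np.ones_like(x), default_platform_model("affymetrix_snp"))
        true_gain = _density_intersection(mu[1], sd[1], w[1], mu[2], sd[2], w[2])
        true_loss = _density_intersection(mu[0], sd[0], w[0], mu[1], sd[1], w[1])
        assert gain == pytest.approx(true_gain, abs=0.03)
        assert loss == pytest.approx(true_loss, abs=0.03)

    def test_single_state_input_falls_back_to_defaults(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.05, 500)
        model = default_platform_model("agilent_acgh")
        with pytest.warns(UserWarning, match="falling back"):
            gain, loss = calibrate_gain_loss(x, np.ones_like(x), model)
        assert (gain, loss) == (model.gain_cutoff, model.loss_cutoff)

    def test_too_few_segments_rejected(self):
        with pytest.raises(CallingError):
            calibrate_gain_loss(np.zeros(50), np.ones(50), default_platform_model("agilent_acgh"))


def amp_cutoff_oracle(values, labels):
    """Exhaustive scan over every midpoint (independent re-derivation)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    xs = np.unique(values)
    best_t, best_acc = None, -1.0
    for t in (xs[:-1] + xs[1:]) / 2:
        acc = np.mean((values >= t) == labels)
        if acc > best_acc or (acc == best_acc and t > best_t):
            best_t, best_acc = float(t), float(acc)
    return best_t


class TestAmpCalibration:
    def test_separated_example_midpoint(self):
        cutoff = calibrate_amp_cutoff([2.1, 2.5, 3.0, 0.2, 0.4, 1.0], [1, 1, 1, 0, 0, 0])
        assert cutoff == pytest.approx(1.55)

    def test_perfect_separation_accuracy_one(self):
        x = np.array([0.1, 0.3, 2.5, 3.1])
        y = np.array([0, 0, 1, 1])
        t = calibrate_amp_cutoff(x, y)
        assert np.mean((x >= t) == y.astype(bool)) == 1.0

    def test_interleaved_labels_majority_accuracy(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        y = np.array([1, 0, 1, 0, 1, 0])
        t = calibrate_amp_cutoff(x, y)
        acc = np.mean((x >= t) == y.astype(bool))
        assert acc == pytest.approx(0.5)  # majority-class fraction

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            x = np.round(rng.normal(y * 1.5, 0.8), 3)
            if y.all() or not y.any() or len(np.unique(x)) < 2:
                continue
            assert calibrate_amp_cutoff(x, y) == amp_cutoff_oracle(x, y)

    def test_single_class_rejected(self):
        with pytest.raises(CallingError):
            calibrate_amp_cutoff([1.0, 2.0], [1, 1])


class TestMycn:
    def test_amplified_segment_over_locus(self, genes):
        segs = make_segments([("2", 15_000_000, 17_000_000, 8, 3.1, "amplification")])
        assert mycn_call(segs, default_platform_model("agilent_acgh"), genes) == "amplified"

    def test_high_gain_below_cutoff_nonamplified(self, genes):
        segs = make_segments([("2", 15_000_000, 17_000_000, 8, 1.2, "gain")])
        assert mycn_call(segs, default_platform_model("agilent_acgh"), genes) == "nonamplified"
        # the same value on Illumina (cutoff 0.7) is amplified
        assert mycn_call(segs, default_platform_model("illumina_snp"), genes) == "amplified"

    def test_no_coverage_unknown(self, genes):
        segs = make_segments([("1", 0, 1_000_000, 5, 0.0, "normal")])
        assert mycn_call(segs, default_platform_model("agilent_acgh"), genes) == "unknown"

    def test_concordance_counts(self, genes):
        import pandas as pd

        segs = []
        ann = []
        for i, (log2, status) in enumerate(
            [(3.0, "amplified"), (0.0, "nonamplified"), (0.0, "amplified")]  # third is discordant
        ):
            segs.append(make_segments([("2", 15_000_000, 17_000_000, 8, log2, "")], sample_id=f"s{i}"))
            ann.append({"sample_id": f"s{i}", "platform": "agilent_acgh", "mycn_status": status})
        res = mycn_concordance(pd.concat(segs, ignore_index=True), pd.DataFrame(ann), genes)
        assert res.concordance.iloc[0] == pytest.approx(2 / 3)
        assert res.n_evaluated.iloc[0] == 3
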