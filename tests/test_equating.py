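"""Crosswalk contract, mean/sigma linking, and true-score equating."""

import numpy as np
import pytest

from traumameta.equating import (
    Crosswalk,
    CrosswalkRangeError,
    apply_link,
    build_crosswalk,
    equate_score,
    invert_crosswalk_threshold,
    mean_sigma_link,
)
from traumameta.grm import GRMParameters, fit_grm
from traumameta.grm import test_characteristic_curve as tcc_curve
from traumameta.synth import default_item_bank, generate_item_responses


class TestReferenceCrosswalk:
    def test_key_scores(self, reference_crosswalk):
        assert equate_score(reference_crosswalk, 0) == 0
        assert equate_score(reference_crosswalk, 13) == 20
        assert equate_score(reference_crosswalk, 21) == 63

    def test_monotone_over_full_range(self, reference_crosswalk):
        vals = [equate_score(reference_crosswalk, s) for s in range(22)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert min(vals) >= 0 and max(vals) <= 63

    def test_probable_depression_threshold_inversion(self, reference_crosswalk):
        assert invert_crosswalk_threshold(reference_crosswalk, 20) == 13

    def test_out_of_range_lookup(self, reference_crosswalk):
        with pytest.raises(CrosswalkRangeError):
            equate_score(reference_crosswalk, 22)

    def test_gapped_or_decreasing_tables_rejected(self):
        with pytest.raises(ValueError):
            Crosswalk("a", "b", {0: 0, 2: 3})
        with pytest.raises(ValueError):
            Crosswalk("a", "b", {0: 5, 1: 3})


@pytest.fixture(scope="module")
def anchor_bank():
    return default_item_bank()["ANCHOR"]


class TestMeanSigmaLinking:
    def test_self_link_is_identity(self, anchor_bank):
        lc = mean_sigma_link(anchor_bank, anchor_bank)
        assert lc.A == pytest.approx(1.0, abs=1e-12)
        assert lc.B == pytest.approx(0.0, abs=1e-12)

    def test_analytically_forced_transform_recovered_exactly(self, anchor_bank):
        # target calibration constructed as b_t = (b - 0.4) / 1.3: the
        # mean/sigma constants must invert it (A = 1.3, |B| = 0.4)
        target = GRMParameters(
            labels=list(anchor_bank.labels),
            discriminations=anchor_bank.discriminations * 1.3,
            thresholds=[(b - 0.4) / 1.3 for b in anchor_bank.thresholds],
            anchor=anchor_bank.anchor,
        )
        lc = mean_sigma_link(anchor_bank, target)
        assert lc.A == pytest.approx(1.3, abs=1e-10)
        assert abs(lc.B) == pytest.approx(0.4, abs=1e-10)
        # applying the link must reproduce the base thresholds
        linked = apply_link(target, lc)
        for b_base, b_got in zip(anchor_bank.thresholds, linked.thresholds):
            assert np.allclose(b_base, b_got, atol=1e-9)

    def test_simulated_offset_population_recovery(self, anchor_bank):
        # one population measured twice; second calibration sees theta+0.5
        n = 5000
        rng = np.random.default_rng(3)
        theta = rng.standard_normal(n)
        resp_base = generate_item_responses(theta, anchor_bank, seed=10)
        resp_target = generate_item_responses(theta + 0.5, anchor_bank, seed=11)
        base, _ = fit_grm(resp_base, labels=anchor_bank.labels, max_iter=300)
        target, _ = fit_grm(resp_target, labels=anchor_bank.labels, max_iter=300)
        lc = mean_sigma_link(base, target)
        assert lc.A == pytest.approx(1.0, abs=0.1)
        assert lc.B == pytest.approx(0.5, abs=0.1)

    def test_degenerate_anchor_set_rejected(self):
        flat = GRMParameters(
            labels=["x"], discriminations=np.array([1.0]), thresholds=[np.array([0.2])]
        )
        with pytest.raises(ValueError):
            mean_sigma_link(flat, flat)


@pytest.fixture(scope="module")
def banks():
    bank = default_item_bank()
    return bank["BDI"], bank["HADS"]


class TestTrueScoreEquating:

    def test_endpoints_pinned(self, banks):
        bdi, hads = banks
        xw = build_crosswalk(bdi, hads)
        assert xw.table[0] == 0
        assert xw.table[21] == 63
        assert sorted(xw.table) == list(range(22))

    def test_equated_scores_monotone(self, banks):
        bdi, hads = banks
        xw = build_crosswalk(bdi, hads)
        vals = [xw.table[s] for s in range(22)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_matches_equipercentile_oracle_on_simulated_thetas(self):
        # independent oracle: simulate one latent sample, observe both total
        # scores, and match quantile ranks (equipercentile equating).  Uses
        # two equal-length instruments: true-score and equipercentile
        # equating coincide only when measurement reliabilities are
        # comparable, which a 7-item and a 21-item scale are not.
        def make(n_items, mean, seed):
            r = np.random.default_rng(seed)
            return GRMParameters(
                labels=[f"q{seed}_{j}" for j in range(n_items)],
                discriminations=np.exp(r.normal(0.45, 0.25, n_items)),
                thresholds=[np.sort(r.normal(mean, 1.2, 3)) for _ in range(n_items)],
            )

        base = make(21, 2.0, seed=1)
        target = make(21, 2.4, seed=2)
        xw = build_crosswalk(base, target, "T", "B")
        rng = np.random.default_rng(0)
        theta = rng.standard_normal(50000)
        base_tot = generate_item_responses(theta, base, seed=1).sum(axis=1)
        targ_tot = generate_item_responses(theta, target, seed=2).sum(axis=1)
        base_sorted = np.sort(base_tot)
        for s in range(8, 50):  # mid-range scores; tails regress to the mean
            # continuized percentile rank (half weight at the score itself)
            p = (targ_tot < s).mean() + 0.5 * (targ_tot == s).mean()
            oracle = base_sorted[min(int(p * 50000), 49999)]
            assert abs(xw.table[s] - oracle) <= 2, f"score {s}: {xw.table[s]} vs {oracle}"

    def test_round_trip_stability(self, banks):
        bdi, hads = banks
        fwd = build_crosswalk(bdi, hads)
        back = build_crosswalk(hads, bdi, source_instrument="BDI", target_instrument="HADS")
        for s in range(22):
            assert abs(back.table[fwd.table[s]] - s) <= 2


class TestEndToEndEquating:
    def test_threshold_agreement_with_true_latent_rule(self):
        """A crosswalk fit from item data measured on one latent trait must
        classify probable depression nearly identically to the true-theta rule."""
        bank = default_item_bank()
        bdi, hads, anchors = bank["BDI"], bank["HADS"], bank["ANCHOR"]
        n = 3000
        rng = np.random.default_rng(21)
        theta = rng.standard_normal(n)
        anchor_resp = generate_item_responses(theta, anchors, seed=31)

        bdi_resp = generate_item_responses(theta, bdi, seed=32)
        hads_resp = generate_item_responses(theta, hads, seed=33)
        fit_bdi, _ = fit_grm(
            np.column_stack([bdi_resp, anchor_resp]),
            labels=bdi.labels + anchors.labels,
            max_iter=150,
        )
        fit_hads, _ = fit_grm(
            np.column_stack([hads_resp, anchor_resp]),
            labels=hads.labels + anchors.labels,
            max_iter=150,
        )
        lc = mean_sigma_link(
            fit_bdi.subset(anchors.labels), fit_hads.subset(anchors.labels)
        )
        linked = apply_link(fit_hads, lc)
        xw = build_crosswalk(fit_bdi.subset(bdi.labels), linked.subset(hads.labels))

        hads_tot = hads_resp.sum(axis=1)
        s_star = min((s for s in range(22) if xw.table[s] >= 20), default=None)
        assert s_star is not None
        # true-theta rule: theta above the TCC-inverse of BDI 20
        tcc = tcc_curve(fit_bdi.subset(bdi.labels), np.linspace(-4, 4, 801))
        theta_cut = np.linspace(-4, 4, 801)[np.searchsorted(tcc, 20.0)]
        agree = ((hads_tot >= s_star) == (theta >= theta_cut)).mean()
        assert agree >= 0.90
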