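"""Cycle segmentation, adhesion estimates and grid assembly."""

import math

import numpy as np
import pytest

from ringtex.extraction import (
    CycleSegments,
    ForceTrace,
    adhesion_minimum,
    extract_features,
    process_grid,
    restored_adhesion_fit,
    segment_cycle,
    viscoelastic_adhesion,
)
from ringtex.synthetic import ContactScenario, generate_force_curve


def truth_segments(trace):
    """Segments straight from generator ground truth (oracle side)."""
    t = trace.meta["truth"]
    n = trace.force_nN.size
    seg = CycleSegments(
        baseline=slice(0, t["i_contact"]),
        loading=slice(t["i_contact"], t["i_max"] + 1),
        retract=slice(t["i_max"] + 1, t["i_detach"] + 1),
        ringing=slice(t["i_detach"] + 1, n),
        detachment_index=t["i_detach"],
        baseline_force=0.0,
        noise_sd=0.0,
    )
    return seg


class TestSegmentation:
    def test_boundaries_match_truth_within_two_samples(self, ring_config):
        tr = generate_force_curve(ring_config, ContactScenario(), seed=0)
        seg = segment_cycle(tr)
        t = tr.meta["truth"]
        assert abs(seg.loading.start - t["i_contact"]) <= 2
        assert abs((seg.loading.stop - 1) - t["i_max"]) <= 2
        assert abs(seg.detachment_index - t["i_detach"]) <= 2

    def test_pure_baseline_flags_no_contact(self):
        tr = ForceTrace(time_s=np.arange(4000) / 2e6, force_nN=np.zeros(4000))
        seg = segment_cycle(tr)
        assert seg.no_contact
        assert math.isnan(adhesion_minimum(tr, seg))

    def test_zero_adhesion_cycle_has_empty_ringing(self, ring_config):
        tr = generate_force_curve(
            ring_config,
            ContactScenario(adhesion_force_nN=0.0, restored_force_nN=0.0),
            seed=0,
        )
        seg = segment_cycle(tr)
        assert seg.ringing.start >= seg.ringing.stop
        assert adhesion_minimum(tr, seg) == pytest.approx(0.0, abs=1e-9)


class TestAdhesionMinimum:
    def test_noiseless_exact(self, ring_config):
        tr = generate_force_curve(ring_config, ContactScenario(), seed=0)
        assert adhesion_minimum(tr) == pytest.approx(2.0, abs=1e-9)

    def test_noise_biases_single_point_estimate_high(self, ring_config):
        ests = []
        for seed in range(50):
            tr = generate_force_curve(
                ring_config, ContactScenario(noise_sd_nN=0.1), seed=seed
            )
            ests.append(adhesion_minimum(tr))
        bias = np.mean(ests) - 2.0
        assert 0.05 < bias < 0.6  # biased high, on the order of the noise sd


class TestRestoredAdhesion:
    def test_noiseless_within_one_percent(self, ring_config):
        tr = generate_force_curve(ring_config, ContactScenario(), seed=0)
        restored, resid, unreliable = restored_adhesion_fit(tr, ring_config)
        assert not unreliable
        assert restored == pytest.approx(1.5, rel=0.01)

    def test_multi_point_fit_beats_single_point_minimum(self, ring_config):
        err_fit, err_min = [], []
        for seed in range(40):
            tr = generate_force_curve(
                ring_config, ContactScenario(noise_sd_nN=0.1), seed=seed
            )
            feats = extract_features(tr, ring_config)
            if math.isnan(feats.restored_adhesion):
                continue
            err_fit.append(abs(feats.restored_adhesion - 1.5))
            err_min.append(abs(feats.adhesion - 2.0))
        assert len(err_fit) >= 35
        assert np.mean(err_fit) < np.mean(err_min)

    def test_single_period_flagged_unreliable(self, ring_config):
        tr = generate_force_curve(
            ring_config, ContactScenario(), seed=0, n_ring_periods=1.0
        )
        _, _, unreliable = restored_adhesion_fit(tr, ring_config, truth_segments(tr))
        assert unreliable

    def test_error_decreases_with_segment_length(self, ring_config):
        """Averaging over more ringing samples reduces the estimator error."""
        rmse = []
        for periods in (4.0, 16.0, 64.0):
            errs = []
            for seed in range(25):
                tr = generate_force_curve(
                    ring_config,
                    ContactScenario(noise_sd_nN=0.1),
                    seed=seed,
                    n_ring_periods=periods,
                )
                restored, _, _ = restored_adhesion_fit(
                    tr, ring_config, truth_segments(tr)
                )
                if math.isfinite(restored):
                    errs.append((restored - 1.5) ** 2)
            rmse.append(math.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_fit_invariant_to_time_origin_shift(self, ring_config):
        tr = generate_force_curve(
            ring_config, ContactScenario(noise_sd_nN=0.05), seed=3
        )
        shifted = ForceTrace(
            time_s=tr.time_s + 1.25, force_nN=tr.force_nN.copy(), meta=tr.meta
        )
        a, _, _ = restored_adhesion_fit(tr, ring_config)
        b, _, _ = restored_adhesion_fit(shifted, ring_config)
        assert a == pytest.approx(b, rel=1e-6)


class TestViscoelastic:
    def test_difference_and_identity(self, ring_config):
        assert viscoelastic_adhesion(2.0, 1.5) == (0.5, False)
        assert viscoelastic_adhesion(1.5, 1.5) == (0.0, False)

    def test_clamped_when_fit_overshoots(self):
        value, clamped = viscoelastic_adhesion(2.0, 2.05)
        assert value == 0.0 and clamped

    def test_identity_holds_preclamp_on_noiseless_grid(self, ring_config):
        for seed, (fa, fr) in enumerate([(2.0, 1.5), (1.0, 0.2), (3.0, 3.0)]):
            tr = generate_force_curve(
                ring_config,
                ContactScenario(adhesion_force_nN=fa, restored_force_nN=fr),
                seed=seed,
            )
            f = extract_features(tr, ring_config)
            # identity pre-clamp; the clamp only engages on tiny overshoots
            expected = max(f.adhesion - f.restored_adhesion, 0.0)
            assert f.viscoelastic_adhesion == pytest.approx(expected, abs=1e-6)
            assert f.adhesion - f.restored_adhesion == pytest.approx(
                fa - fr, abs=0.05
            )


class TestProcessGrid:
    def _grid(self, ring_config, n=8, noise=0.0):
        out = []
        for i in range(n):
            row = []
            for j in range(n):
                adh = 1.5 + 0.5 * math.sin(2 * math.pi * i / n)
                sc = ContactScenario(
                    adhesion_force_nN=adh,
                    restored_force_nN=0.75 * adh,
                    noise_sd_nN=noise,
                )
                tr = generate_force_curve(ring_config, sc, seed=i * n + j)
                tr.meta["height_nm"] = float(i)
                row.append(tr)
            out.append(row)
        return out

    def test_noiseless_grid_recovers_pattern(self, ring_config):
        grid = self._grid(ring_config)
        maps, qc = process_grid(grid, ring_config)
        n = len(grid)
        truth = np.array(
            [[0.75 * (1.5 + 0.5 * math.sin(2 * math.pi * i / n))] * n for i in range(n)]
        )
        assert not qc.any()
        assert np.allclose(maps["restored adhesion"].values, truth, rtol=0.01)
        assert np.allclose(maps["height"].values, np.arange(n)[:, None] * np.ones(n))

    def test_all_baseline_grid_fully_flagged(self, ring_config):
        flat = [
            [ForceTrace(time_s=np.arange(2000) / 2e6, force_nN=np.zeros(2000))
             for _ in range(4)]
            for _ in range(4)
        ]
        _, qc = process_grid(flat, ring_config)
        assert qc.all()

    def test_bad_pixel_median_filled_and_flagged(self, ring_config):
        grid = self._grid(ring_config, n=4)
        grid[1][2] = ForceTrace(time_s=np.arange(2000) / 2e6, force_nN=np.zeros(2000))
        maps, qc = process_grid(grid, ring_config)
        assert qc[1, 2] and qc.sum() == 1
        neighbours = [
            maps["restored adhesion"].values[i, j]
            for i, j in ((0, 2), (2, 2), (1, 1), (1, 3))
        ]
        assert maps["restored adhesion"].values[1, 2] == pytest.approx(
            np.median(neighbours)
        )

    def test_ragged_grid_rejected(self, ring_config):
        grid = self._grid(ring_config, n=4)
        grid[2] = grid[2][:-1]
        with pytest.raises(ValueError, match="rectangular"):
            process_grid(grid, ring_config)
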