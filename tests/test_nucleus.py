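"""Nucleus segmentation, compaction classification, signal mapping, morphometry."""

import numpy as np
import pytest

from chromotion import (
    SimulationConfig,
    TextureParams,
    Trajectory,
    assign_track_class,
    classify_seven_class,
    classify_two_class,
    compute_msd,
    map_signal_fractions,
    nuclear_morphometry,
    segment_nucleus,
    simulate_nucleus,
    simulate_trajectories,
)
from chromotion.nucleus import CompactionMap, NucleusMask


def _ball_mask(radius_um=2.0, voxel=0.1, pad=4):
    n = int(2 * radius_um / voxel) + 2 * pad
    grid = (np.indices((n, n, n)).T * voxel).T
    center = (n - 1) / 2 * voxel
    mask = np.linalg.norm(grid - center, axis=0) <= radius_um
    return NucleusMask(mask=mask, voxel_size=(voxel,) * 3)


class TestSegmentNucleus:
    def test_dice_against_truth(self):
        samp = simulate_nucleus((32, 64, 64), (0.15, 0.1, 0.1),
                                TextureParams(means=(100.0, 300.0),
                                              sds=(20.0, 20.0)), seed=3)
        rng = np.random.default_rng(0)
        noisy = samp.dna + rng.normal(0, 10, samp.dna.shape)
        seg = segment_nucleus(noisy, (0.15, 0.1, 0.1))
        truth = samp.mask.mask
        dice = 2 * (seg.mask & truth).sum() / (seg.mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_all_background_raises(self):
        with pytest.raises(ValueError):
            segment_nucleus(np.zeros((8, 32, 32)), (0.2, 0.1, 0.1))

    def test_intensity_scale_invariance(self, nucleus_sample):
        rng = np.random.default_rng(1)
        vol = nucleus_sample.dna + rng.normal(0, 5, nucleus_sample.dna.shape)
        a = segment_nucleus(vol, (0.2, 0.1, 0.1))
        b = segment_nucleus(vol * 10.0, (0.2, 0.1, 0.1))
        assert np.array_equal(a.mask, b.mask)


class TestTwoClass:
    def test_misclassification_below_one_percent(self, nucleus_sample):
        cmap = classify_two_class(nucleus_sample.dna, nucleus_sample.mask, seed=0)
        inside = nucleus_sample.labels > 0
        err = (cmap.labels[inside] != nucleus_sample.labels[inside]).mean()
        assert err < 0.01
        assert cmap.class_means[0] < cmap.class_means[1]

    def test_unimodal_falls_back_to_otsu(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(100.0, 1e-3, size=(8, 24, 24))
        mask = np.ones(vol.shape, bool)
        cmap = classify_two_class(vol, mask, seed=0)
        assert cmap.fallback

    def test_seed_determinism(self, nucleus_sample):
        a = classify_two_class(nucleus_sample.dna, nucleus_sample.mask, seed=5)
        b = classify_two_class(nucleus_sample.dna, nucleus_sample.mask, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestSevenClass:
    def _plateaus(self, noise_sd=5.0, seed=4):
        """Piecewise-constant nucleus with 7 known intensity plateaus."""
        rng = np.random.default_rng(seed)
        shape = (8, 56, 56)
        labels = np.zeros(shape, dtype=int)
        vol = np.zeros(shape)
        mask = np.zeros(shape, bool)
        mask[1:-1, 4:-4, 4:-4] = True
        xs = np.linspace(4, 52, 8).astype(int)
        for k in range(7):
            sel = np.zeros(shape, bool)
            sel[1:-1, 4:-4, xs[k]:xs[k + 1]] = True
            labels[sel] = k + 1
            vol[sel] = 100.0 + 60.0 * k
        vol += rng.normal(0, noise_sd, shape)
        return vol, mask, labels

    def test_beta_zero_equals_ml_assignment(self, nucleus_sample):
        cmap = classify_seven_class(nucleus_sample.dna, nucleus_sample.mask, beta=0.0)
        vol = nucleus_sample.dna
        unary = np.stack([
            (vol - mu) ** 2 / (2 * sd ** 2) + np.log(sd)
            for mu, sd in zip(cmap.class_means, cmap.class_sds)
        ])
        ml = np.argmin(unary, axis=0) + 1
        inside = nucleus_sample.mask.mask
        assert np.array_equal(cmap.labels[inside], ml[inside])

    def test_plateau_accuracy_with_spatial_prior(self):
        vol, mask, truth = self._plateaus()
        cmap = classify_seven_class(vol, mask, beta=0.5)
        for k in range(1, 8):
            sel = truth == k
            assert (cmap.labels[sel] == k).mean() >= 0.95

    def test_class_means_strictly_increasing(self, nucleus_sample):
        for beta in (0.0, 0.5):
            cmap = classify_seven_class(nucleus_sample.dna, nucleus_sample.mask,
                                        beta=beta)
            assert np.all(np.diff(cmap.class_means) > 0)

    def test_outside_mask_is_zero(self, nucleus_sample):
        cmap = classify_seven_class(nucleus_sample.dna, nucleus_sample.mask, beta=0.3)
        assert np.all(cmap.labels[~nucleus_sample.mask.mask] == 0)


def _map_from_labels(labels, n_classes=2):
    means = np.arange(1, n_classes + 1, dtype=float)
    return CompactionMap(labels=labels, n_classes=n_classes, class_means=means,
                         class_sds=np.ones(n_classes))


class TestAssignTrackClass:
    VS = (0.2, 0.1, 0.1)

    def _track(self, positions):
        pos = np.atleast_2d(positions)
        return Trajectory(id=0, frames=np.arange(len(pos)), positions=pos,
                          sizes=np.ones(len(pos)))

    def test_majority_wins(self):
        labels = np.ones((4, 10, 10), dtype=np.uint8)
        labels[:, :, 5:] = 2
        cmap = _map_from_labels(labels)
        pos = np.array([[0.4, 0.5, 0.8]] * 7 + [[0.4, 0.5, 0.2]] * 3)
        assert assign_track_class(self._track(pos), cmap, self.VS) == "heterochromatin"

    def test_exact_tie_unassigned(self):
        labels = np.ones((4, 10, 10), dtype=np.uint8)
        labels[:, :, 5:] = 2
        cmap = _map_from_labels(labels)
        pos = np.array([[0.4, 0.5, 0.8]] * 5 + [[0.4, 0.5, 0.2]] * 5)
        assert assign_track_class(self._track(pos), cmap, self.VS) == "unassigned"

    def test_all_points_outside_unassigned(self):
        labels = np.zeros((4, 10, 10), dtype=np.uint8)
        cmap = _map_from_labels(labels)
        pos = np.array([[0.4, 0.5, 0.5]] * 4)
        assert assign_track_class(self._track(pos), cmap, self.VS) == "unassigned"

    def test_blob_seeded_tracks_assigned_correctly(self, nucleus_sample):
        cmap = classify_two_class(nucleus_sample.dna, nucleus_sample.mask, seed=0)
        rng = np.random.default_rng(7)
        vs = np.array(self.VS)
        correct = total = 0
        for target in (1, 2):
            vox = np.argwhere(nucleus_sample.labels == target)
            for idx in vox[rng.choice(len(vox), 25, replace=False)]:
                center = idx * vs
                pos = center + rng.normal(0, 0.02, size=(8, 3))  # tight wiggle
                name = assign_track_class(self._track(pos), cmap, self.VS)
                total += 1
                expect = "euchromatin" if target == 1 else "heterochromatin"
                correct += name == expect
        assert correct / total >= 0.9


class TestSignalFractions:
    def _cmap7(self):
        labels = np.zeros((4, 10, 10), dtype=np.uint8)
        for k in range(1, 8):
            labels[:, :, k - 1] = k
        return _map_from_labels(labels, n_classes=7)

    def test_point_mass_in_one_class(self):
        cmap = self._cmap7()
        sig = np.zeros((4, 10, 10))
        sig[cmap.labels == 3] = 50.0
        frac, flagged = map_signal_fractions(sig, cmap)
        assert not flagged
        assert np.allclose(frac, np.eye(7)[2])

    def test_fractions_sum_to_one(self, nucleus_sample):
        cmap = classify_seven_class(nucleus_sample.dna, nucleus_sample.mask, beta=0.0)
        rng = np.random.default_rng(3)
        sig = rng.uniform(0, 100, nucleus_sample.dna.shape)
        frac, flagged = map_signal_fractions(sig, cmap)
        assert flagged or frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_signal_gives_volume_shares(self):
        cmap = self._cmap7()
        sig = np.zeros((4, 10, 10))
        sig[cmap.labels > 0] = 100.0  # uniform signal: every voxel is signal
        frac, _ = map_signal_fractions(sig, cmap)
        shares = np.array([(cmap.labels == k).sum() for k in range(1, 8)], float)
        shares /= shares.sum()
        assert np.allclose(frac, shares, atol=0.01)

    def test_intensity_doubling_invariance(self, nucleus_sample):
        cmap = classify_two_class(nucleus_sample.dna, nucleus_sample.mask, seed=0)
        rng = np.random.default_rng(5)
        sig = rng.uniform(0, 100, nucleus_sample.dna.shape)
        f1, _ = map_signal_fractions(sig, cmap)
        f2, _ = map_signal_fractions(2.0 * sig, cmap)
        assert np.allclose(f1, f2)


class TestMorphometry:
    def test_ball_volume_and_sphericity(self):
        mask = _ball_mask(radius_um=2.0, voxel=0.1)
        m = nuclear_morphometry(mask, np.ones(mask.mask.shape))
        assert m.volume_um3 == pytest.approx(4 / 3 * np.pi * 8.0, rel=0.03)
        assert m.shape_factor >= 0.95

    def test_intensity_shift_identities(self, nucleus_sample):
        mask = nucleus_sample.mask
        a = nuclear_morphometry(mask, nucleus_sample.dna)
        b = nuclear_morphometry(mask, nucleus_sample.dna + 10.0)
        n = mask.mask.sum()
        assert b.std_intensity == pytest.approx(a.std_intensity, rel=1e-9)
        assert b.sum_intensity == pytest.approx(a.sum_intensity + 10.0 * n, rel=1e-9)

    def test_elongated_ellipsoid_less_spherical(self):
        ball_mask = _ball_mask(1.5, 0.1)
        ball = nuclear_morphometry(ball_mask, np.ones(ball_mask.mask.shape))
        samp = simulate_nucleus((64, 24, 24), (0.1, 0.1, 0.1),
                                TextureParams(semi_axes_um=(3.0, 0.75, 0.75)), seed=0)
        ell = nuclear_morphometry(samp.mask, samp.dna)
        assert ell.shape_factor < ball.shape_factor


class TestMobilityByCompartment:
    def test_heterochromatin_msd_below_euchromatin(self, nucleus_sample):
        """Foci simulated with lower D inside high-intensity (heterochromatin)
        blobs must produce the lower ensemble MSD curve after class
        assignment — the compaction-dependent mobility ordering."""
        cmap = classify_two_class(nucleus_sample.dna, nucleus_sample.mask, seed=0)
        rng = np.random.default_rng(11)
        vs = np.array((0.2, 0.1, 0.1))
        groups = {}
        for name, target, d in [("euchromatin", 1, 3e-4), ("heterochromatin", 2, 5e-5)]:
            cfg = SimulationConfig(n_foci=60, n_frames=40, D=d, loc_noise_sigma=0.01,
                                   seed=int(rng.integers(1 << 30)), noise=False)
            vox = np.argwhere(nucleus_sample.labels == target)
            starts = vox[rng.choice(len(vox), 60, replace=False)] * vs
            truth = simulate_trajectories(cfg, None)
            offsets = truth.observed_positions - truth.observed_positions[:, :1, :]
            pos = starts[:, None, :] + offsets
            tracks = [
                Trajectory(id=i, frames=np.arange(40), positions=pos[i],
                           sizes=np.full(40, 0.1))
                for i in range(60)
            ]
            labels = [assign_track_class(tr, cmap, tuple(vs)) for tr in tracks]
            kept = [tr for tr, lab in zip(tracks, labels) if lab == name]
            assert len(kept) >= 30  # most tracks stay in their compartment
            groups[name] = compute_msd(kept, 5.0, max_lag=50.0)
        assert np.all(groups["heterochromatin"].msd < groups["euchromatin"].msd)
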