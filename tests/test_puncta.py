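import numpy as np
import pandas as pd
import pytest
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from arborsim.geometry import GeometryError
from arborsim.puncta import (
    NormalizationError,
    colocalize,
    detect_puncta,
    measure,
    normalize_intensities,
)
from arborsim.segmentation import NeuronMask
from arborsim.volume import VolumeImage

VS = (1.0, 0.25, 0.25)


def puncta_stack(centers_um, amplitudes, shape=(9, 120, 120), noise_sd=20.0,
                 offset=100.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.float32)
    for c, a in zip(centers_um, amplitudes):
        vox = np.round(np.asarray(c) / np.array(VS)).astype(int)
        img[tuple(vox)] = a * 8.0  # delta; blur spreads it below
    img = ndi.gaussian_filter(img, sigma=(0.5, 1, 1))
    img = img + offset + rng.normal(0, noise_sd, shape)
    return VolumeImage(np.clip(img, 0, 65535).astype(np.uint16), VS, "VGlut1")


class TestDetect:
    def test_noise_only_stack_detects_nothing(self):
        img = puncta_stack([], [], seed=1)
        assert len(detect_puncta(img)) == 0

    def test_single_gaussian_gives_exactly_one_mask(self):
        img = puncta_stack([(4, 15, 15)], [3000.0], noise_sd=10.0)
        ps = detect_puncta(img)
        assert len(ps) == 1

    def test_pair_separated_1p5_um_stays_split(self):
        img = puncta_stack([(4, 15, 15), (4, 15, 16.5)], [3000.0, 3000.0],
                           noise_sd=10.0)
        assert len(detect_puncta(img)) == 2

    def test_pair_separated_3px_stays_split(self):
        img = puncta_stack([(4, 20, 20), (4, 20, 20.75)], [3000.0, 3000.0],
                           noise_sd=5.0)
        assert len(detect_puncta(img)) == 2

    def test_recall_and_precision_on_50_random_punctae(self):
        rng = np.random.default_rng(4)
        centers = []
        while len(centers) < 50:
            c = (rng.uniform(2, 6), rng.uniform(4, 70), rng.uniform(4, 70))
            if all(np.linalg.norm(np.subtract(c, o)) > 2.5 for o in centers):
                centers.append(c)
        img = puncta_stack(centers, rng.uniform(2000, 5000, 50), noise_sd=15.0,
                           shape=(9, 300, 300))
        ps = detect_puncta(img)
        det = ps.table[["z_um", "y_um", "x_um"]].to_numpy()
        tru = np.asarray(centers)
        recall = (cKDTree(det).query(tru)[0] <= 0.5).mean()
        precision = (cKDTree(tru).query(det)[0] <= 0.5).mean()
        assert recall >= 0.9
        assert precision >= 0.9

    def test_offset_invariance_and_gain_stability(self):
        rng = np.random.default_rng(5)
        centers = [(4, 5 + 6 * i, 5 + 5 * j) for i in range(4) for j in range(4)]
        img = puncta_stack(centers, rng.uniform(2000, 4000, 16), noise_sd=15.0)
        n0 = len(detect_puncta(img))
        shifted = VolumeImage(
            (img.voxels.astype(np.int64) + 900).astype(np.uint16), VS
        )
        assert len(detect_puncta(shifted)) == n0
        doubled = VolumeImage(
            np.clip(img.voxels.astype(np.int64) * 2, 0, 65535).astype(np.uint16),
            VS,
        )
        assert abs(len(detect_puncta(doubled)) - n0) <= max(1, 0.05 * n0)


class TestColocalize:
    def _setup(self):
        img = puncta_stack([(4, 10, 10), (4, 20, 20)], [3000.0, 3000.0],
                           noise_sd=5.0)
        ps = detect_puncta(img)
        assert len(ps) == 2
        return ps

    def test_one_voxel_overlap_suffices(self):
        ps = self._setup()
        ps.table = ps.table.sort_values("y_um").reset_index(drop=True)
        mask = np.zeros(ps.labels.shape, dtype=bool)
        first = ps.table.iloc[0]
        vox_of_first = np.argwhere(ps.labels == first["id"])
        mask[tuple(vox_of_first[0])] = True  # exactly one shared voxel
        colocalize(ps, NeuronMask(mask, VS))
        by_id = ps.table.set_index("id")["colocalized"]
        assert by_id[first["id"]]
        assert not by_id.drop(first["id"]).any()

    def test_idempotent_and_monotone_in_mask(self):
        ps = self._setup()
        small = np.zeros(ps.labels.shape, dtype=bool)
        small[3:6, 35:45, 35:45] = True
        colocalize(ps, NeuronMask(small, VS))
        flags1 = ps.table["colocalized"].copy()
        colocalize(ps, NeuronMask(small, VS))
        pd.testing.assert_series_equal(flags1, ps.table["colocalized"])
        big = small | np.ones_like(small)
        colocalize(ps, NeuronMask(big, VS))
        assert (ps.table["colocalized"] >= flags1).all()

    def test_grid_mismatch_rejected(self):
        ps = self._setup()
        with pytest.raises(GeometryError):
            colocalize(ps, NeuronMask(np.zeros((2, 2, 2), bool), VS))


class TestMeasure:
    def test_uniform_punctum_mean_and_distance(self):
        labels = np.zeros((5, 20, 20), dtype=np.int32)
        labels[2, 5:8, 5] = 1
        from arborsim.puncta import PunctaSet

        ps = PunctaSet(
            labels=labels,
            table=pd.DataFrame({"id": [1], "channel": "VGlut1",
                                "n_voxels": [3], "z_um": [2.0],
                                "y_um": [1.5], "x_um": [1.25]}),
            voxel_size=VS,
        )
        raw = VolumeImage(np.full((5, 20, 20), 1000, dtype=np.uint16), VS)
        dmap = np.zeros((5, 20, 20), dtype=np.float32)
        dmap[2, 5:8, 5] = [10.0, 10.5, 11.0]
        measure(ps, raw, dmap)
        assert ps.table["raw_mean"].iloc[0] == pytest.approx(1000.0)
        assert ps.table["dist_um"].iloc[0] == pytest.approx(10.5)

    def test_phantom_distance_within_punctum_radius(self, simple_phantom):
        spec, vols, truth = simple_phantom
        from arborsim.segmentation import distance_transform, SomaReference

        ps = detect_puncta(vols["VGlut1"])
        dmap = distance_transform(
            SomaReference(spec.soma_center_um), vols["VGlut1"].shape, VS
        )
        measure(ps, vols["VGlut1"], dmap)
        on = truth.puncta[truth.puncta["on_neuron"]].iloc[0]
        det = ps.table.iloc[
            np.argmin(
                np.abs(ps.table["y_um"] - on.y_um) + np.abs(ps.table["x_um"] - on.x_um)
            )
        ]
        assert abs(det["dist_um"] - on["dist_um"]) <= 1.0


class TestNormalize:
    def _table(self):
        return pd.DataFrame(
            {
                "neuron": ["c1", "c1", "t1", "t1"],
                "session": [0, 0, 0, 0],
                "channel": ["VGlut1"] * 4,
                "raw_mean": [900.0, 1100.0, 1500.0, 1500.0],
            }
        )

    def test_control_session_mean_is_one(self):
        out = normalize_intensities(self._table(), control_ids={"c1"})
        ctrl = out[out["neuron"] == "c1"]
        assert ctrl["afu"].mean() == pytest.approx(1.0)

    def test_ratio_preserved(self):
        out = normalize_intensities(self._table(), control_ids={"c1"})
        assert out[out["neuron"] == "t1"]["afu"].iloc[0] == pytest.approx(1.5)

    def test_session_gain_invariance(self):
        t = self._table()
        t2 = t.copy()
        t2["session"] = 1
        t2["raw_mean"] *= 3.7  # lamp drift between sessions
        out = normalize_intensities(pd.concat([t, t2], ignore_index=True),
                                    control_ids={"c1"})
        a = out[(out["session"] == 0) & (out["neuron"] == "t1")]["afu"].to_numpy()
        b = out[(out["session"] == 1) & (out["neuron"] == "t1")]["afu"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_missing_controls_raise(self):
        with pytest.raises(NormalizationError):
            normalize_intensities(self._table(), control_ids={"nope"})
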