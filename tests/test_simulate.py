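import hashlib

import numpy as np
import pytest

from paircell.core import ContractError
from paircell.simulate import (
    CellGeometry,
    Mixture,
    SyntheticSpec,
    crops_from_images,
    generate_dataset,
    generate_image,
    generate_images,
    parse_pattern,
    render_cell,
)


def _geom(center=(16.0, 16.0), radius=8.0):
    return CellGeometry(center=center, radius=radius, eccentricity=1.2, rotation=0.4)


class TestRenderCell:
    def test_mixture_endpoint_equals_pure(self):
        geom = _geom()
        s1, p1 = render_cell((32, 32), geom, "nuclear", np.random.default_rng(0))
        s2, p2 = render_cell(
            (32, 32), geom, Mixture("nuclear", "cytosolic", 1.0), np.random.default_rng(0)
        )
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)

    def test_nuclear_contrast(self):
        geom = _geom()
        _, protein = render_cell((32, 32), geom, "nuclear", np.random.default_rng(0))
        from paircell.simulate import _ellipse_mask

        nucleus = _ellipse_mask((32, 32), geom, geom.nucleus_frac) > 0.5
        inside = protein[..., 0][nucleus].mean()
        outside = protein[..., 0][~nucleus].mean()
        assert inside > 5 * max(outside, 1e-9)

    def test_deterministic_given_rng_state(self):
        geom = _geom()
        for pattern in ("nucleolar", "punctate"):
            a = render_cell((32, 32), geom, pattern, np.random.default_rng(42))
            b = render_cell((32, 32), geom, pattern, np.random.default_rng(42))
            np.testing.assert_array_equal(a[1], b[1])

    def test_unknown_class_rejected(self):
        with pytest.raises(ContractError):
            render_cell((32, 32), _geom(), "endoplasmic", np.random.default_rng(0))

    @pytest.mark.parametrize("pattern", ["nuclear", "nucleolar", "nucleolar_rim",
                                         "cytosolic", "punctate", "membrane"])
    def test_protein_confined_to_cell_body(self, pattern):
        geom = _geom()
        _, protein = render_cell((32, 32), geom, pattern, np.random.default_rng(3))
        from paircell.simulate import _ellipse_mask

        body = _ellipse_mask((32, 32), geom, 1.05) > 0
        assert protein[..., 0][~body].max() < 0.1


class TestParsePattern:
    def test_mixture_syntax(self):
        m = parse_pattern("mixture(nuclear,cytosolic,0.25)")
        assert m == Mixture("nuclear", "cytosolic", 0.25)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ContractError):
            Mixture("nuclear", "cytosolic", 1.5)


class TestGenerateImage:
    def _spec(self, **kw):
        defaults = dict(
            pattern_classes=("nuclear",),
            images_per_class=1,
            cells_per_image=(1, 1),
            field_size=(96, 96),
            seed=0,
        )
        defaults.update(kw)
        return SyntheticSpec(**defaults)

    def test_single_cell_single_center(self):
        spec = self._spec()
        img = generate_image("w", "nuclear", spec, np.random.default_rng(0))
        assert sum(len(c) for c in img.metadata["centers"]) == 1

    def test_requested_cell_count_recorded(self):
        spec = self._spec(cells_per_image=(12, 12), field_size=(512, 512))
        img = generate_image("w", "cytosolic", spec, np.random.default_rng(1))
        assert sum(len(c) for c in img.metadata["centers"]) == 12

    def test_nuisance_off_limit(self):
        # no gradient, no gain spread, no noise, no jitter: per-image variation
        # comes only from cell geometry
        spec = self._spec(
            cells_per_image=(3, 3),
            illumination_gradient=0.0,
            gain_range=(1.0, 1.0),
            noise_sd=0.0,
            cell_jitter_sd=0.0,
        )
        img = generate_image("w", "nuclear", spec, np.random.default_rng(2))
        fov = img.fields_of_view[0]
        assert np.all(fov >= 0)
        # protein only where nuclei are: sparse support
        assert np.mean(fov[..., -1] > 0.2) < 0.1

    def test_overfull_field_rejected(self):
        spec = self._spec(cells_per_image=(200, 200), field_size=(64, 64))
        with pytest.raises(ContractError, match="could not place"):
            generate_image("w", "nuclear", spec, np.random.default_rng(0))


class TestGenerateDataset:
    def test_class_image_multiplication(self, tmp_path):
        spec = SyntheticSpec(
            pattern_classes=("nuclear", "cytosolic", "membrane", "punctate"),
            images_per_class=3,
            cells_per_image=(2, 3),
            field_size=(96, 96),
            seed=5,
        )
        manifest, labels = generate_dataset(spec, tmp_path / "d")
        assert manifest.n_images == 12
        assert len(labels) == 12
        assert labels["label"].nunique() == 4

    def test_seed_reproducibility_bytes(self, tmp_path):
        spec = SyntheticSpec(
            pattern_classes=("nuclear",),
            images_per_class=2,
            cells_per_image=(2, 3),
            field_size=(96, 96),
            seed=11,
        )
        generate_dataset(spec, tmp_path / "a")
        generate_dataset(spec, tmp_path / "b")
        for p in sorted((tmp_path / "a").iterdir()):
            q = tmp_path / "b" / p.name
            ha = hashlib.sha256(p.read_bytes()).hexdigest()
            hb = hashlib.sha256(q.read_bytes()).hexdigest()
            assert ha == hb, p.name

    def test_empty_dataset_valid(self, tmp_path):
        spec = SyntheticSpec(
            pattern_classes=("nuclear",), images_per_class=0, seed=0,
            field_size=(96, 96), cells_per_image=(2, 3),
        )
        manifest, labels = generate_dataset(spec, tmp_path / "e")
        assert manifest.n_images == 0 and len(labels) == 0


@pytest.fixture(scope="module")
def small_collection():
    spec = SyntheticSpec(
        pattern_classes=("nuclear", "cytosolic", "membrane"),
        images_per_class=6,
        cells_per_image=(5, 8),
        field_size=(160, 160),
        seed=21,
    )
    images = generate_images(spec)
    crops, labels = crops_from_images(images, crop_size=32)
    return images, crops, labels


class TestStatisticalStructure:
    """The generated data must actually pose the problem the features solve."""

    def test_nuisance_intensity_spread(self, small_collection):
        # per-image mean intensity must vary >=20% within one class, so a
        # trivial intensity feature cannot win the benchmark
        images, _, _ = small_collection
        by_class = {}
        for img in images:
            by_class.setdefault(img.metadata["pattern_class"], []).append(
                float(np.mean(img.fields_of_view[0]))
            )
        for cls, means in by_class.items():
            spread = (max(means) - min(means)) / np.mean(means)
            assert spread >= 0.20, f"{cls}: spread {spread:.2f}"

    def test_within_class_correlation_exceeds_between(self, small_collection):
        # separability oracle on raw protein-channel crops
        _, crops, labels = small_collection
        vecs = {}
        for c in crops:
            vecs.setdefault(labels[c.image_id], []).append(c.pixels[..., -1].ravel())
        classes = sorted(vecs)
        within, between = [], []
        rng = np.random.default_rng(0)
        for ci in classes:
            arr = vecs[ci]
            idx = rng.choice(len(arr), size=(60, 2))
            within.extend(
                np.corrcoef(arr[i], arr[j])[0, 1] for i, j in idx if i != j
            )
            for cj in classes:
                if cj <= ci:
                    continue
                brr = vecs[cj]
                idx = rng.choice(min(len(arr), len(brr)), size=(60, 2))
                between.extend(np.corrcoef(arr[i], brr[j])[0, 1] for i, j in idx)
        assert np.mean(within) > np.mean(between)
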