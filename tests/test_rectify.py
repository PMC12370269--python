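import numpy as np
import pytest

from socketgen.aop_io import enclosed_volume
from socketgen.rectify import (
    FEATURES,
    KernelSpec,
    OverCarveError,
    RectificationSet,
    apply_rectifications,
    default_kernel_specs,
    extract_rectifications,
    kernel_field,
)
from socketgen.ssm import align
from socketgen.synthetic_limb import CANONICAL_LANDMARKS, LimbShapeParams, generate_limb


@pytest.fixture(scope="module")
def limb():
    params = LimbShapeParams(
        bump_amplitudes={name: 2.0 for name in CANONICAL_LANDMARKS},
        surface_noise=0.2,
    )
    return align(generate_limb(params, seed=11))


def narrow_specs():
    """Kernels small enough that no two features' supports overlap."""
    return {
        "patella_tendon_bar": KernelSpec("patella_tendon_bar", 10.0, 8.0),
        "paratibial": KernelSpec("paratibial", 10.0, 8.0),
        "fibula_head": KernelSpec("fibula_head", 10.0, 8.0),
        "distal_tibia": KernelSpec("distal_tibia", 10.0, 8.0),
        "anterior_tibia": KernelSpec("anterior_tibia", 10.0, 8.0),
        "supracondylar": KernelSpec("supracondylar", 10.0, 8.0),
        "distal_end": KernelSpec("distal_end", 90.0, 10.0, cap=True),
    }


class TestRectificationSet:
    def test_sign_invariants_enforced(self):
        with pytest.raises(ValueError):
            RectificationSet(patella_tendon_bar=1.0)
        with pytest.raises(ValueError):
            RectificationSet(distal_end=-1.0)
        with pytest.raises(ValueError):
            RectificationSet(volume_change=0.6)

    def test_clip_to_feasible(self):
        r = RectificationSet.clip_to_feasible([2.0, -1.0, -3.0, 4.0, 0, 0, 1.0, -0.1])
        assert r.patella_tendon_bar == 0.0  # carve clipped from +2
        assert r.paratibial == -1.0
        assert r.fibula_head == 0.0         # build clipped from -3
        assert r.distal_end == 4.0
        assert r.supracondylar == 0.0
        assert r.volume_change == -0.1

    def test_json_roundtrip(self):
        r = RectificationSet(paratibial=-2.5, fibula_head=1.0, volume_change=-0.03)
        assert RectificationSet.from_json(r.to_json()) == r


class TestKernelField:
    def test_peak_one_at_anchor(self, limb):
        spec = default_kernel_specs()["patella_tendon_bar"]
        w = kernel_field(spec, limb)
        si, ti = limb.landmarks["PATELLAR_TENDON"]
        assert w[si, ti] == pytest.approx(1.0)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_compact_support(self, limb):
        spec = KernelSpec("fibula_head", 15.0, 10.0)
        w = kernel_field(spec, limb)
        si, ti = limb.landmarks["FIBULAR_HEAD"]
        theta = limb.grid.theta_deg
        dth = np.abs((theta - theta[ti] + 180.0) % 360.0 - 180.0)
        far = dth >= 15.0
        assert np.all(w[:, far] == 0.0)
        dz = np.abs(limb.grid.slice_z - limb.grid.slice_z[si])
        assert np.all(w[dz >= 10.0, :] == 0.0)

    def test_bilateral_feature_symmetric_in_anchor_order(self, limb):
        spec = default_kernel_specs()["paratibial"]
        w = kernel_field(spec, limb)
        si_m, ti_m = limb.landmarks["PARATIBIAL_MEDIAL"]
        si_l, ti_l = limb.landmarks["PARATIBIAL_LATERAL"]
        assert w[si_m, ti_m] == pytest.approx(1.0)
        assert w[si_l, ti_l] == pytest.approx(1.0)

    def test_distal_cap_covers_all_angles(self, limb):
        spec = default_kernel_specs()["distal_end"]
        w = kernel_field(spec, limb)
        assert np.allclose(w[0], 1.0)
        z = limb.grid.slice_z
        assert np.all(w[z - z[0] >= spec.half_height_mm] == 0.0)

    def test_missing_anchor_raises(self, limb):
        bare = limb.copy()
        bare.landmarks = {}
        with pytest.raises(KeyError, match="FIBULAR_HEAD"):
            kernel_field(default_kernel_specs()["fibula_head"], bare)


class TestApply:
    def test_zero_rectifications_is_identity(self, limb):
        socket = apply_rectifications(limb, RectificationSet())
        assert np.array_equal(socket.radii, limb.radii)

    def test_volume_change_scales_enclosed_volume(self, limb):
        socket = apply_rectifications(limb, RectificationSet(volume_change=-0.10))
        ratio = enclosed_volume(socket) / enclosed_volume(limb)
        assert ratio == pytest.approx(0.90, rel=0.005)

    def test_single_carve_is_local_and_exact_at_anchor(self, limb):
        specs = default_kernel_specs()
        socket = apply_rectifications(
            limb, RectificationSet(patella_tendon_bar=-5.0), specs
        )
        si, ti = limb.landmarks["PATELLAR_TENDON"]
        assert socket.radii[si, ti] == pytest.approx(limb.radii[si, ti] - 5.0)
        outside = kernel_field(specs["patella_tendon_bar"], limb) == 0.0
        assert np.array_equal(socket.radii[outside], limb.radii[outside])

    def test_monotone_in_carve_depth(self, limb):
        shallow = apply_rectifications(limb, RectificationSet(paratibial=-2.0))
        deep = apply_rectifications(limb, RectificationSet(paratibial=-6.0))
        assert np.all(deep.radii <= shallow.radii + 1e-12)

    def test_overcarve_raises_with_location(self, limb):
        with pytest.raises(OverCarveError, match="patella_tendon_bar"):
            apply_rectifications(limb, RectificationSet(patella_tendon_bar=-80.0))


class TestExtract:
    def test_identical_surfaces_give_zero_design(self, limb):
        rects, rms = extract_rectifications(limb, limb.copy())
        assert np.array_equal(rects.as_array(), np.zeros(len(FEATURES)))
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_recovery_nonoverlapping(self, limb):
        specs = narrow_specs()
        truth = RectificationSet(
            patella_tendon_bar=-4.0, paratibial=-2.5, fibula_head=2.0,
            distal_end=3.0, distal_tibia=1.5, anterior_tibia=1.0,
            supracondylar=-2.0, volume_change=-0.06,
        )
        socket = apply_rectifications(limb, truth, specs)
        rects, rms = extract_rectifications(limb, socket, specs)
        assert np.allclose(rects.as_array(), truth.as_array(), atol=1e-6)
        assert rms < 1e-6

    def test_round_trip_default_overlapping_kernels(self, limb):
        # overlap between neighbouring footprints must stay well-conditioned
        specs = default_kernel_specs()
        truth = RectificationSet(
            patella_tendon_bar=-3.0, paratibial=-2.0, fibula_head=2.0,
            distal_end=4.0, distal_tibia=2.0, anterior_tibia=1.5,
            supracondylar=-2.0, volume_change=-0.05,
        )
        socket = apply_rectifications(limb, truth, specs)
        rects, _ = extract_rectifications(limb, socket, specs)
        err = np.abs(rects.as_array()[:-1] - truth.as_array()[:-1])
        scale = np.abs(truth.as_array()[:-1])
        assert np.all(err <= 0.05 * np.maximum(scale, 1.0))

    def test_noise_only_difference_fits_nothing(self, limb):
        rng = np.random.default_rng(0)
        specs = narrow_specs()
        noisy = limb.copy()
        noisy.radii = limb.radii + rng.normal(0.0, 0.5, size=limb.radii.shape)
        rects, rms = extract_rectifications(limb, noisy, specs)
        assert rms == pytest.approx(0.5, abs=0.05)
        # magnitudes bounded by 3x their unconstrained least-squares SE
        fields = np.stack(
            [kernel_field(specs[f], limb).ravel() for f in specs], axis=1
        )
        cov = np.linalg.inv(fields.T @ fields)
        se = rms * np.sqrt(np.diag(cov))
        se_by_name = dict(zip(specs, se))
        from socketgen.rectify import LOCAL_FEATURES

        for name in LOCAL_FEATURES:
            assert abs(getattr(rects, name)) < 3.0 * se_by_name[name]

    def test_grid_mismatch_rejected(self, limb):
        other = align(limb, n_slices=limb.grid.n_slices // 2)
        with pytest.raises(ValueError, match="grid"):
            extract_rectifications(limb, other)
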