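"""Phantom generator: geometry oracles, determinism, fODF structure."""

import numpy as np
import pytest

from sphtract.phantom import (
    FiberLobe,
    PhantomSpec,
    TractGeometry,
    add_noise,
    default_tracts,
    generate_phantom,
    make_single_fiber_lobe,
)
from sphtract.sh import SHBasisSpec, extract_peaks


def angle_deg(u, v):
    return np.degrees(np.arccos(min(1.0, abs(float(np.dot(u, v))))))


# --------------------------------------------------------------------------- #
# single-fiber kernel
# --------------------------------------------------------------------------- #

def test_lobe_peak_matches_construction_direction(sh8):
    coeffs = make_single_fiber_lobe(np.array([0.0, 0.0, 1.0]), 20.0, sh8)
    peaks = extract_peaks(coeffs, sh8)
    assert len(peaks) == 1
    assert angle_deg(peaks.directions[0], [0, 0, 1.0]) < 2.0


def test_lobe_rotated_direction(sh8, rng):
    mu = rng.normal(size=3)
    mu /= np.linalg.norm(mu)
    coeffs = make_single_fiber_lobe(mu, 20.0, sh8)
    peaks = extract_peaks(coeffs, sh8)
    assert len(peaks) >= 1
    assert angle_deg(peaks.directions[0], mu) < 2.0


def test_lobe_flattens_to_isotropic_as_kappa_vanishes(sh8):
    coeffs = make_single_fiber_lobe(np.array([0.0, 0.0, 1.0]), 1e-4, sh8)
    assert abs(coeffs[0] - 1.0 / (2.0 * np.sqrt(np.pi))) < 1e-4
    assert np.abs(coeffs[1:]).max() < 1e-4 * abs(coeffs[0])


def test_fiber_lobe_validation():
    with pytest.raises(ValueError):
        FiberLobe(np.array([0.0, 0.0, 2.0]), 20.0)
    with pytest.raises(ValueError):
        FiberLobe(np.array([0.0, 0.0, 1.0]), -1.0)
    with pytest.raises(ValueError):
        FiberLobe(np.array([0.0, 0.0, 1.0]), 20.0, volume_fraction=1.5)


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #

def brute_force_cylinder_count(S, p0, p1, radius):
    """Independent oracle: point-by-point distance to one segment."""
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    ab = b - a
    n = 0
    for x in range(S):
        for y in range(S):
            for z in range(S):
                p = np.array([x, y, z], float)
                t = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
                if np.linalg.norm(p - (a + t * ab)) <= radius:
                    n += 1
    return n


def test_tube_mask_matches_brute_force_cylinder():
    S, r = 20, 3.0
    path = np.array([[2.0, 9.5, 9.5], [17.0, 9.5, 9.5]])
    spec = PhantomSpec(
        volume_side=S,
        tracts=(TractGeometry("t", path, r),),
        scenario="single",
    )
    ds = generate_phantom(spec)
    assert int(ds.masks["t"].sum()) == brute_force_cylinder_count(S, path[0], path[1], r)


def test_phantom_determinism():
    spec = PhantomSpec(volume_side=16, scenario="crossing", seed=5,
                       noise_sigma=0.02)
    d1 = generate_phantom(spec)
    d2 = generate_phantom(spec)
    assert np.array_equal(d1.fodf, d2.fodf)
    for k in d1.masks:
        assert np.array_equal(d1.masks[k], d2.masks[k])


def test_path_outside_volume_rejected():
    bad = TractGeometry("bad", np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0]]), 2.0)
    with pytest.raises(ValueError, match="leaves the volume"):
        PhantomSpec(volume_side=16, tracts=(bad,), scenario="single")


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(volume_side=8)
    with pytest.raises(ValueError):
        PhantomSpec(scenario="spiral")
    with pytest.raises(ValueError):
        PhantomSpec(noise_sigma=-0.1)


def test_spec_round_trips_through_dict():
    spec = PhantomSpec(volume_side=24, scenario="bottleneck", seed=9,
                       noise_sigma=0.01)
    spec2 = PhantomSpec.from_dict(spec.to_dict())
    assert spec2.volume_side == 24 and spec2.scenario == "bottleneck"
    assert np.array_equal(spec2.tracts[0].path if spec2.tracts else [],
                          spec.tracts[0].path if spec.tracts else [])
    d1 = generate_phantom(spec)
    d2 = generate_phantom(spec2)
    assert np.array_equal(d1.fodf, d2.fodf)


# --------------------------------------------------------------------------- #
# fODF structure
# --------------------------------------------------------------------------- #

def test_crossing_voxels_carry_two_orthogonal_peaks(crossing32_dataset, sh8):
    ds = crossing32_dataset
    overlap = np.argwhere(ds.overlap)
    assert overlap.size > 0
    center = overlap[np.argmin(np.abs(overlap - 15.5).sum(axis=1))]
    peaks = extract_peaks(ds.fodf[tuple(center)].astype(float), sh8)
    assert len(peaks) == 2
    assert abs(angle_deg(peaks.directions[0], peaks.directions[1]) - 90.0) < 2.0


def test_tract_voxels_have_energy_above_background(crossing32_dataset):
    ds = crossing32_dataset
    energy = np.sum(ds.fodf.astype(np.float64) ** 2, axis=-1)
    any_tract = np.stack(list(ds.masks.values())).sum(axis=0) > 0
    assert energy[any_tract].min() > energy[~any_tract].max()


def test_bottleneck_corridor_single_orientation_two_masks(sh8):
    """In the corridor, orientation is ambiguous (one dominant peak along the
    corridor axis) while both tract masks are positive."""
    ds = generate_phantom(PhantomSpec(volume_side=32, scenario="bottleneck", seed=3))
    names = list(ds.masks)
    assert len(names) == 2
    both = (ds.masks[names[0]] > 0) & (ds.masks[names[1]] > 0)
    assert both.sum() > 0
    # corridor interior: overlap voxels away from the merge/diverge corners
    xs = np.argwhere(both)
    x_lo, x_hi = 32 / 3.0 + 4, 2 * 32 / 3.0 - 4
    interior = xs[(xs[:, 0] > x_lo) & (xs[:, 0] < x_hi)]
    assert len(interior) > 0
    for vox in interior[:: max(1, len(interior) // 5)]:
        peaks = extract_peaks(ds.fodf[tuple(vox)].astype(float), sh8)
        assert len(peaks) == 1
        assert angle_deg(peaks.directions[0], [1.0, 0.0, 0.0]) < 2.0


def test_default_tracts_stay_inside():
    for scenario in ("crossing", "bottleneck", "single"):
        for S in (16, 48):
            for t in default_tracts(scenario, S):
                assert np.all(t.path >= 0) and np.all(t.path <= S - 1)


# --------------------------------------------------------------------------- #
# noise
# --------------------------------------------------------------------------- #

def test_add_noise_zero_sigma_is_identity(rng):
    vol = rng.normal(size=(4, 4, 4, 6)).astype(np.float32)
    out = add_noise(vol, 0.0, seed=1)
    assert np.array_equal(out, vol) and out is not vol


def test_add_noise_reproducible(rng):
    vol = rng.normal(size=(4, 4, 4, 6)).astype(np.float32)
    assert np.array_equal(add_noise(vol, 0.05, seed=3), add_noise(vol, 0.05, seed=3))


def test_add_noise_empirical_sigma():
    vol = np.zeros((48, 48, 48, 45), dtype=np.float64)
    sigma = 0.05
    noisy = add_noise(vol, sigma, seed=7)
    sd = (noisy - vol).std()
    assert abs(sd - sigma) / sigma < 0.05


def test_add_noise_rejects_negative_sigma():
    with pytest.raises(ValueError):
        add_noise(np.zeros((2, 2, 2, 3)), -0.1, seed=0)
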