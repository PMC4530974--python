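"""Synthetic phantom generator: determinism and invariants."""

from dataclasses import replace

import numpy as np
import pytest

from octseg.errors import ConfigurationError
from octseg.io_formats import BOUNDARY_ORDER
from octseg.phantom import PhantomSpec, default_specs, generate_phantom


def test_same_seed_reproduces_identical_volume(specs):
    spec = replace(specs["vessels_speckle"], n_frames=2, seed=11)
    va, ta, ma = generate_phantom(spec)
    vb, tb, mb = generate_phantom(spec)
    assert np.array_equal(va.frames, vb.frames)
    assert np.array_equal(ma, mb)
    for lab in ta.surfaces:
        assert np.array_equal(ta.surfaces[lab], tb.surfaces[lab])


def test_named_fixtures_satisfy_their_invariants(specs):
    assert {"flat_noiseless", "fovea_clean", "fovea_speckle",
            "vessels_speckle", "full_volume"} <= set(specs)
    for name, spec in specs.items():
        spec = replace(spec, n_frames=min(spec.n_frames, 4))
        _, truth, _ = generate_phantom(spec)
        truth.validate()
        zs = [truth.surfaces[lab] for lab in BOUNDARY_ORDER]
        for zu, zl in zip(zs[:-1], zs[1:]):
            assert (zl - zu).min() >= 2.0  # minimum layer thickness
        for z in zs:
            if z.shape[0] > 1:
                assert np.abs(np.diff(z, axis=0)).max() <= 10.0


def test_band_reflectivities_rendered_between_surfaces(small_clean_phantom):
    vol, truth, _ = small_clean_phantom
    frame = np.asarray(vol.frames[0], float)
    x = 40
    ilm = int(truth.surfaces["ILM"][0, x])
    isos = int(truth.surfaces["IS-OS"][0, x])
    assert frame[ilm - 20, x] == pytest.approx(0.05, abs=0.01)   # vitreous
    assert frame[isos + 5, x] == pytest.approx(0.80, abs=0.02)   # IS-OS band
    assert frame[-5, x] == pytest.approx(0.60, abs=0.02)         # choroid


def test_vessel_columns_attenuated_and_flagged(specs):
    spec = replace(specs["vessels_speckle"], n_frames=2, speckle_shape=None)
    vol, truth, mask = generate_phantom(spec)
    assert mask.any() and mask.sum() < mask.size * 0.2
    n, x = 0, int(np.argwhere(mask[0]).ravel()[0])
    ilm = int(round(truth.surfaces["ILM"][n, x]))
    frame = np.asarray(vol.frames[n], float)
    clear = np.asarray(vol.frames[n], float)[:, x - 20]
    assert frame[ilm + 5, x] > clear[ilm + 5]       # sub-ILM brightening
    assert frame[ilm + 60, x] < 0.5 * clear[ilm + 60]  # shadow attenuation


def test_invalid_specs_rejected():
    with pytest.raises(ConfigurationError, match="thickness"):
        generate_phantom(PhantomSpec(
            base_depths=(150, 151, 190, 210, 228, 260, 272, 285),
            speckle_shape=None))
    with pytest.raises(ConfigurationError):
        generate_phantom(PhantomSpec(reflectivities=(0.1, 0.2)))
    with pytest.raises(ConfigurationError, match="bounds"):
        generate_phantom(PhantomSpec(n_rows=292))


def test_spec_dict_round_trip(specs):
    spec = specs["vessels_speckle"]
    back = PhantomSpec.from_dict(spec.to_dict())
    assert back == spec


def test_speckle_is_multiplicative_noise(specs):
    spec = replace(specs["fovea_speckle"], n_frames=1)
    noisy, truth, _ = generate_phantom(spec)
    clean, _, _ = generate_phantom(replace(spec, speckle_shape=None))
    # vitreous stays dark, bright band fluctuates around its clean level
    x = 30
    isos = int(round(truth.surfaces["IS-OS"][0, x]))
    band_noisy = np.asarray(noisy.frames[0], float)[isos + 3:isos + 9, :]
    band_clean = np.asarray(clean.frames[0], float)[isos + 3:isos + 9, :]
    ratio = band_noisy / band_clean
    assert 0.9 < ratio.mean() < 1.1
    assert 0.1 < ratio.std() < 0.5
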