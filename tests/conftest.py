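"""Shared fixtures: phantoms and their detector outputs (session-scoped,
since the detectors are the expensive part of the suite)."""

import numpy as np
import pytest

import retscreen as rs
from retscreen import phantoms as ph


@pytest.fixture(scope="session")
def lesion_phantom():
    """Fundus phantom with 3 exudates and 3 MAHM blobs, plus ground truth."""
    spec = ph.default_fundus_lesion_spec(seed=7)
    return ph.make_fundus_phantom(spec)


@pytest.fixture(scope="session")
def lesion_detections(lesion_phantom):
    """All detector outputs on the lesion phantom (no CLAHE: raw phantom)."""
    img, truth = lesion_phantom
    disc = rs.detect_optic_disc(img)
    vessels = rs.extract_vessels(img)
    exudates = rs.detect_exudates(img, None, disc)
    fovea = rs.detect_fovea(img, vessels, disc)
    mahm = rs.detect_mahm(img, vessels)
    return {
        "img": img,
        "truth": truth,
        "disc": disc,
        "vessels": vessels,
        "exudates": exudates,
        "fovea": fovea,
        "mahm": mahm,
    }


@pytest.fixture(scope="session")
def oct_noiseless():
    """Noiseless OCT phantom with a gently curved anterior boundary."""
    spec = ph.OctPhantomSpec(anterior_coeffs=(80.0, 0.05, 1e-4, -2e-7), looks=None, seed=0)
    return ph.make_oct_phantom(spec)


@pytest.fixture(scope="session")
def oct_speckled():
    """4-look speckled OCT phantom."""
    spec = ph.OctPhantomSpec(anterior_coeffs=(80.0, 0.05, 1e-4, -2e-7), looks=4, seed=1)
    return ph.make_oct_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
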