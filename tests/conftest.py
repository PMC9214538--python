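import numpy as np
import pytest

import fifspec as fs


@pytest.fixture(scope="session")
def psf():
    return fs.PSFModel()


@pytest.fixture(scope="session")
def detector():
    return fs.DetectorModel()


@pytest.fixture(scope="session")
def quiet_detector():
    """Noise-free detector: offset only."""
    return fs.DetectorModel(offset=100.0, read_noise_sd=0.0, background_mean=0.0, background_sd=0.0)


def rect_roi(side_px: float, name: str = "frame"):
    s = float(side_px)
    return (name, np.array([(0.0, 0.0), (s, 0.0), (s, s), (0.0, s)]))


@pytest.fixture(scope="session")
def monomer_image(psf, detector):
    """240x240-px pure-monomer field at 40 protomers/µm² plus its manifest."""
    mix = fs.SpeciesMixture.pure(1, 40.0)
    return fs.simulate_image(mix, psf, detector, (240, 240), 0.06, seed=42)


@pytest.fixture(scope="session")
def dimer_image(psf, detector):
    mix = fs.SpeciesMixture.pure(2, 40.0)
    return fs.simulate_image(mix, psf, detector, (240, 240), 0.06, seed=43)


@pytest.fixture(scope="session")
def monomer_segments(monomer_image, psf, detector):
    img, _ = monomer_image
    segs = fs.segment_rois(img, [rect_roi(240)])
    return fs.analyze_segments(segs, detector, psf, 0.06)


@pytest.fixture(scope="session")
def dimer_segments(dimer_image, psf, detector):
    img, _ = dimer_image
    segs = fs.segment_rois(img, [rect_roi(240)])
    return fs.analyze_segments(segs, detector, psf, 0.06)
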