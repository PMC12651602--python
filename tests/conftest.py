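import numpy as np
import pytest

from picscan.simulate import SimConfig, generate_slide


def empty_config(**kw) -> SimConfig:
    """SimConfig with all object counts zero (small canvas)."""
    base = dict(width=256, height=256, n_wbc=0, n_epi_ctc=0, n_im_ctc=0,
                n_epi_lev=0, n_im_lev=0, n_small_ev=0, n_pic=0, n_overlap=0,
                n_gap_pair=0, seed=0)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def mini_slide():
    """A small but statistically valid slide: the CK+ fraction stays below
    ~1.5% so the 6-SD cytokeratin rule has headroom."""
    cfg = SimConfig(width=1024, height=1024, n_wbc=600, n_epi_ctc=3,
                    n_im_ctc=2, n_epi_lev=3, n_im_lev=2, n_small_ev=2,
                    n_pic=2, n_overlap=1, n_gap_pair=1, seed=20)
    image, gt = generate_slide(cfg)
    return cfg, image, gt


@pytest.fixture(scope="session")
def mini_detection(mini_slide):
    from picscan.detect import detect_events
    cfg, image, gt = mini_slide
    return detect_events(image)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
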