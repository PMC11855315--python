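import numpy as np
import pytest

from poremorph import AnalysisSettings, PhantomSpec, Session, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """512x512 phantom, 8 clean interior pores: (spec, image, ground truth)."""
    spec = PhantomSpec(width=512, height=512, n_pores=8, seed=3)
    img, truth = generate_phantom(spec)
    return spec, img, truth


@pytest.fixture()
def clean_session(clean_phantom):
    """A session with one default pass run over the clean phantom."""
    _, img, truth = clean_phantom
    session = Session(img).run_pass(AnalysisSettings())
    return session, truth


def traced_region_contour(mask):
    """Outer contour of the single black region in a boolean mask."""
    from poremorph import trace_contours

    binary = np.where(mask, 0, 255).astype(np.uint8)
    contours = [c for c in trace_contours(binary) if c.parent_id is None]
    assert len(contours) == 1
    return contours[0]
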