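"""Shared fixtures: small rendered fields with ground truth.

Fields are rendered once per session (rendering is deterministic given the
seed, so caching does not weaken any test).
"""

import pytest

from lc3screen import synthgen


@pytest.fixture(scope="session")
def noiseless_field():
    """One noiseless default-parameter field with truth (seed fixed)."""
    return synthgen.render_field(n_cells=12, seed=101)


@pytest.fixture(scope="session")
def noisy_field_snr5():
    """Same geometry class at DNA SNR ~5."""
    p = synthgen.RenderParams()
    nl = p.noise_level_for_dna_snr(5.0)
    return synthgen.render_field(n_cells=12, seed=102, noise_level=nl)


@pytest.fixture(scope="session")
def segmented_noiseless(noiseless_field):
    """Noiseless field with the full segmentation stack applied."""
    from lc3screen import segmentation

    fi, truth = noiseless_field
    params = segmentation.SegmentationParams()
    labels = segmentation.segment_nuclei(fi.dna, params)
    rings = segmentation.cytoplasm_rings(labels, params.ring_radius)
    holes = segmentation.detect_nuclear_holes(fi.dna, labels, params)
    puncta = segmentation.detect_puncta(fi.lc3, labels, rings, params)
    return fi, truth, labels, rings, holes, puncta
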