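import pytest

from osseq import panel, simlib


@pytest.fixture(scope="session")
def small_design_config():
    # single probe length and a coarse anchor stride keep design fast on
    # the synthetic fixtures without changing any scoring behaviour
    return panel.DesignConfig(probe_len=(25, 25), anchor_step=5)


@pytest.fixture(scope="session")
def small_fixture(small_design_config):
    """A 2-gene synthetic reference with a designed panel."""
    genome, rois = simlib.make_reference(2, 1, 1500, seed=3)
    probes, gaps = panel.design_panel(rois, genome, small_design_config)
    return {"genome": genome, "rois": rois, "probes": probes, "gaps": gaps}
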