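"""Shared fixtures.

The two trained-study fixtures run the full desk-scale studies once per
session (about 20 + 10 trainings); every test that checks a directional claim
about the learned representations reuses them.
"""

import pytest

from augbias import pipeline


@pytest.fixture(scope="session")
def phenotype_results():
    """Crop / rotation / center / dual runs over 5 seeds on synthetic cells."""
    cfg = pipeline.default_phenotype_config()
    return pipeline.run_phenotype_study(cfg)


@pytest.fixture(scope="session")
def style_results():
    """Glyph two-transformation-set study over 5 seeds."""
    cfg = pipeline.default_style_config()
    return pipeline.run_style_study(cfg)
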