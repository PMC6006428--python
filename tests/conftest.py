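import warnings

import numpy as np
import pytest

from npcfit.density import centered_map
from npcfit.phantoms import build_assembly, crnpc_spec, default_subunits, render_density

warnings.filterwarnings("ignore", message="rejecting placement")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_map16():
    vals = np.random.default_rng(7).normal(size=(16, 16, 16))
    return centered_map(vals, 2.0)


@pytest.fixture(scope="session")
def smooth_phantom():
    """A smooth asymmetric blob map used wherever interpolation-tolerant
    geometry checks are needed."""
    from npcfit.phantoms import make_subunit

    model = make_subunit("blob-cluster", {"n_beads": 12, "extent_nm": 10.0}, seed=5)
    return render_density(model, 1.5, 48.0, 5.0)


@pytest.fixture(scope="session")
def crnpc_assembly():
    """Ground truth table, merged bead model and rendered map of the stock
    algal-NPC phantom at the study conditions."""
    spec = crnpc_spec()
    subunits = default_subunits()
    truth, merged = build_assembly(spec, subunits)
    amap = render_density(merged, 3.0, 132.0, 6.0)
    return spec, subunits, truth, merged, amap
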