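import numpy as np
import pandas as pd
import pytest

from nucaccess import synth
from nucaccess.seenseq import design_variants
from nucaccess.structscan import AtomModel


@pytest.fixture(scope="session")
def backbone():
    return synth.gen_backbone(seed=11)


@pytest.fixture(scope="session")
def library(backbone):
    lib = design_variants(backbone)
    lib.spike_in = backbone.sequence
    return lib


@pytest.fixture(scope="session")
def toy_structures():
    """(nucleosome, anchors, probe, truth) toy atomic models."""
    return synth.gen_toy_structures(seed=13)


@pytest.fixture(scope="session")
def smf_ref():
    return synth.gen_smf_ref(seed=17)


def make_model(rows):
    """AtomModel from (element, x, y, z, group) shorthand tuples."""
    full = [
        (el, "CA" if el != "P" else "P", "A", i + 1, "XXX", x, y, z, grp)
        for i, (el, x, y, z, grp) in enumerate(rows)
    ]
    return AtomModel(pd.DataFrame(full, columns=list(AtomModel.REQUIRED)))


def brute_force_clash(tf_xyz, nuc_xyz, threshold):
    """Independent all-pairs clash count (strictly-closer convention)."""
    d = np.linalg.norm(tf_xyz[:, None, :] - nuc_xyz[None, :, :], axis=2)
    return int(np.sum(d.min(axis=1) < threshold))
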