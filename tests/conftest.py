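import numpy as np
import pytest

import fvdesign as fd
from fvdesign.engine import _full_matrix, _one_hot


@pytest.fixture(scope="session")
def toy_problem():
    """A small seeded design problem shared across test modules.

    20-residue Fv, 3 designable positions mid-heavy-chain, toy oracle with
    8 bins, target geometry generated from the wildtype subsequence.
    """
    rng = np.random.default_rng(0)
    fx = fd.generate_fixtures(fd.FixtureSpec(), rng)
    fv, coords, region = fx["fv"], fx["coords"], fx["region"]
    mask = fd.build_contact_mask(coords, region)
    oracle = fd.ToyOracle(seed=7, n_bins=8)
    wt_sub = "".join(fv.letter(i) for i in region.design_positions)
    target = fd.toy_target(oracle, _full_matrix(_one_hot(wt_sub), fv, region), mask)
    return {
        "fv": fv,
        "coords": coords,
        "region": region,
        "mask": mask,
        "oracle": oracle,
        "target": target,
        "wt_sub": wt_sub,
        "reference_profile": fx["reference_profile"],
        "reference_library": fx["reference_library"],
    }


@pytest.fixture(scope="session")
def eight_letter_mask():
    """Reduced 8-letter alphabet containing the toy wildtype letters."""
    letters = "ADEFGHIK"
    allowed = np.zeros((3, 20), dtype=bool)
    for aa in letters:
        allowed[:, fd.aa_index(aa)] = True
    return letters, fd.AlphabetMask(allowed)


def full_matrix_for(sub, fv, region):
    """One-hot full-Fv matrix with ``sub`` substituted at the design rows."""
    return _full_matrix(_one_hot(sub), fv, region)
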