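import numpy as np
import pytest

from memprox import FrameEnsemble
from memprox.synthetic import DistanceMixture, SyntheticSystemSpec


def make_ensemble(coords, box=(80.0, 80.0, 90.0), species=None, residues=None,
                  charges=None, masses=None, tags=None):
    """Small hand-built ensemble; coords is (F, N, 3)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return FrameEnsemble(
        coords=coords,
        box=np.tile(box, (coords.shape[0], 1)),
        species=np.array(species if species is not None else ["X"] * n, dtype=object),
        residues=np.array(residues if residues is not None else ["RES"] * n, dtype=object),
        charges=np.asarray(charges if charges is not None else np.zeros(n), dtype=float),
        masses=np.asarray(masses if masses is not None else np.ones(n), dtype=float),
        tags=tags if tags is not None else [frozenset()] * n,
    )


@pytest.fixture
def small_mixture():
    return DistanceMixture(w_surf=0.5, lam=1.5, r_max_exp=8.0, r_max=40.0)


@pytest.fixture
def system_b_spec():
    """Composition of the charged-membrane reference system: 80 superoxide,
    134 K+, 54 singly charged lipids -> electroneutral."""
    return SyntheticSystemSpec(
        lipid_grid=16,
        ion_counts={"O2-": 80, "K+": 134},
        charged_lipids=54,
        enrichment={
            "O2-": DistanceMixture(w_surf=0.33),
            "K+": DistanceMixture(w_surf=0.20, lam=1.8),
        },
        n_frames=3,
        seed=11,
    )
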