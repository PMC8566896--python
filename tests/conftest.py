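import dataclasses

import numpy as np
import pytest

from domchemodiv.chemodiversity import DOMProfile
from domchemodiv.formula import AssignmentConfig, MolecularFormula, Peak, assign_peaks
from domchemodiv.synthetic import (
    SyntheticDesign,
    generate_dom_samples,
    generate_formula_library,
)


@pytest.fixture(scope="session")
def default_config() -> AssignmentConfig:
    return AssignmentConfig()


@pytest.fixture(scope="session")
def full_design() -> SyntheticDesign:
    """The default-size synthetic chronosequence (4,000 formulae,
    5 ages x 3 replicates, ppm_sigma 0.3, 5% noise peaks)."""
    return SyntheticDesign(seed=42)


@pytest.fixture(scope="session")
def full_library(full_design):
    return generate_formula_library(full_design)


@pytest.fixture(scope="session")
def full_dom(full_design, full_library):
    return generate_dom_samples(full_design, full_library)


@pytest.fixture(scope="session")
def full_assignments(full_dom, default_config):
    """Assignment results for every synthetic peak list."""
    out = {}
    for sid, df in full_dom.peaks.items():
        peaks = [Peak(mz=float(r.mz), intensity=float(r.intensity)) for r in df.itertuples()]
        out[sid] = assign_peaks(peaks, default_config)
    return out


@pytest.fixture(scope="session")
def assigned_profiles(full_dom, full_assignments):
    """Profiles recovered by running assignment on every synthetic peak
    list (the estimated counterpart of full_dom.profiles)."""
    return {
        sid: DOMProfile.from_assigned_peaks(
            sid, assigned, group=full_dom.sample_groups[sid]
        )
        for sid, (assigned, _) in full_assignments.items()
    }


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """A scaled-down design for fast structural tests."""
    return SyntheticDesign(seed=5, n_formulae=300, n_otus=80, seq_depth=5000)


def random_profile(rng: np.random.Generator, pool, k: int, sample_id: str = "s") -> DOMProfile:
    """Profile over k formulae drawn from a pool, log-normal intensities."""
    idx = rng.choice(len(pool), size=k, replace=False)
    records = [(pool[i], float(rng.lognormal(0, 1))) for i in idx]
    return DOMProfile.from_records(sample_id, records)


@pytest.fixture(scope="session")
def formula_pool():
    """A deterministic pool of valid formulae for random-profile tests."""
    pool = []
    for c in range(5, 30):
        for o in range(0, min(20, c + 1), 2):
            h = 2 * (c // 2) + 2
            if h > 2 + 2 * c:
                h = 2 + 2 * c
            pool.append(MolecularFormula(c=c, h=h, o=o))
            if c > 6:
                pool.append(MolecularFormula(c=c, h=h - 4, o=o, n=0))
    return tuple(dict.fromkeys(pool))
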