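"""Formula arithmetic, candidate enumeration and peak assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domchemodiv.errors import (
    ChemistryError,
    NoPeaksInWindowError,
    UnsupportedIonModeError,
    ValidationError,
)
from domchemodiv.formula import (
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    AssignmentConfig,
    MolecularFormula,
    Peak,
    assign_peaks,
    dbe,
    enumerate_candidates,
    enumerate_candidates_exhaustive,
    monoisotopic_mass,
    neutral_mass_from_mz,
    theoretical_mz,
)

formulae = st.builds(
    lambda c, h2, n, o, s: MolecularFormula(c=c, h=2 * h2 + n % 2, n=n, o=o, s=s),
    c=st.integers(1, 40),
    h2=st.integers(1, 30),
    n=st.integers(0, 4),
    o=st.integers(0, 20),
    s=st.integers(0, 2),
)


class TestMolecularFormula:
    @pytest.mark.parametrize(
        "kwargs,hill",
        [
            (dict(c=10, h=12, n=2, o=5), "C10H12N2O5"),
            (dict(c=1, h=4), "CH4"),
            (dict(c=6, h=12, o=6), "C6H12O6"),
            (dict(c=5, h=10, o=2, s=1), "C5H10O2S"),
        ],
    )
    def test_hill_string_and_roundtrip(self, kwargs, hill):
        f = MolecularFormula(**kwargs)
        assert f.hill() == hill
        assert MolecularFormula.from_string(hill) == f

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(c=0, h=2),                 # no carbon
            dict(c=1, h=0),                 # no hydrogen
            dict(c=1, h=3),                 # nitrogen rule: H+N odd
            dict(c=2, h=5, n=2),            # H+N odd with nitrogen
            dict(c=1, h=2, o=-1),           # negative count
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValidationError):
            MolecularFormula(**kwargs)

    @given(formulae)
    @settings(max_examples=50, derandomize=True)
    def test_parse_roundtrip(self, f):
        assert MolecularFormula.from_string(f.hill()) == f


class TestMassAndDBE:
    def test_methane_like_mass(self):
        assert monoisotopic_mass(MolecularFormula(c=1, h=4)) == pytest.approx(
            16.0313001, abs=1e-7
        )

    def test_glucose_mass(self):
        assert monoisotopic_mass(MolecularFormula(c=6, h=12, o=6)) == pytest.approx(
            180.0633881, abs=1e-7
        )

    @given(formulae)
    @settings(max_examples=50, derandomize=True)
    def test_mass_additivity_doubling(self, f):
        double = MolecularFormula(c=2 * f.c, h=2 * f.h, n=2 * f.n, o=2 * f.o, s=2 * f.s)
        assert monoisotopic_mass(double) == pytest.approx(
            2 * monoisotopic_mass(f), abs=1e-9
        )

    @pytest.mark.parametrize(
        "f,expected",
        [
            (MolecularFormula(c=6, h=6), 4),          # benzene
            (MolecularFormula(c=1, h=4), 0),          # saturated
            (MolecularFormula(c=10, h=12, n=2, o=5), 6),
        ],
    )
    def test_dbe_closed_form(self, f, expected):
        assert dbe(f) == expected

    def test_dbe_negative_raises(self):
        with pytest.raises(ChemistryError):
            dbe(MolecularFormula(c=1, h=6))  # 1 + 1 - 3 = -1

    @given(formulae)
    @settings(max_examples=50, derandomize=True)
    def test_dbe_integer_under_nitrogen_rule(self, f):
        try:
            value = dbe(f)
        except ChemistryError:
            return
        assert value == int(value)


class TestIonConventions:
    def test_glucose_deprotonated_roundtrip(self):
        assert neutral_mass_from_mz(179.0561116) == pytest.approx(180.0633881, abs=1e-7)

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValidationError):
            neutral_mass_from_mz(0.0)

    def test_unsupported_ion_mode(self):
        with pytest.raises(UnsupportedIonModeError):
            neutral_mass_from_mz(200.0, ion_mode="[M+H]+")

    @given(formulae)
    @settings(max_examples=100, derandomize=True)
    def test_mz_roundtrip_identity(self, f):
        assert neutral_mass_from_mz(theoretical_mz(f)) == pytest.approx(
            monoisotopic_mass(f), abs=1e-9
        )


class TestEnumeration:
    def test_glucose_found_with_defaults(self, default_config):
        cands = enumerate_candidates(180.0633881, default_config)
        assert MolecularFormula(c=6, h=12, o=6) in cands

    def test_restricted_oxygen_range_empty(self):
        cfg = AssignmentConfig(o_range=(0, 2))
        assert enumerate_candidates(180.0633881, cfg) == []

    def test_deterministic_ordering(self, default_config):
        a = enumerate_candidates(499.1234, default_config)
        b = enumerate_candidates(499.1234, default_config)
        assert a == b
        errors = [abs(monoisotopic_mass(f) - 499.1234) for f in a]
        assert errors == sorted(errors)

    def test_matches_exhaustive_reference_sample(self, default_config):
        rng = np.random.default_rng(1)
        for mass in rng.uniform(200, 800, 25):
            fast = set(enumerate_candidates(mass, default_config))
            slow = set(enumerate_candidates_exhaustive(mass, default_config))
            assert fast == slow

    def test_reference_matches_five_deep_nested_loop(self):
        """Validate the package reference enumerator against a fully
        unrolled nested loop (entire H range) on a reduced grid."""
        cfg = AssignmentConfig(
            tol_ppm=5.0, c_range=(1, 20), h_range=(1, 40), n_range=(0, 2),
            o_range=(0, 12), s_range=(0, 1),
        )

        def five_deep(neutral_mass):
            out = set()
            tol = neutral_mass * cfg.tol_ppm * 1e-6
            for c in range(cfg.c_range[0], cfg.c_range[1] + 1):
                for h in range(cfg.h_range[0], cfg.h_range[1] + 1):
                    for n in range(cfg.n_range[0], cfg.n_range[1] + 1):
                        for o in range(cfg.o_range[0], cfg.o_range[1] + 1):
                            for s in range(cfg.s_range[0], cfg.s_range[1] + 1):
                                mass = (
                                    c * MONOISOTOPIC_MASS["C"]
                                    + h * MONOISOTOPIC_MASS["H"]
                                    + n * MONOISOTOPIC_MASS["N"]
                                    + o * MONOISOTOPIC_MASS["O"]
                                    + s * MONOISOTOPIC_MASS["S"]
                                )
                                if abs(mass - neutral_mass) > tol:
                                    continue
                                if (h + n) % 2 or not (cfg.hc_min <= h / c <= cfg.hc_max):
                                    continue
                                if o / c > cfg.oc_max or 1 + c - h / 2 + n / 2 < 0:
                                    continue
                                out.add(MolecularFormula(c=c, h=h, n=n, o=o, s=s))
            return out

        rng = np.random.default_rng(2)
        for mass in rng.uniform(150, 320, 8):
            assert set(enumerate_candidates_exhaustive(mass, cfg)) == five_deep(mass)
            assert set(enumerate_candidates(mass, cfg)) == five_deep(mass)


class TestAssignPeaks:
    def test_exact_match_zero_error(self, default_config):
        f = MolecularFormula(c=10, h=12, o=5)  # [M-H]- m/z ~ 211, in window
        mz = theoretical_mz(f)
        assigned, unassigned = assign_peaks([Peak(mz=mz, intensity=10.0)], default_config)
        assert unassigned == []
        assert assigned[0].formula == f
        assert assigned[0].error_ppm == pytest.approx(0.0, abs=1e-9)

    def test_error_ppm_reproducible_from_formula(self, default_config):
        mz = theoretical_mz(MolecularFormula(c=10, h=12, o=5)) * (1 + 0.4e-6)
        assigned, _ = assign_peaks([Peak(mz=mz, intensity=1.0)], default_config)
        ap = assigned[0]
        recomputed = (ap.peak.mz - theoretical_mz(ap.formula)) / theoretical_mz(ap.formula) * 1e6
        assert ap.error_ppm == pytest.approx(recomputed, abs=1e-6)

    def test_out_of_window_peak_raises(self, default_config):
        with pytest.raises(NoPeaksInWindowError):
            assign_peaks([Peak(mz=150.0, intensity=1.0)], default_config)

    def test_empty_input_rejected(self, default_config):
        with pytest.raises(ValidationError):
            assign_peaks([], default_config)

    def test_outputs_partition_retained_peaks(self, default_config):
        rng = np.random.default_rng(3)
        peaks = [Peak(mz=float(m), intensity=1.0) for m in rng.uniform(200, 800, 50)]
        assigned, unassigned = assign_peaks(peaks, default_config)
        assert len(assigned) + len(unassigned) == len(peaks)
        assigned_ids = {id(a.peak) for a in assigned}
        assert assigned_ids.isdisjoint({id(p) for p in unassigned})

    def test_every_assignment_passes_plausibility_filters(self, default_config):
        rng = np.random.default_rng(4)
        peaks = [Peak(mz=float(m), intensity=1.0) for m in rng.uniform(200, 800, 300)]
        assigned, _ = assign_peaks(peaks, default_config)
        assert assigned  # random masses do produce some assignments
        for ap in assigned:
            f = ap.formula
            assert abs(ap.error_ppm) <= default_config.tol_ppm
            assert (f.h + f.n) % 2 == 0
            assert dbe(f) >= 0 and dbe(f) == int(dbe(f))
            assert default_config.hc_min <= f.hc <= default_config.hc_max
            assert f.oc <= default_config.oc_max
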