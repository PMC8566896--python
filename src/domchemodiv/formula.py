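"""Molecular formulae and formula assignment for negative-ESI FT-ICR MS peaks.

Ultrahigh-resolution mass spectrometry of dissolved organic matter (DOM)
resolves thousands of peaks per sample, each of which can be bound to a
unique CHNOS elemental formula because the mass defect of an exact mass is
nearly formula-specific at sub-ppm accuracy.  This module provides

* :class:`MolecularFormula` — the "species" unit of DOM chemodiversity,
* exact monoisotopic masses, double bond equivalents (DBE) and the
  [M-H]- ion-mass conventions for negative electrospray ionisation,
* bounded enumeration of candidate formulae for a measured neutral mass
  with the chemical-plausibility filters standard in DOM studies
  (nitrogen rule, H/C and O/C windows, non-negative DBE), and
* :func:`assign_peaks`, the peak-list -> formula-table step.

Only singly charged, singly deprotonated even-electron ions are
considered; isotopologue peaks are out of scope.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field, fields
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import (
    ChemistryError,
    NoPeaksInWindowError,
    UnsupportedIonModeError,
    ValidationError,
)

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "Peak",
    "AssignedPeak",
    "AssignmentConfig",
    "monoisotopic_mass",
    "dbe",
    "theoretical_mz",
    "neutral_mass_from_mz",
    "enumerate_candidates",
    "enumerate_candidates_exhaustive",
    "assign_peaks",
]

#: CODATA monoisotopic atomic masses, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
}

#: Mass of a proton, Da ([M-H]- m/z = neutral mass - PROTON_MASS).
PROTON_MASS = 1.00727646

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A neutral CHNOS molecular formula.

    Invariants: ``c >= 1``, ``h >= 1``, all counts non-negative integers,
    and ``h + n`` even (nitrogen rule for an even-electron neutral
    molecule, which forces DBE to be an integer).
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)):
                raise ValidationError(f"element count {f.name}={v!r} is not an integer")
            object.__setattr__(self, f.name, int(v))
        if self.c < 1 or self.h < 1:
            raise ValidationError(f"formula requires c >= 1 and h >= 1, got {self}")
        if self.n < 0 or self.o < 0 or self.s < 0:
            raise ValidationError(f"negative element count in {self}")
        if (self.h + self.n) % 2 != 0:
            raise ValidationError(
                f"nitrogen rule violated: H + N = {self.h + self.n} is odd for {self.hill()}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def hc(self) -> float:
        """Hydrogen-to-carbon ratio (van Krevelen y-axis)."""
        return self.h / self.c

    @property
    def oc(self) -> float:
        """Oxygen-to-carbon ratio (van Krevelen x-axis)."""
        return self.o / self.c

    def hill(self) -> str:
        """Canonical Hill-order string, e.g. ``C10H12N2O5``."""
        parts = []
        for sym, cnt in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o), ("S", self.s)):
            if cnt == 0:
                continue
            parts.append(sym if cnt == 1 else f"{sym}{cnt}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-order CHNOS string such as ``C6H12O6``."""
        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
        pos = 0
        for m in _HILL_TOKEN.finditer(text.strip()):
            if m.start() != pos:
                raise ValidationError(f"cannot parse formula string {text!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            if sym not in counts:
                raise ValidationError(f"unsupported element {sym!r} in {text!r}")
            counts[sym] += int(num) if num else 1
        if pos != len(text.strip()) or pos == 0:
            raise ValidationError(f"cannot parse formula string {text!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"], o=counts["O"], s=counts["S"])


@dataclass(frozen=True)
class Peak:
    """A measured peak: m/z in Da and detector intensity (arbitrary units)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class AssignedPeak:
    """A peak bound to a formula with its signed relative mass error (ppm).

    ``error_ppm`` is measured on the m/z scale:
    ``(measured m/z - theoretical [M-H]- m/z) / theoretical m/z * 1e6``.
    """

    peak: Peak
    formula: MolecularFormula
    error_ppm: float


@dataclass(frozen=True)
class AssignmentConfig:
    """Element ranges, tolerance and plausibility windows for assignment.

    Defaults cover CHNOS soil-DOM space in the 200-800 Da analysis window
    of a 9.4 T instrument: C 1-60, H 1-122, N 0-4, O 0-40, S 0-2,
    0.3 <= H/C <= 2.5, O/C <= 1.2, |error| <= 1 ppm.
    """

    tol_ppm: float = 1.0
    c_range: tuple[int, int] = (1, 60)
    h_range: tuple[int, int] = (1, 122)
    n_range: tuple[int, int] = (0, 4)
    o_range: tuple[int, int] = (0, 40)
    s_range: tuple[int, int] = (0, 2)
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_max: float = 1.2
    mz_min: float = 200.0
    mz_max: float = 800.0

    def __post_init__(self) -> None:
        if not (self.tol_ppm > 0):
            raise ValidationError(f"tol_ppm must be > 0, got {self.tol_ppm}")
        for name in ("c_range", "h_range", "n_range", "o_range", "s_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} minimum {lo} exceeds maximum {hi}")
        if not (self.mz_min < self.mz_max):
            raise ValidationError("mz_min must be < mz_max")
        if not (self.hc_min <= self.hc_max):
            raise ValidationError("hc_min must be <= hc_max")


# -- elemental arithmetic ---------------------------------------------------


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (additive over element counts)."""
    return (
        formula.c * MONOISOTOPIC_MASS["C"]
        + formula.h * MONOISOTOPIC_MASS["H"]
        + formula.n * MONOISOTOPIC_MASS["N"]
        + formula.o * MONOISOTOPIC_MASS["O"]
        + formula.s * MONOISOTOPIC_MASS["S"]
    )


def dbe(formula: MolecularFormula) -> float:
    """Double bond equivalents: DBE = 1 + C - H/2 + N/2.

    Oxygen and sulfur are divalent and do not contribute.  Raises
    :class:`ChemistryError` for a negative result (chemically impossible;
    such candidates must be rejected upstream).
    """
    value = 1 + formula.c - formula.h / 2 + formula.n / 2
    if value < 0:
        raise ChemistryError(f"negative DBE ({value}) for {formula.hill()}")
    return value


def theoretical_mz(formula: MolecularFormula) -> float:
    """Theoretical [M-H]- m/z of the singly deprotonated ion."""
    return monoisotopic_mass(formula) - PROTON_MASS


def neutral_mass_from_mz(mz: float, ion_mode: str = "[M-H]-") -> float:
    """Neutral monoisotopic mass from a measured m/z.

    Only the singly deprotonated negative-mode ion ``[M-H]-`` is
    supported (``ion_mode`` also accepts the alias ``"deprotonated"``).
    """
    if ion_mode not in ("[M-H]-", "deprotonated"):
        raise UnsupportedIonModeError(f"unsupported ion mode {ion_mode!r}")
    if not (mz > 0):
        raise ValidationError(f"m/z must be positive, got {mz}")
    return mz + PROTON_MASS


# -- candidate enumeration --------------------------------------------------


class _CandidateTable(NamedTuple):
    mass: np.ndarray  # sorted ascending
    c: np.ndarray
    h: np.ndarray
    n: np.ndarray
    o: np.ndarray
    s: np.ndarray


@functools.lru_cache(maxsize=8)
def _candidate_table(config: AssignmentConfig) -> _CandidateTable:
    """All formulae in the config grid passing every plausibility filter,
    sorted by neutral monoisotopic mass.

    Built once per config; queries then reduce to a binary search.  The
    filters applied are exactly those of :func:`enumerate_candidates`:
    element ranges, H/C window, O/C maximum, nitrogen rule, DBE >= 0.
    """
    c_lo, c_hi = config.c_range
    n_lo, n_hi = config.n_range
    o_lo, o_hi = config.o_range
    s_lo, s_hi = config.s_range
    h_lo_cfg, h_hi_cfg = config.h_range

    c, n, o, s = np.meshgrid(
        np.arange(c_lo, c_hi + 1),
        np.arange(n_lo, n_hi + 1),
        np.arange(o_lo, o_hi + 1),
        np.arange(s_lo, s_hi + 1),
        indexing="ij",
    )
    c, n, o, s = (a.ravel() for a in (c, n, o, s))
    keep = o <= config.oc_max * c
    c, n, o, s = c[keep], n[keep], o[keep], s[keep]

    # Valid H range per (c, n): H/C window, configured H range, DBE >= 0
    # (h <= 2 + 2c + n), and parity h == n (mod 2) from the nitrogen rule.
    h_lo = np.maximum(np.ceil(config.hc_min * c - 1e-9).astype(np.int64), h_lo_cfg)
    h_lo = np.maximum(h_lo, 1)
    h_hi = np.minimum(np.floor(config.hc_max * c + 1e-9).astype(np.int64), h_hi_cfg)
    h_hi = np.minimum(h_hi, 2 + 2 * c + n)
    # align h_lo to the parity of n
    h_lo = h_lo + ((h_lo + n) % 2)
    counts = np.maximum((h_hi - h_lo) // 2 + 1, 0)
    nonempty = counts > 0
    c, n, o, s, h_lo, counts = (a[nonempty] for a in (c, n, o, s, h_lo, counts))

    idx = np.repeat(np.arange(c.size), counts)
    offsets = np.arange(idx.size) - np.repeat(np.cumsum(counts) - counts, counts)
    h = h_lo[idx] + 2 * offsets
    c, n, o, s = c[idx], n[idx], o[idx], s[idx]

    mass = (
        c * MONOISOTOPIC_MASS["C"]
        + h * MONOISOTOPIC_MASS["H"]
        + n * MONOISOTOPIC_MASS["N"]
        + o * MONOISOTOPIC_MASS["O"]
        + s * MONOISOTOPIC_MASS["S"]
    )
    order = np.argsort(mass, kind="stable")
    return _CandidateTable(
        mass=mass[order],
        c=c[order].astype(np.int32),
        h=h[order].astype(np.int32),
        n=n[order].astype(np.int32),
        o=o[order].astype(np.int32),
        s=s[order].astype(np.int32),
    )


def _rank_candidates(
    cands: Iterable[MolecularFormula], neutral_mass: float
) -> list[MolecularFormula]:
    """Order by |mass error|, then fewer heteroatoms (n+s), fewer N,
    then canonical Hill string."""
    return sorted(
        cands,
        key=lambda f: (
            abs(monoisotopic_mass(f) - neutral_mass),
            f.n + f.s,
            f.n,
            f.hill(),
        ),
    )


def enumerate_candidates(
    neutral_mass: float, config: AssignmentConfig = AssignmentConfig()
) -> list[MolecularFormula]:
    """All plausible formulae within ``tol_ppm`` of ``neutral_mass``.

    A formula qualifies when its monoisotopic mass lies within
    ``+-tol_ppm`` (relative to ``neutral_mass``), its element counts fall
    in the configured ranges, ``hc_min <= H/C <= hc_max``,
    ``O/C <= oc_max``, ``h + n`` is even and DBE >= 0.  The result is
    ordered by absolute mass error with the deterministic tie-break
    (fewest heteroatoms, fewest N, Hill string); an empty list means no
    match.
    """
    if not (neutral_mass > 0):
        raise ValidationError(f"neutral mass must be positive, got {neutral_mass}")
    tab = _candidate_table(config)
    tol_da = neutral_mass * config.tol_ppm * 1e-6
    lo = np.searchsorted(tab.mass, neutral_mass - tol_da, side="left")
    hi = np.searchsorted(tab.mass, neutral_mass + tol_da, side="right")
    cands = [
        MolecularFormula(
            c=int(tab.c[i]), h=int(tab.h[i]), n=int(tab.n[i]), o=int(tab.o[i]), s=int(tab.s[i])
        )
        for i in range(lo, hi)
    ]
    return _rank_candidates(cands, neutral_mass)


def enumerate_candidates_exhaustive(
    neutral_mass: float, config: AssignmentConfig = AssignmentConfig()
) -> list[MolecularFormula]:
    """Reference enumeration by an unoptimized nested loop over the
    (C, N, O, S) element grid.

    For each grid point the admissible H window follows from the mass
    equation; every filter is then checked candidate by candidate.  This
    path shares no code or precomputation with
    :func:`enumerate_candidates` and exists to validate it (the two must
    return identical sets).
    """
    if not (neutral_mass > 0):
        raise ValidationError(f"neutral mass must be positive, got {neutral_mass}")
    m_h = MONOISOTOPIC_MASS["H"]
    tol_da = neutral_mass * config.tol_ppm * 1e-6
    out: list[MolecularFormula] = []
    for c in range(config.c_range[0], config.c_range[1] + 1):
        for n in range(config.n_range[0], config.n_range[1] + 1):
            for o in range(config.o_range[0], config.o_range[1] + 1):
                for s in range(config.s_range[0], config.s_range[1] + 1):
                    heavy = (
                        c * MONOISOTOPIC_MASS["C"]
                        + n * MONOISOTOPIC_MASS["N"]
                        + o * MONOISOTOPIC_MASS["O"]
                        + s * MONOISOTOPIC_MASS["S"]
                    )
                    h_min = int(np.ceil((neutral_mass - tol_da - heavy) / m_h - 1e-12))
                    h_max = int(np.floor((neutral_mass + tol_da - heavy) / m_h + 1e-12))
                    for h in range(max(h_min, 1), h_max + 1):
                        if abs(heavy + h * m_h - neutral_mass) > tol_da:
                            continue
                        if not (config.h_range[0] <= h <= config.h_range[1]):
                            continue
                        if (h + n) % 2 != 0:
                            continue
                        hc = h / c
                        if not (config.hc_min <= hc <= config.hc_max):
                            continue
                        if o / c > config.oc_max:
                            continue
                        if 1 + c - h / 2 + n / 2 < 0:
                            continue
                        out.append(MolecularFormula(c=c, h=h, n=n, o=o, s=s))
    return _rank_candidates(out, neutral_mass)


# -- peak assignment --------------------------------------------------------


def assign_peaks(
    peaks: Sequence[Peak], config: AssignmentConfig = AssignmentConfig()
) -> tuple[list[AssignedPeak], list[Peak]]:
    """Assign each peak in the m/z analysis window its best candidate.

    Peaks outside ``[mz_min, mz_max]`` are excluded before assignment.
    For each retained peak the first candidate from
    :func:`enumerate_candidates` (smallest |mass error|, deterministic
    tie-break) whose m/z-scale error also satisfies
    ``|error_ppm| <= tol_ppm`` becomes its assignment; peaks with no
    candidate are returned unassigned.  Duplicate formulae within a
    sample are merged downstream, not here.
    """
    if not peaks:
        raise ValidationError("assign_peaks requires a non-empty peak list")
    retained = [p for p in peaks if config.mz_min <= p.mz <= config.mz_max]
    if not retained:
        raise NoPeaksInWindowError(
            f"no peaks in analysis window [{config.mz_min}, {config.mz_max}] Da"
        )
    assigned: list[AssignedPeak] = []
    unassigned: list[Peak] = []
    for p in retained:
        neutral = neutral_mass_from_mz(p.mz)
        hit = None
        for cand in enumerate_candidates(neutral, config):
            tmz = theoretical_mz(cand)
            err = (p.mz - tmz) / tmz * 1e6
            if abs(err) <= config.tol_ppm:
                hit = AssignedPeak(peak=p, formula=cand, error_ppm=err)
                break
        if hit is None:
            unassigned.append(p)
        else:
            assigned.append(hit)
    return assigned, unassigned
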