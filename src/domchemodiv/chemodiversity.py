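"""Per-sample DOM descriptors, chemodiversity indices and molecule turnover.

A sample's assigned formula list becomes a :class:`DOMProfile` whose
normalized intensities ``M_i = I_i / sum(I_i)`` weight every descriptor:

* intensity-weighted means ``X/C_wa = sum(X_i/C_i * M_i)`` for O/C and
  H/C, plus weighted DBE and weighted m/z,
* Shannon chemodiversity ``H' = -sum(M_i ln M_i)`` (molecular formulae
  treated as species, intensity in place of relative abundance) and
  Pielou evenness ``J = H'/ln(richness)``,
* a seven-class van Krevelen classification (rectangles in O/C-H/C
  space) and per-class relative abundances, and
* presence/absence turnover sets (disappeared / unchanged / new)
  between two profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .formula import AssignedPeak, MolecularFormula, dbe, theoretical_mz

__all__ = [
    "DOMProfile",
    "WeightedSummary",
    "ClassBoundaries",
    "TurnoverSets",
    "DEFAULT_BOUNDARIES",
    "CLASS_LABELS",
    "UNCLASSIFIED",
    "normalize_intensities",
    "weighted_descriptors",
    "shannon_chemodiversity",
    "pielou_evenness",
    "summarize",
    "classify",
    "class_composition",
    "compare_samples",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassBoundaries:
    """Ordered van Krevelen rectangles ``(label, hc_min, hc_max, oc_min,
    oc_max)``; first match wins, inclusion is ``[min, max)`` on both axes.
    """

    rows: tuple[tuple[str, float, float, float, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for label, hc_lo, hc_hi, oc_lo, oc_hi in self.rows:
            if label in seen:
                raise ValidationError(f"duplicate class label {label!r}")
            seen.add(label)
            if not (hc_lo < hc_hi and oc_lo < oc_hi):
                raise ValidationError(f"degenerate rectangle for class {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.rows)

    def classify(self, hc: float, oc: float) -> str:
        for label, hc_lo, hc_hi, oc_lo, oc_hi in self.rows:
            if hc_lo <= hc < hc_hi and oc_lo <= oc < oc_hi:
                return label
        return UNCLASSIFIED


#: Default seven-class scheme, precedence top to bottom.  Rectangles are
#: the widely used van Krevelen regions consistent with the seven labels
#: (lipids, aliphatic/proteins, lignins/CRAM, carbohydrates, unsaturated
#: hydrocarbons, aromatic structures, tannins); alternative literature
#: boundaries can be swapped in from a file.
DEFAULT_BOUNDARIES = ClassBoundaries(
    rows=(
        ("unsaturated_hydrocarbons", 0.7, 1.5, 0.0, 0.1),
        ("lipids", 1.5, 2.0, 0.0, 0.3),
        ("aliphatic_proteins", 1.5, 2.2, 0.3, 0.67),
        ("carbohydrates", 1.5, 2.4, 0.67, 1.2),
        ("lignins_CRAM", 0.7, 1.5, 0.1, 0.67),
        ("tannins", 0.5, 1.5, 0.67, 1.2),
        ("aromatic_structures", 0.2, 0.7, 0.0, 0.67),
    )
)

#: The seven class labels in precedence order (without "unclassified").
CLASS_LABELS = DEFAULT_BOUNDARIES.labels


@dataclass
class DOMProfile:
    """One sample's merged, intensity-normalized set of assigned formulae.

    ``weight[i]`` holds the Eq.-style normalized intensity
    ``M_i = I_i / sum(I_i)`` (sums to 1); formulae are unique within a
    profile.  ``measured_mz``, when present, carries one measured m/z per
    formula (intensity-weighted mean if a formula was hit repeatedly).
    """

    sample_id: str
    formulas: tuple[MolecularFormula, ...]
    intensity: np.ndarray
    weight: np.ndarray
    group: str | None = None
    measured_mz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.formulas) == self.intensity.size == self.weight.size):
            raise ValidationError("profile arrays have inconsistent lengths")
        if len(set(self.formulas)) != len(self.formulas):
            raise ValidationError("duplicate formulae in profile (merge first)")
        if self.weight.size and abs(self.weight.sum() - 1.0) > 1e-12:
            raise ValidationError("normalized weights must sum to 1")

    @property
    def richness(self) -> int:
        return len(self.formulas)

    def formula_set(self) -> frozenset[MolecularFormula]:
        return frozenset(self.formulas)

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        records: Iterable[tuple[MolecularFormula, float]],
        group: str | None = None,
    ) -> "DOMProfile":
        return normalize_intensities(records, sample_id=sample_id, group=group)

    @classmethod
    def from_assigned_peaks(
        cls,
        sample_id: str,
        assigned: Sequence[AssignedPeak],
        group: str | None = None,
    ) -> "DOMProfile":
        """Merge duplicate formula assignments (summing intensity) and
        normalize; measured m/z per formula is the intensity-weighted mean."""
        totals: dict[MolecularFormula, float] = {}
        mz_wsum: dict[MolecularFormula, float] = {}
        for ap in assigned:
            totals[ap.formula] = totals.get(ap.formula, 0.0) + ap.peak.intensity
            mz_wsum[ap.formula] = mz_wsum.get(ap.formula, 0.0) + ap.peak.intensity * ap.peak.mz
        profile = normalize_intensities(totals.items(), sample_id=sample_id, group=group)
        mz = np.array(
            [
                mz_wsum[f] / totals[f] if totals[f] > 0 else theoretical_mz(f)
                for f in profile.formulas
            ]
        )
        profile.measured_mz = mz
        return profile


def normalize_intensities(
    records: Iterable[tuple[MolecularFormula, float]],
    sample_id: str = "sample",
    group: str | None = None,
) -> DOMProfile:
    """Build a :class:`DOMProfile` with ``M_i = I_i / sum(I_i)``.

    Duplicate formulae are merged by summing intensity; zero-intensity
    records are dropped (count logged).  All-zero input is an error.
    """
    totals: dict[MolecularFormula, float] = {}
    for f, inten in records:
        if inten < 0:
            raise ValidationError(f"negative intensity {inten} for {f.hill()}")
        totals[f] = totals.get(f, 0.0) + float(inten)
    dropped = sum(1 for v in totals.values() if v == 0.0)
    if dropped:
        logger.info("sample %s: dropped %d zero-intensity records", sample_id, dropped)
    kept = sorted(((f, v) for f, v in totals.items() if v > 0), key=lambda t: t[0].hill())
    if not kept:
        raise ValidationError(f"sample {sample_id!r}: all intensities are zero")
    formulas = tuple(f for f, _ in kept)
    intensity = np.array([v for _, v in kept], dtype=float)
    weight = intensity / intensity.sum()
    # guard against accumulated rounding in the normalization itself
    weight = weight / weight.sum()
    return DOMProfile(
        sample_id=sample_id, formulas=formulas, intensity=intensity, weight=weight, group=group
    )


@dataclass(frozen=True)
class WeightedSummary:
    """Intensity-weighted descriptors and chemodiversity of one profile."""

    oc_wa: float
    hc_wa: float
    dbe_wa: float
    mz_wa: float
    shannon: float
    pielou: float
    richness: int


def weighted_descriptors(profile: DOMProfile, use_measured_mz: bool = False) -> dict[str, float]:
    """Intensity-weighted O/C, H/C, DBE and m/z of a normalized profile.

    ``m/z_wa`` uses the theoretical [M-H]- m/z of each assigned formula
    by default (differences from measured values are sub-ppm); pass
    ``use_measured_mz=True`` to weight the measured masses instead.
    """
    w = profile.weight
    oc = np.array([f.oc for f in profile.formulas])
    hc = np.array([f.hc for f in profile.formulas])
    d = np.array([dbe(f) for f in profile.formulas])
    if use_measured_mz:
        if profile.measured_mz is None:
            raise ValidationError("profile carries no measured m/z values")
        mz = profile.measured_mz
    else:
        mz = np.array([theoretical_mz(f) for f in profile.formulas])
    return {
        "oc_wa": float(oc @ w),
        "hc_wa": float(hc @ w),
        "dbe_wa": float(d @ w),
        "mz_wa": float(mz @ w),
    }


def shannon_chemodiversity(profile: DOMProfile) -> float:
    """Shannon index ``H' = -sum(M_i ln M_i)`` in nats (0 for richness 1)."""
    w = profile.weight[profile.weight > 0]
    return float(-(w * np.log(w)).sum())


def pielou_evenness(profile: DOMProfile) -> float:
    """Pielou evenness ``J = H' / ln(richness)``; NaN (with a warning)
    when richness < 2, where evenness is undefined."""
    if profile.richness < 2:
        warnings.warn(
            f"sample {profile.sample_id!r}: Pielou evenness undefined for richness "
            f"{profile.richness}; reporting NaN",
            stacklevel=2,
        )
        return float("nan")
    return shannon_chemodiversity(profile) / np.log(profile.richness)


def summarize(profile: DOMProfile, use_measured_mz: bool = False) -> WeightedSummary:
    """Full Table-1-style descriptor suite for one sample."""
    desc = weighted_descriptors(profile, use_measured_mz=use_measured_mz)
    shannon = shannon_chemodiversity(profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pielou = pielou_evenness(profile)
    return WeightedSummary(
        oc_wa=desc["oc_wa"],
        hc_wa=desc["hc_wa"],
        dbe_wa=desc["dbe_wa"],
        mz_wa=desc["mz_wa"],
        shannon=shannon,
        pielou=pielou,
        richness=profile.richness,
    )


def classify(
    formula: MolecularFormula, boundaries: ClassBoundaries = DEFAULT_BOUNDARIES
) -> str:
    """Compound-class label of a formula from its (O/C, H/C) position."""
    return boundaries.classify(formula.hc, formula.oc)


def class_composition(
    profile: DOMProfile, boundaries: ClassBoundaries = DEFAULT_BOUNDARIES
) -> dict[str, float]:
    """Per-class relative abundance ``sum(M_i)``; keys cover every class
    label plus ``unclassified`` and the values sum to 1."""
    comp = {label: 0.0 for label in boundaries.labels}
    comp[UNCLASSIFIED] = 0.0
    for f, w in zip(profile.formulas, profile.weight):
        comp[boundaries.classify(f.hc, f.oc)] += float(w)
    return comp


@dataclass(frozen=True)
class TurnoverSets:
    """Presence/absence turnover between a reference and a comparison
    profile: formulae that disappeared, persisted, or newly appeared."""

    disappeared: frozenset[MolecularFormula]
    unchanged: frozenset[MolecularFormula]
    new: frozenset[MolecularFormula]


def compare_samples(
    reference: DOMProfile, comparison: DOMProfile, min_weight: float = 0.0
) -> TurnoverSets:
    """Set algebra on formula identity between two profiles.

    ``min_weight`` optionally ignores formulae below a normalized
    intensity floor in either profile (off by default: appearance and
    disappearance are pure presence/absence).
    """
    def present(profile: DOMProfile) -> frozenset[MolecularFormula]:
        if min_weight <= 0:
            return profile.formula_set()
        return frozenset(
            f for f, w in zip(profile.formulas, profile.weight) if w >= min_weight
        )

    ref, comp = present(reference), present(comparison)
    return TurnoverSets(
        disappeared=frozenset(ref - comp),
        unchanged=frozenset(ref & comp),
        new=frozenset(comp - ref),
    )
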