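"""Ground-truth synthetic chronosequence datasets.

Emulates the study design the pipeline targets: five stand-age groups
(4/15/24/43/100 years) with three replicate soils each, a library of a
few thousand CHNOS formulae spread over the seven van Krevelen classes,
log-normal peak intensities whose class mixture drifts monotonically
across the chronosequence (lignins/CRAM and lipids up,
aliphatic/proteins and carbohydrates down), ppm-scale mass error,
a configurable fraction of unassignable noise peaks, and OTU count
tables with planted OTU-molecule correlations.

Every stage is deterministic under the design seed, and ground truth
(true formula per peak, true normalized intensities, true class
composition, planted-link ledger) is emitted alongside the observables
so each pipeline stage can be scored against what was planted.

Two deliberate idealisations keep the round trip exact where the real
measurement is exact-by-construction: library m/z values follow a
truncated Gaussian centred near 420 Da (matching the unimodal m/z
distributions of real soil DOM spectra), and every library formula is
required to be mass-unambiguous — no other formula of the assignment
grid lies within 2 ppm — mirroring the fact that published DOM formula
lists are already uniqueness-resolved.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemodiversity import (
    CLASS_LABELS,
    DEFAULT_BOUNDARIES,
    ClassBoundaries,
    DOMProfile,
    normalize_intensities,
)
from .community import OTUTable
from .errors import InfeasibleDesignError, ValidationError
from .formula import (
    MONOISOTOPIC_MASS,
    AssignmentConfig,
    MolecularFormula,
    _candidate_table,
    monoisotopic_mass,
    theoretical_mz,
)

__all__ = [
    "SyntheticDesign",
    "FormulaLibrary",
    "SyntheticDOMData",
    "default_class_weights",
    "generate_formula_library",
    "generate_dom_samples",
    "generate_otu_table",
    "generate_dataset",
    "SyntheticDataset",
    "top_dom_indices",
]

_DEFAULT_GROUPS = ("4", "15", "24", "43", "100")

# Endpoint class mixtures of the chronosequence drift (linear in between):
# lignins/CRAM and lipids increase with stand age, aliphatic/proteins and
# carbohydrates decrease; magnitudes are generator defaults, not claims
# about the real system.
_WEIGHTS_YOUNG = {
    "unsaturated_hydrocarbons": 0.05,
    "lipids": 0.05,
    "aliphatic_proteins": 0.20,
    "carbohydrates": 0.15,
    "lignins_CRAM": 0.40,
    "tannins": 0.10,
    "aromatic_structures": 0.05,
}
_WEIGHTS_OLD = {
    "unsaturated_hydrocarbons": 0.05,
    "lipids": 0.09,
    "aliphatic_proteins": 0.12,
    "carbohydrates": 0.07,
    "lignins_CRAM": 0.50,
    "tannins": 0.12,
    "aromatic_structures": 0.05,
}


def default_class_weights(n_groups: int = 5) -> pd.DataFrame:
    """Per-group class mixture weights (rows sum to 1), drifting linearly
    from the young to the old endpoint mixture."""
    t = np.linspace(0.0, 1.0, n_groups)[:, None]
    young = np.array([_WEIGHTS_YOUNG[c] for c in CLASS_LABELS])
    old = np.array([_WEIGHTS_OLD[c] for c in CLASS_LABELS])
    w = (1 - t) * young + t * old
    groups = _DEFAULT_GROUPS if n_groups == 5 else tuple(str(i) for i in range(n_groups))
    return pd.DataFrame(w, index=list(groups), columns=list(CLASS_LABELS))


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic chronosequence study.

    Defaults mirror the target study's scale: 5 stand ages x 3 replicate
    soils, ~4,000 formulae per spectrum, sub-ppm mass accuracy
    (``ppm_sigma`` 0.3), 5% unassignable noise peaks, 500 OTUs sequenced
    to 50,000 counts per sample.  ``planted_links`` lists
    ``(otu_index, library_formula_index, target_pearson_r)`` triples.
    """

    seed: int = 42
    n_groups: int = 5
    n_reps: int = 3
    n_formulae: int = 4000
    class_weights: tuple[tuple[float, ...], ...] | None = None
    ppm_sigma: float = 0.3
    noise_peak_fraction: float = 0.05
    n_otus: int = 500
    seq_depth: int = 50_000
    planted_links: tuple[tuple[int, int, float], ...] = ()
    intensity_sigma: float = 1.0
    mz_center: float = 420.0
    mz_sd: float = 90.0
    uniqueness_ppm: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.n_reps, self.n_formulae, self.n_otus, self.seq_depth) < 1:
            raise ValidationError("all design counts must be positive")
        if not (0 <= self.noise_peak_fraction < 1):
            raise ValidationError("noise_peak_fraction must be in [0, 1)")
        if self.ppm_sigma < 0:
            raise ValidationError("ppm_sigma must be >= 0")
        for otu_i, dom_i, r in self.planted_links:
            if not (abs(r) < 1):
                raise ValidationError(f"planted |r| must be < 1, got {r}")
            if otu_i < 0 or otu_i >= self.n_otus:
                raise ValidationError(f"planted OTU index {otu_i} out of range")
        w = self.weights_frame()
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("class_weights rows must sum to 1")

    def weights_frame(self) -> pd.DataFrame:
        if self.class_weights is None:
            return default_class_weights(self.n_groups)
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (self.n_groups, len(CLASS_LABELS)):
            raise ValidationError(
                f"class_weights must be {self.n_groups} x {len(CLASS_LABELS)}"
            )
        groups = _DEFAULT_GROUPS if self.n_groups == 5 else tuple(
            str(i) for i in range(self.n_groups)
        )
        return pd.DataFrame(w, index=list(groups), columns=list(CLASS_LABELS))

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.weights_frame().index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(
            f"age{g}_rep{r + 1}" for g in self.group_labels for r in range(self.n_reps)
        )


@dataclass
class FormulaLibrary:
    """The planted formula universe: formulae, intended class labels and
    theoretical [M-H]- m/z values, deduplicated."""

    formulas: tuple[MolecularFormula, ...]
    classes: tuple[str, ...]
    mz: np.ndarray

    def __len__(self) -> int:
        return len(self.formulas)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.classes:
            out[c] = out.get(c, 0) + 1
        return out


# approximate mass per carbon for each class (C + hc_mid*H + oc_mid*O),
# used only to aim sampled c at a target molecular mass
def _mass_per_carbon(hc_lo, hc_hi, oc_lo, oc_hi) -> float:
    hc_mid = 0.5 * (hc_lo + hc_hi)
    oc_mid = 0.5 * (oc_lo + oc_hi)
    return 12.0 + hc_mid * MONOISOTOPIC_MASS["H"] + oc_mid * MONOISOTOPIC_MASS["O"]


def _is_unambiguous(
    mass: float, config: AssignmentConfig, uniqueness_ppm: float
) -> bool:
    tab = _candidate_table(config)
    tol = mass * uniqueness_ppm * 1e-6
    lo = np.searchsorted(tab.mass, mass - tol, side="left")
    hi = np.searchsorted(tab.mass, mass + tol, side="right")
    return hi - lo == 1  # only the formula itself


def generate_formula_library(
    design: SyntheticDesign,
    boundaries: ClassBoundaries = DEFAULT_BOUNDARIES,
    config: AssignmentConfig = AssignmentConfig(),
) -> FormulaLibrary:
    """Sample ``n_formulae`` distinct formulae inside their intended class
    rectangles.

    Each formula passes every assignment plausibility filter (element
    ranges, H/C and O/C windows, nitrogen rule, DBE >= 0), has a
    theoretical [M-H]- m/z inside the analysis window, classifies back
    to its intended label, and is mass-unambiguous at
    ``design.uniqueness_ppm``.  Class labels are drawn from the mean of
    the per-group class weights so library coverage matches prevalence.
    """
    rng = np.random.default_rng([design.seed, 0])
    weights = design.weights_frame().mean(axis=0)
    weights = weights / weights.sum()
    rect = {r[0]: r[1:] for r in boundaries.rows}
    labels = list(weights.index)
    probs = weights.to_numpy()

    seen: set[MolecularFormula] = set()
    formulas: list[MolecularFormula] = []
    classes: list[str] = []
    max_attempts = 300 * design.n_formulae
    attempts = 0
    while len(formulas) < design.n_formulae:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleDesignError(
                f"could not realize {design.n_formulae} formulae after "
                f"{max_attempts} attempts (rectangle/element-range combination "
                "too restrictive)"
            )
        label = labels[rng.choice(len(labels), p=probs)]
        hc_lo, hc_hi, oc_lo, oc_hi = rect[label]
        # respect the assignment H/C window from below (aromatic rectangle
        # extends to 0.2 but assignable space starts at hc_min)
        hc_lo = max(hc_lo, config.hc_min)
        mpc = _mass_per_carbon(hc_lo, hc_hi, oc_lo, oc_hi)
        target_mass = rng.normal(design.mz_center, design.mz_sd)
        if not (config.mz_min + 2 < target_mass < config.mz_max - 2):
            continue
        c = int(np.round(target_mass / mpc))
        if not (config.c_range[0] <= c <= config.c_range[1]) or c < 4:
            continue
        # integer O with o/c in [oc_lo, oc_hi)
        o_lo = int(np.ceil(oc_lo * c - 1e-9))
        o_hi = int(np.ceil(oc_hi * c - 1e-9)) - 1
        o_hi = min(o_hi, config.o_range[1])
        if o_hi < max(o_lo, config.o_range[0]):
            continue
        o = int(rng.integers(max(o_lo, config.o_range[0]), o_hi + 1))
        # occasional heteroatoms, mostly CHO as in real soil DOM
        n = int(rng.choice([0, 1, 2], p=[0.70, 0.20, 0.10]))
        s = int(rng.choice([0, 1], p=[0.92, 0.08]))
        # integer H with h/c in [hc_lo, hc_hi), parity h == n (mod 2),
        # DBE >= 0 (h <= 2 + 2c + n)
        h_lo = int(np.ceil(hc_lo * c - 1e-9))
        h_hi = int(np.ceil(hc_hi * c - 1e-9)) - 1
        h_hi = min(h_hi, config.h_range[1], 2 + 2 * c + n)
        h_lo = max(h_lo, 1)
        h_lo += (h_lo + n) % 2
        if h_hi < h_lo:
            continue
        n_steps = (h_hi - h_lo) // 2 + 1
        h = h_lo + 2 * int(rng.integers(0, n_steps))
        f = MolecularFormula(c=c, h=h, n=n, o=o, s=s)
        if f in seen:
            continue
        mass = monoisotopic_mass(f)
        if not (config.mz_min < mass - 1.00727646 < config.mz_max):
            continue
        if boundaries.classify(f.hc, f.oc) != label:
            continue
        if not _is_unambiguous(mass, config, design.uniqueness_ppm):
            continue
        seen.add(f)
        formulas.append(f)
        classes.append(label)
    mz = np.array([theoretical_mz(f) for f in formulas])
    return FormulaLibrary(formulas=tuple(formulas), classes=tuple(classes), mz=mz)


@dataclass
class SyntheticDOMData:
    """Per-sample peak lists plus the ground truth behind them.

    ``peaks[sample]`` has columns mz, intensity (the observable input to
    assignment); ``truth[sample]`` adds formula (Hill string, empty for
    noise), class and is_noise per peak; ``profiles[sample]`` is the true
    normalized :class:`DOMProfile` over library formulae only.
    """

    design: SyntheticDesign
    library: FormulaLibrary
    peaks: dict[str, pd.DataFrame]
    truth: dict[str, pd.DataFrame]
    profiles: dict[str, DOMProfile]
    sample_groups: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.peaks)

    def dom_matrix(self) -> pd.DataFrame:
        """True normalized intensities M_i as a molecule x sample table
        (rows indexed by Hill string, aligned to the library order)."""
        cols = {}
        for sid, prof in self.profiles.items():
            cols[sid] = pd.Series(
                prof.weight, index=[f.hill() for f in prof.formulas]
            )
        index = [f.hill() for f in self.library.formulas]
        return pd.DataFrame(cols).reindex(index).fillna(0.0)


def generate_dom_samples(
    design: SyntheticDesign, library: FormulaLibrary
) -> SyntheticDOMData:
    """Simulate one noisy peak list per sample from the library.

    Per sample, library intensities are log-normal with a group-specific
    class multiplier (``weight / class size``) so the expected class
    composition follows the design's class weights; measured m/z =
    theoretical m/z x (1 + eps/1e6) with eps ~ Normal(0, ppm_sigma);
    noise peaks (fraction ``noise_peak_fraction`` of all peaks) have
    uniform random m/z in the analysis window and low-scale log-normal
    intensities, and carry no true formula.
    """
    rng = np.random.default_rng([design.seed, 1])
    weights = design.weights_frame()
    class_n = library.class_counts()
    label_idx = np.array([CLASS_LABELS.index(c) for c in library.classes])
    class_sizes = np.array([class_n.get(c, 0) for c in CLASS_LABELS], dtype=float)
    n_lib = len(library)
    n_noise = int(round(n_lib * design.noise_peak_fraction / (1 - design.noise_peak_fraction)))
    noise_scale = 0.2 / n_lib

    peaks: dict[str, pd.DataFrame] = {}
    truth: dict[str, pd.DataFrame] = {}
    profiles: dict[str, DOMProfile] = {}
    groups: dict[str, str] = {}
    for g in weights.index:
        mult = weights.loc[g].to_numpy() / np.maximum(class_sizes, 1)
        for rep in range(design.n_reps):
            sid = f"age{g}_rep{rep + 1}"
            base = rng.lognormal(mean=0.0, sigma=design.intensity_sigma, size=n_lib)
            inten = base * mult[label_idx]
            eps = rng.normal(0.0, design.ppm_sigma, size=n_lib)
            mz_meas = library.mz * (1 + eps * 1e-6)
            noise_mz = rng.uniform(200.0, 800.0, size=n_noise)
            noise_int = rng.lognormal(mean=0.0, sigma=design.intensity_sigma, size=n_noise)
            noise_int *= noise_scale

            mz_all = np.concatenate([mz_meas, noise_mz])
            int_all = np.concatenate([inten, noise_int])
            hill = [f.hill() for f in library.formulas] + [""] * n_noise
            klass = list(library.classes) + [""] * n_noise
            is_noise = np.concatenate(
                [np.zeros(n_lib, dtype=bool), np.ones(n_noise, dtype=bool)]
            )
            order = np.argsort(mz_all, kind="stable")
            peaks[sid] = pd.DataFrame(
                {"mz": mz_all[order], "intensity": int_all[order]}
            )
            truth[sid] = pd.DataFrame(
                {
                    "mz": mz_all[order],
                    "intensity": int_all[order],
                    "formula": np.array(hill, dtype=object)[order],
                    "compound_class": np.array(klass, dtype=object)[order],
                    "is_noise": is_noise[order],
                }
            )
            profiles[sid] = normalize_intensities(
                zip(library.formulas, inten), sample_id=sid, group=str(g)
            )
            groups[sid] = str(g)
    return SyntheticDOMData(
        design=design,
        library=library,
        peaks=peaks,
        truth=truth,
        profiles=profiles,
        sample_groups=groups,
    )


def generate_otu_table(
    design: SyntheticDesign, dom: SyntheticDOMData
) -> tuple[OTUTable, pd.DataFrame]:
    """OTU count table with planted OTU-molecule correlations.

    Baseline latent abundances are log-normal per OTU and sample; counts
    are multinomial at ``seq_depth``.  For each planted link the OTU's
    latent series across samples is a closed-form blend
    ``rho * x + sqrt(1 - rho^2) * e`` of the target molecule's
    standardized M_i trajectory ``x`` and an orthogonalized noise series
    ``e``, so the latent Pearson correlation equals the target exactly;
    multinomial sampling and compositional closure attenuate it only
    mildly.  Returns the table and the planted-link ledger.
    """
    rng = np.random.default_rng([design.seed, 2])
    samples = list(dom.sample_ids)
    n_s = len(samples)
    mu = rng.normal(0.0, 1.5, size=design.n_otus)
    latent = np.exp(mu[:, None] + rng.normal(0.0, 0.8, size=(design.n_otus, n_s)))

    dom_mat = dom.dom_matrix()
    ledger_rows = []
    for otu_i, dom_i, target_r in design.planted_links:
        if dom_i < 0 or dom_i >= len(dom.library):
            raise ValidationError(f"planted dom index {dom_i} out of range")
        hill = dom.library.formulas[dom_i].hill()
        x = dom_mat.loc[hill].to_numpy()
        if np.ptp(x) == 0:
            raise ValidationError(f"planted molecule {hill} constant across samples")
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=n_s)
        e = e - e.mean()
        e = e - (e @ x) / (x @ x) * x  # orthogonalize against x
        e = e / e.std()
        z = target_r * x + np.sqrt(1 - target_r**2) * e
        level = np.exp(2.5)  # abundant OTU: safely inside any top-100 screen
        series = level * (1.0 + 0.25 * z)
        latent[otu_i] = np.maximum(series, 1e-6)
        ledger_rows.append(
            {
                "otu_id": f"OTU{otu_i + 1:04d}",
                "dom_id": hill,
                "target_r": target_r,
                "latent_r": float(np.corrcoef(latent[otu_i], x)[0, 1]),
            }
        )

    p = latent / latent.sum(axis=0, keepdims=True)
    counts = np.empty((design.n_otus, n_s), dtype=np.int64)
    for j in range(n_s):
        counts[:, j] = rng.multinomial(design.seq_depth, p[:, j])
    otu_ids = [f"OTU{i + 1:04d}" for i in range(design.n_otus)]
    phyla = ("Acidobacteria", "Proteobacteria", "Chloroflexi", "Actinobacteria",
             "Verrucomicrobia", "Firmicutes", "Planctomycetes", "Gemmatimonadetes")
    taxonomy = pd.Series(
        [f"k__Bacteria; p__{phyla[i % len(phyla)]}; g__g{i + 1}" for i in range(design.n_otus)],
        index=otu_ids,
        name="taxonomy",
    )
    table = OTUTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=samples), taxonomy=taxonomy
    )
    ledger = pd.DataFrame(
        ledger_rows, columns=["otu_id", "dom_id", "target_r", "latent_r"]
    )
    return table, ledger


@dataclass
class SyntheticDataset:
    """One complete synthetic study: DOM data, OTU table, planted links."""

    design: SyntheticDesign
    library: FormulaLibrary
    dom: SyntheticDOMData
    otu: OTUTable
    planted: pd.DataFrame


def generate_dataset(design: SyntheticDesign) -> SyntheticDataset:
    """Run all three generators under the design seed."""
    library = generate_formula_library(design)
    dom = generate_dom_samples(design, library)
    otu, ledger = generate_otu_table(design, dom)
    return SyntheticDataset(design=design, library=library, dom=dom, otu=otu, planted=ledger)


def top_dom_indices(dom: SyntheticDOMData, n: int) -> list[int]:
    """Library indices of the n molecules with highest mean true M_i
    (the molecules a top-N screen will retain)."""
    mat = dom.dom_matrix()
    means = mat.mean(axis=1)
    hills = [f.hill() for f in dom.library.formulas]
    ranked = means.sort_values(ascending=False, kind="stable").index[:n]
    lookup = {h: i for i, h in enumerate(hills)}
    return [lookup[h] for h in ranked]
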