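# Methods

## Scope and model

`domchemodiv` implements the desk side of a paired soil study: one
ultrahigh-resolution negative-ESI mass spectrum per soil sample, one
marker-gene OTU table over the same samples, and the statistics that
connect them. The chain is

1. **Formula assignment.** Each peak's m/z is converted to a neutral
   monoisotopic mass under the singly deprotonated even-electron ion
   convention (`neutral mass = m/z + 1.00727646 Da`). Candidate CHNOS
   formulae within a relative tolerance are enumerated over bounded
   element ranges and filtered by the standard plausibility rules for
   natural organic matter: nitrogen rule (H + N even, which makes DBE an
   integer), `0.3 <= H/C <= 2.5`, `O/C <= 1.2`, and
   `DBE = 1 + C - H/2 + N/2 >= 0`. The closest candidate by absolute
   mass error wins; exact ties go to the candidate with fewer
   heteroatoms (N + S), then fewer N, then the lexicographically first
   Hill string, so output is fully deterministic.
2. **Per-sample descriptors.** Intensities are closed to weights
   `M_i = I_i / sum(I_i)`; weighted means of O/C, H/C, DBE and m/z,
   Shannon chemodiversity `H' = -sum(M_i ln M_i)` (formulae as species,
   natural log) and Pielou evenness `J = H'/ln(richness)` summarize each
   sample. Seven van Krevelen rectangles (unsaturated hydrocarbons,
   lipids, aliphatic/proteins, carbohydrates, lignins/CRAM, tannins,
   aromatic structures; first match wins, `[min, max)` inclusion)
   partition the formulae into compound classes, and presence/absence
   set algebra between two profiles yields disappeared / unchanged / new
   molecule sets.
3. **Community summaries.** Observed OTUs, bias-corrected Chao1
   (`S_obs + F1(F1-1)/(2(F2+1))`), Shannon in nats, Gini-Simpson
   (`1 - sum p^2`; a dominance flag reports `sum p^2` instead), Pielou,
   and Faith's PD (total branch length of the subtree spanning the
   observed tips and the root) per sample.
4. **Linkage.** A Pearson screen of the top-N most abundant DOM
   molecules against the top-N OTUs (two-sided p from
   `t = r sqrt(n-2)/sqrt(1-r^2)`, edges at `p < alpha`, unadjusted by
   default with an optional Benjamini-Hochberg mode), and Mantel /
   partial Mantel permutation tests between whole distance matrices
   (Bray-Curtis on proportions, or Euclidean on per-feature population
   z-scores).

## Key parameters

| parameter | default | rationale |
|---|---|---|
| mass tolerance | 1.0 ppm | routine accuracy of a 9.4 T FT-ICR instrument |
| element ranges | C 1-60, H 1-122, N 0-4, O 0-40, S 0-2 | covers CHNOS DOM space for 200-800 Da |
| analysis window | 200-800 m/z | the spectral acquisition window |
| H/C, O/C windows | 0.3-2.5, <= 1.2 | plausibility bounds standard in DOM work |
| class rectangles | see `DEFAULT_BOUNDARIES` | widely used regions for the seven labels; replaceable from file |
| screen size | top 100 DOM x top 100 OTUs (50 for fungi) | common practice for tractable co-occurrence screens |
| screen alpha | 0.01, unadjusted | matches the field's reporting style; `fdr=True` available |
| Mantel permutations | 999, one-sided greater | field standard; p = (1 + exceedances)/(1 + permutations) is never 0 |

`m/z_wa` uses each formula's theoretical [M-H]- m/z (deterministic and
reproducible; differences from measured masses are sub-ppm). A flag
switches to intensity-weighted measured masses.

## The synthetic chronosequence

Real spectra for this kind of study are rarely shareable, so the
package ships a generator whose ground truth exercises every stage:
5 age groups x 3 replicate samples; a library of 4,000 CHNOS formulae
placed inside the class rectangles with integer-exact H/C and O/C
membership; log-normal intensities (sigma = 1) with group-specific
class multipliers so the expected class composition follows a weight
table that drifts linearly across the chronosequence (lignins/CRAM and
lipids up, aliphatic/proteins and carbohydrates down — the qualitative
pattern reported for conifer plantations; magnitudes are generator
defaults, not claims about any real system); mass errors
`~ Normal(0, 0.3 ppm)`; 5% unassignable noise peaks uniform in m/z; and
an OTU table (500 OTUs, multinomial at 50,000 counts per sample over a
log-normal compositional baseline) with planted OTU-molecule
correlations.

Two deliberate idealisations:

* **Library m/z follows a truncated Gaussian centred at 420 Da
  (SD 90).** Real soil DOM spectra show unimodal, roughly Gaussian m/z
  distributions with intensity-weighted means near 415-430 Da; a
  mass-uniform library would be dominated by > 600 Da formulae where
  CHNOS compositions crowd together.
* **Library formulae are mass-unambiguous**: no other formula of the
  assignment grid lies within 2.0 ppm. CHNOS space contains
  near-degenerate substitutions (e.g. +C13 H-8 N2 O-11 = 0.51 mDa,
  +C21 H-12 O-13 S-1 = 0.14 mDa), so without this constraint a
  planted formula above ~500 Da is misassigned to a closer neighbour in
  up to a quarter of draws. Published DOM formula lists are already
  uniqueness-resolved by the vendor software; the constraint emulates
  that, and makes per-peak recovery limited only by
  `P(|error| <= 1 ppm) = 99.9%` at sigma = 0.3 ppm.

Planted links blend the target molecule's standardized M_i trajectory
with a Gram-Schmidt-orthogonalized noise series,
`rho x + sqrt(1 - rho^2) e`, so the latent Pearson correlation equals
the target exactly; multinomial sampling and compositional closure
attenuate the observed correlation only mildly at the default depth.

What the generator does **not** emulate: isotopologues and adducts,
chemically structured (homologous-series) noise, spray/matrix effects
on intensity, read-level sequencing artefacts, rarefaction-depth
differences, or phylogenetic structure among OTUs (no tree is
generated; Faith's PD is exercised on explicit toy trees). Passing
tests therefore demonstrate correctness of the computations and
recoverability under a clean, well-specified measurement model — not
robustness to every artefact of real instruments.

## Numerical and design choices

* **DBE convention.** `DBE = 1 + C - H/2 + N/2` for CHNOS neutrals;
  oxygen and sulfur are divalent and do not contribute. A negative DBE
  is a chemical impossibility and raises an error rather than being
  clamped.
* **Enumeration and its oracle.** The production path precomputes the
  full filtered formula table once per configuration (about 0.9 million
  rows for the defaults), sorts it by mass and answers queries by
  binary search. A nested-loop reference (`enumerate_candidates_exhaustive`)
  shares no code with it; the test suite additionally checks that
  reference against a fully unrolled five-deep loop on a reduced grid.
* **Error bookkeeping.** `error_ppm` is reported on the m/z scale
  relative to the candidate's theoretical [M-H]- m/z, and assignments
  are re-filtered so `|error_ppm| <= tol` holds exactly under that
  convention.
* **Shannon uses the natural log.** Reported evenness values around
  0.92 with Shannon near 7.6 imply richness `exp(H/J) ~ 3,800`
  formulae, which is the right order for FT-ICR DOM only in nats.
* **Partial Mantel.** Computed with the first-order partial-correlation
  formula on the unfolded upper triangles (algebraically the
  correlation of regression residuals); when a control matrix is
  collinear with one of the inputs the denominator vanishes and the
  statistic is defined as 0 (no residual variance to correlate).
  Permutations relabel the first matrix jointly and recompute the
  statistic, as in the vegan implementation this was cross-checked
  against.
* **Screen calibration is checked under its own model.** The t-based
  Pearson p-value is exact for Gaussian data, and the Monte-Carlo null
  calibration uses independent Gaussian feature matrices accordingly.
  On the generator's log-normal compositional data the same screen is
  anti-conservative (measured false-edge rate ~0.02 at nominal 0.01,
  n = 15) — a genuine property of unadjusted Pearson screens on such
  data that users should keep in mind when interpreting edge counts.
* **Degenerate inputs.** Pielou is NaN (with a warning) for richness
  < 2; zero-variance features are skipped (not edges) in the screen;
  all-zero samples and intensity vectors raise named errors; top-N
  requests beyond the feature count keep everything with a warning.
* **Determinism.** All randomness flows through seeded NumPy
  generators; per-stage generators derive from `(seed, stage index)`.
  Two pipeline runs with identical inputs and seeds are byte-identical
  (the run manifest records a path-independent config hash).

## Problem sizes in the shipped checks

The test suite and the acceptance script run the study at its design
scale where that is what is being claimed (4,000-formula library,
15 samples, 100 x 100 screens, 200-replicate Monte-Carlo calibrations,
999-permutation Mantel tests) and at a scaled-down size
(300 formulae, 80 OTUs) where only orchestration or determinism is
being exercised.

## Known limitations

* No isotopologue or adduct handling; a real peak list should be
  deisotoped upstream.
* Above ~500 Da the CHNOS grid at 1 ppm is intrinsically ambiguous;
  with real (non-uniqueness-screened) mixtures the best-match rule will
  misassign a mass-dependent fraction of peaks, as quantified above.
* Compound classes are rectangle proxies; molecules outside all
  rectangles are reported as `unclassified` rather than forced.
* The unadjusted p < 0.01 screen controls nothing family-wise: with
  10,000 pairs, ~100 false edges are expected under the null even at
  nominal calibration. The `fdr` option exists for stricter analyses.
* No rarefaction or depth normalization beyond closure to proportions.
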