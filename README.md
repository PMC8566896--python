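# domchemodiv

Molecular-level chemodiversity of soil dissolved organic matter (DOM)
and its association with soil microbial communities.

Soils store a large part of terrestrial carbon, and the water-soluble
fraction of that carbon — DOM — is its most reactive pool. Ultrahigh-
resolution mass spectrometry (negative-ESI FT-ICR MS) resolves
thousands of peaks per soil extract, each assignable to a unique CHNOS
elemental formula, which lets ecological diversity theory be applied at
the level of molecules: formulae become "species", normalized peak
intensities become abundances. Paired with 16S/ITS OTU tables from the
same soils, the molecular and microbial views can be linked through
correlation networks and Mantel tests. `domchemodiv` is a tested,
reusable implementation of that whole desk pipeline for researchers in
soil biogeochemistry and microbial ecology.

## What it computes

* **Formula assignment** — bounded CHNOS enumeration for [M−H]⁻ peaks
  with the nitrogen rule, H/C–O/C windows, DBE ≥ 0 and deterministic
  best-match selection at a configurable ppm tolerance.
* **Intensity-weighted descriptors** — with weights `M_i = I_i / ΣI_i`:
  `O/C_wa = Σ (O_i/C_i · M_i)`, likewise H/C_wa, `DBE_wa = Σ (DBE_i · M_i)`
  with `DBE = 1 + C − H/2 + N/2`, and `m/z_wa = Σ (m/z_i · M_i)`.
* **Chemodiversity** — Shannon `H' = −Σ M_i ln M_i` (nats) and Pielou
  `J = H'/ln(richness)` over molecular formulae.
* **Van Krevelen classes** — seven-rectangle classification (lipids,
  aliphatic/proteins, lignins/CRAM, carbohydrates, unsaturated
  hydrocarbons, aromatic structures, tannins) and per-class relative
  abundances; molecule turnover sets (disappeared / unchanged / new)
  between samples or age groups.
* **Community alpha diversity** — observed OTUs, bias-corrected Chao1,
  Shannon, Gini–Simpson, Pielou, Faith's PD.
* **DOM–microbe linkage** — top-N × top-N Pearson screens (default
  100 × 100, p < 0.01) yielding bipartite edge lists/GraphML, and
  seeded Mantel / partial Mantel permutation tests on Bray–Curtis or
  Euclidean distance matrices.
* **Synthetic ground truth** — a five-age, three-replicate
  chronosequence generator (formula library, noisy peak lists, OTU
  tables with planted OTU–molecule correlations) so every stage can be
  validated against known truth. See `docs/methods.md`.

## Worked example

`examples/02_chemodiversity_descriptors.py` builds a four-molecule
profile and summarizes it:

```text
molecules (normalized intensity M_i, class):
  C10H12O4     M_i = 0.540  lignins_CRAM
  C12H22O11    M_i = 0.230  carbohydrates
  C14H12O10    M_i = 0.110  tannins
  C20H36O2     M_i = 0.120  lipids

O/C_wa  = 0.5174
H/C_wa  = 1.3800
DBE_wa  = 4.5100
m/z_wa  = 257.96
Shannon = 1.1680 nats, Pielou = 0.8425
```

The weighted averages are convex combinations of the per-molecule
ratios (the lignin-like molecule dominates because it carries 54% of
the intensity); Shannon/Pielou treat the four formulae as species with
abundances M_i — evenness 0.84 reflects the skew toward one molecule.

The other examples cover assignment (`01`), alpha diversity (`03`), the
correlation network + Mantel linkage with planted correlations (`04`),
and the full driver on a simulated chronosequence (`05`); each prints
its results with a short interpretation. The same stages are available
from the shell:

```bash
domchemodiv simulate --out sim --seed 42
domchemodiv run --input sim --out results_dir --seed 1
domchemodiv assign --peaks sim/peaks_age4_rep1.csv --out assigned.tsv
domchemodiv alphadiv --otu sim/otu_table.tsv --out alpha.tsv
```

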