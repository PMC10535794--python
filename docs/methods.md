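# Methods

## Scope and model

`troutrisk` assesses the human health risk of dietary heavy-metal exposure
through consumption of farmed rainbow trout (*Oncorhynchus mykiss*) in a
smelter-impacted Andean river system (the Tishgo River near La Oroya, Peru).
The study design it models has three river sectors (upper, middle, lower
course), three matrices — trout muscle (mg/kg wet weight), water (mg/L),
sediment (mg/kg, as reported) — four elements (As, Cu, Pb, Zn) and 12
replicates per cell.

The analysis chain:

1. **Screening** of each (sector, matrix, element) cell against regulatory
   maximum limits (Codex/FAO-WHO and FSANZ for fish muscle, USEPA criteria for
   water, Canadian interim sediment quality guidelines), with a one-sided
   Wilcoxon signed-rank exceedance flag.
2. **Bioaccumulation**: the bioconcentration factor BCF = C/C_w (muscle over
   water) and biosediment accumulation factor BSAF = C_MF/C_MS (muscle over
   sediment), formed per replicate pair and summarised by their median.
3. **Deterministic risk**: estimated daily and weekly intake (EDI, EWI = 7·EDI),
   target hazard quotient THQ = intake/RfD per element, hazard index
   HI = ΣTHQ, carcinogenic risk CR = CSF·EDI per carcinogen (As, Pb) and total
   cancer risk TCR = ΣCR, judged against the closed acceptability band
   [10⁻⁶, 10⁻⁴].
4. **Probabilistic risk**: Monte Carlo propagation of concentration
   uncertainty through the (linear) risk chain, reporting the probability that
   TCR exceeds a threshold, with binomial standard error and percentile
   summaries.
5. **Nonparametric statistics**: Kruskal–Wallis across sectors, one-sample
   Wilcoxon against maximum limits, and the Spearman correlation matrix across
   all matrix–element pairs.

## Exposure and toxicity parameters

| symbol | meaning | default | units |
|---|---|---|---|
| IR | fish ingestion rate | 0.34 | kg/person/day |
| FIR | same, in the THQ path | 340 | g/person/day |
| EF | exposure frequency | 365 | days/year |
| ED | exposure duration (expected lifetime) | 74.8 | years |
| BW | adult body weight | 60 | kg |
| AT | averaging time | EF·ED | days |
| ADAF | age-dependent adjustment factor (adult) | 1 | – |
| ARm | gastrointestinal absorption efficiency | Pb 0.33, As 0.75, Cu/Zn 1.0 | – |
| RfD | oral reference dose (USEPA IRIS) | As 3·10⁻⁴, Cu 4·10⁻², Pb 3.5·10⁻³, Zn 3·10⁻¹ | mg/kg-bw/day |
| CSF | cancer slope factor | As 1.5, Pb 0.0085 | (mg/kg-day)⁻¹ |

All are overridable through the YAML config or the dataclass constructors.
With the default AT = EF·ED, the EF·ED/AT factor cancels and EDI reduces to
C·IR/BW·ADAF·ARm. ARm enters the EDI (and hence CR) path only, not THQ,
whose intake term uses the raw concentration — the two equations are
implemented exactly as conventionally printed rather than harmonised.

The 10⁻³ factor in THQ is the g→kg conversion of FIR. The analogous 10⁻³
printed in the CR equation has no dimensional reading; because it moves TCR
by three orders of magnitude, both conventions are first-class:
`as_printed` (default, CR = CSF·EDI·10⁻³ at default AT) and `unscaled`
(CR = CSF·EDI). Every risk table, log line and simulation result records
which mode produced it, and the pipeline reports both.

The published per-sector THQ/HI table for this fishery is **not** derivable
from the published concentration table under any standard RfD set; the
package therefore treats that table as an internal-consistency surface
(HI must equal the sum of its THQs, which the suite asserts) and exposes
every parameter explicitly instead of hard-coding a reconciliation. The
published headline of a 1.27% carcinogenic-risk exceedance in the lower
course likewise does not pin down its distribution family, threshold bound
or scale-mode; the package reports a threshold sweep over 10⁻⁶–10⁻⁴ under
both CR modes with the full configuration attached, rather than asserting
equivalence to any single number.

## Distributions and the synthetic generator

Concentration uncertainty and synthetic replicates share one distribution
layer. The default family is a lognormal moment-matched to the cell's mean m
and standard deviation s (σ² = ln(1+s²/m²), μ = ln m − σ²/2), chosen because
concentrations are positive and right-skewed and the study data were
non-normal; a normal truncated at zero (parameterised by the pre-truncation
moments, so its realised mean sits slightly above nominal when m ≲ 2s) is
available for sensitivity. A zero dispersion degenerates to a point mass.

The generator's default targets are the published survey table: 36 cells of
central value ± dispersion. The printed "±" is treated as a standard
deviation (the survey does not say whether it is SD, SE or an IQR
half-width). The generator emulates cell-level location and spread only: it
has no spatial or temporal autocorrelation and no between-element or
between-matrix correlation, so passing tests demonstrate calibration of
marginal cells, not joint structure of real data. Cells are drawn from a
single seeded generator in a fixed order (sector, then matrix, then element
alphabetical), making a seed fully determine the dataset.

Because the lognormal calibration targets the *mean*, cells whose
coefficient of variation is large (up to 1.0 for upper-course muscle Cu)
have a distribution median well below the central value; per-pair ratio
medians (BCF/BSAF profiles) on synthetic data consequently sit above the
ratio of the published medians — the two summaries answer different
questions and are both reported.

Calibration note: at 10,000 draws per cell the relative standard error of a
lognormal sample mean is cv/100, i.e. 0.55–1.0% for the high-cv cells, so a
fixed 1% tolerance on cell means operates at the 1–2σ noise floor and will
fail for some seeds under a perfectly calibrated generator; the suite
therefore also checks standardized errors against a 4σ bound, which is the
statistically meaningful calibration statement.

## Statistical choices

* **Kruskal–Wallis**: tie-corrected H with the χ² approximation (k−1 df),
  via scipy.
* **Wilcoxon vs limit**: differences equal to the limit are dropped
  (Wilcoxon's zero rule). For n ≤ 25 the p-value is exact even under tied
  ranks: doubling the midranks yields integer weights and a subset-sum
  dynamic program over the 2ⁿ sign assignments gives the full null
  distribution of W⁺. Above n = 25 a tie-corrected normal approximation
  without continuity correction is used. Two-sided p-values double the
  smaller tail (capped at 1). The exceedance flag uses the one-sided
  "greater" alternative at α = 0.05, matching the survey's asterisk
  convention; the two-sided variant is available.
* **Spearman**: average-rank ρ with per-cell p-values via scipy, on records
  aligned by (sector, replicate); sectors are pooled by default (n = 36) with
  per-sector matrices available. Raw p-values are reported, as in the
  original analysis; a Benjamini–Hochberg helper is provided for users who
  want adjusted values.

## Numerical and design notes

* HI and TCR are plain Python sums of their components, so the conservation
  identities hold to machine precision.
* BCF mixes mg/kg over mg/L (an implicit L/kg); values are reported as plain
  quotients. Published factor distributions for this fishery carry "%"
  labels of the same magnitude as the raw ratios; the package treats those
  labels as cosmetic and reports raw ratios.
* Ratio pairing is by replicate index within a sector — the only auditable
  rule when field provenance of pairings is unrecorded; orphans are errors,
  never silently dropped.
* The TCR acceptability band is closed at both ends: exactly 10⁻⁶ or 10⁻⁴
  classifies as "within band".
* Non-detects and missing values are rejected at ingest; a censored-data
  policy is out of scope.
* Monte Carlo draws are element-major from one seeded PCG64 generator;
  identical configurations reproduce bit-identical results.
* As–Pb concentrations are drawn independently (no correlation is specified
  for the study system); the simulation layer is structured so a rank
  correlation could be added without changing the chain.

## Problem sizes

Default analyses run at the study design (12 replicates per cell, 10,000
Monte Carlo scenarios). The test suite uses 10,000 replicates per cell for
generator-calibration checks, 2,000 simulated null datasets for p-value
calibration, and up to 2·10⁵ draws for distribution-quantile checks; the
whole suite completes in a few seconds on one CPU.

## Known limitations

* No dermal or inhalation exposure routes; the scalar adult ADAF only.
* No PTWI/PTDI compliance tables (reference values not part of the study's
  published record).
* No kinetic uptake/depuration or trophic-transfer modelling.
* Sediment concentrations are carried "as reported" (dry/wet basis unknown).
* The Monte Carlo layer simulates carcinogenic risk only; THQ uncertainty
  propagation is not wired into the pipeline.
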