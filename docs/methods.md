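# Methods

## Crossover model

Meiotic crossovers are simulated as the superposition of two point processes
on the genetic (cM) scale of one bivalent:

* **Type I (interfering).**  A stationary gamma-renewal process with shape
  ν and mean inter-event distance 50/λ₁ cM, so the expected chiasma count on
  an interval of genetic length X cM is λ₁·X/50.  ν = 1 reduces to a
  homogeneous Poisson process (no interference); larger ν makes inter-event
  spacing more regular (interarrival CV = 1/√ν), which is what suppresses a
  second crossover next to an existing one.  Stationarity is enforced by
  drawing the first event from the equilibrium forward-recurrence
  distribution — a uniform fraction of a length-biased interarrival, which
  for a gamma is Gamma(ν+1, θ) — so event rates carry no edge bias and
  every marker interval sees the nominal intensity.
* **Type II (non-interfering).**  A homogeneous Poisson process with the
  analogous intensity λ₂·X/50.

The intensity split is λ₁ = f₁·(Type I rate factor) and λ₂ = (1−f₁)·(Type II
scale) with the Type I fraction f₁ = 0.85, reflecting the ~85/15 split
between the two crossover pathways in Arabidopsis.  At all factors equal to
1 the total intensity is X/50, which is exactly the calibration that makes
the expected Perkins estimate equal the configured map distance in the
small-interval limit (each chiasma involves 2 of 4 chromatids, so bivalent
intensity X/50 ⇒ single-spore recombination fraction X/100).

**Chromatid choice.**  Each chiasma involves one chromatid from each homolog
*axis* (original chromatid identity), chosen uniformly and independently per
event — no chromatid interference.  Resolution tracks, for every spore
strand, which original chromatid it currently follows; a chiasma swaps the
followers of its two chromatids.  Two properties pin down this choice of
semantics (the alternative — applying exchanges sequentially to composite
strands — violates both): a single chiasma inside an interval always yields
a tetratype, and tetrad classes in disjoint intervals are independent when
ν = 1.  Same-interval doubles still give the textbook 2-/3-/4-strand ratio
PD:T:NPD = 1:2:1.

Events are simulated only on the marker span: the process is stationary and
exchanges outside the span permute chromatid labels without changing any
tetrad class.

**Defaults.**  ν = 3 (moderate positive interference); no obligate-crossover
constraint.  The temperature effect is carried entirely by the Type I rate
factor: 1.0 at 20°C, 1.228 at 28°C (see calibration).  Genotype presets:
`msh4` disables Type I, `mus81` disables Type II, `fancm` scales the Type II
intensity ×10 (a representative hyper-recombination magnitude; with the 0.15
baseline share this gives ≈2.35× wild-type map distances), `spo11` disables
both pathways and scales DSBs to 10%.

## Calibration to the study conditions

| quantity | value | basis |
| --- | --- | --- |
| Type I fraction f₁ | 0.85 | pathway share of crossovers |
| DSB mean per meiocyte | 200 | γH2AX/RAD51 focus counts |
| genome genetic length | 541.2 cM | so Type I events + 0.5 background give the observed MLH1 mean 9.7 at 20°C |
| 28°C Type I factor | 1.228 | MLH1 means 9.7 → 11.8 with the 0.5 background: (11.8−0.5)/(9.7−0.5) |
| RAD51 detection efficiency | 0.9 | RAD51 mean ≈ 180 vs γH2AX ≈ 200 |
| viable pollen per anther | 665.7 (20°C), 294.5 (28°C) | observed group means |
| qPCR effects (log2FC) | BHLH122: log2 1.2 / log2 8.2; AKR4C9: log2 1.6 / log2 10.5 (100/200 mM NaCl) | observed fold changes |

MLH1 counts are the meiocyte's genome-wide Type I event count (the same
renewal process run over 5 chromosomes) plus a Poisson(0.5) background; the
background avoids a degenerate zero-variance count in pathway-null
genotypes.  DSB-marker counts are Poisson around the homeostatic mean and
deliberately independent of the Type I factor — the model encodes DSB
homeostasis, so simulated γH2AX means differ between temperatures only by
sampling noise.  Viable-pollen counts are gamma-Poisson with shape 16
(anther-to-anther CV ≈ 0.25) around the per-temperature means.

qPCR wells are CT = baseline − (log2 effect + biological noise) + technical
noise, with σ_bio = 0.25 and σ_tech = 0.15 cycles, three technical
replicates, and an endogenous control (TUB4) carrying no treatment effect.
Noise magnitudes are typical SYBR-green plate values and give the observed
significance pattern at a 3-biological-replicate design: the 200 mM response
is strongly significant under Tukey's HSD, the 100 mM response is not.

## Statistics

* **Perkins distance.**  X = 100·(T/2 + 3·NPD)/n on the PD/T/NPD multinomial
  (OTHER tetrads — patterns impossible for a true coupling-phase tetrad,
  e.g. 3:1 channel segregation — are logged and excluded from n).  Exact
  rational arithmetic until the final float.
* **Standard error.**  Delta-method multinomial SE of the per-tetrad score
  s ∈ {0, ½, 3}: SE = 100·√((E[s²]−E[s]²)/n).  The population variance (n,
  not n−1) is used, matching the estimator's plug-in derivation; a
  100,000-replicate parametric bootstrap agrees within 2% in the tests.
* **Distance comparison.**  Z = (X_A−X_B)/√(SE_A²+SE_B²) against a standard
  normal, two-sided; a chi-square homogeneity test on the class counts is
  provided as a cross-check.
* **Interference.**  R = X_wo/X_wi with the adjacent-interval conditioning
  partition: a tetrad is "with crossover" when its conditioning-interval
  class is T **or NPD** (an NPD contains two crossovers; tetrads whose
  conditioning class is OTHER are excluded).  Var R by the first-order
  ratio-variance expansion with zero covariance; condition comparison by
  Z = |R₁−R₂|/√(Var R₁+Var R₂) with a two-sided normal p (sidedness chosen
  conservatively).  X_wi = 0 or an empty partition raises an explicit
  undefined-ratio error rather than propagating NaN.
* **Cytology.**  Welch's unequal-variance t-test with Welch–Satterthwaite
  df; groups of constant equal values give t = 0, p = 1.  Significance
  labels follow the figure-legend convention verbatim — `****` ≤ 0.0001 down
  to `*` ≤ 0.05 and `ns` for p > 0.5 — which leaves p ∈ (0.05, 0.5]
  unlabeled; `significance_label` documents this quirk rather than silently
  repairing it.
* **qPCR.**  Technical replicates are averaged to one CT per sample × gene
  before ΔCT (standard comparative-CT practice); ΔΔCT is the difference of
  treatment-mean ΔCTs against the reference treatment and the reference fold
  change is exactly 1.  One-way ANOVA on ΔCT plus Tukey HSD (studentized
  range) for pairwise adjusted p-values.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes: multinomial
tetrad classes with interference-driven dependence between adjacent
intervals, homeostatic DSB counts, pathway-resolved MLH1 counts, and
plate-structured CT values.  It does not model microscope scoring errors,
transgene silencing or aborted grains (real tables contain OTHER rows; the
classifier handles them, the generator never produces them), chromosome-
scale crossover redistribution, obligate-crossover enforcement (deliberately
omitted: conditioning on at least one chiasma per bivalent would break the
closed-form Poisson/gamma oracles and the span-only simulation, and none of
the implemented analyses depend on it), female meiosis, or any mechanistic
temperature dependence beyond the single rate factor.  Passing tests therefore validate the estimators and the pipeline,
not the biology of any particular dataset.

## Problem sizes and numerical choices

Test and acceptance runs use simulation sizes chosen so Monte-Carlo error is
small against each tolerance: 10,000–20,000 tetrads for distance recovery
(SE ≈ 0.2–0.3 cM), 20,000 cells for foci means (SE ≈ 0.02 on MLH1, 0.1 on
γH2AX), 1,000 replicate experiments of 2×2,000 tetrads for the interference
null-calibration rate, 24 biological replicates for fold-change recovery
(ΔΔCT SE ≈ 0.08 cycles), and experiment-scale sizes (2,500 tetrads, 3
biological replicates) where the point is to mirror an experiment's
significance behaviour rather than to pin an estimate.  Seeds are explicit
everywhere; identical configuration and seed give bit-identical datasets.
Degenerate inputs (zero rates, empty partitions, all-one-class tables,
zero-variance groups) are either exact special cases or explicit errors, as
documented per function.
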