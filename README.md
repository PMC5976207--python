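# ftlmap

Pollen-tetrad crossover analysis for fluorescent-tagged lines (FTLs) in
*Arabidopsis thaliana*: tetrad classification, Perkins map distances,
crossover-interference ratios, cytological focus-count statistics, and
comparative-C<sub>T</sub> qPCR — together with a two-pathway meiosis
simulator so the whole pipeline is testable end to end without microscope
data.

## The problem

In a *qrt1* background the four pollen grains of one meiosis stay attached,
and pollen-expressed fluorescent transgenes at known genetic positions turn
each tetrad into a readable cross.  For two linked markers in coupling, a
tetrad is a **parental ditype** (PD), **tetratype** (T) or **non-parental
ditype** (NPD), and the genetic distance of the interval follows from the
Perkins equation

```
X = 100 · (T/2 + 3·NPD) / n   cM,      n = PD + T + NPD
```

with a multinomial delta-method standard error
`SE = 100·sqrt((E[s²] − E[s]²)/n)` over the per-tetrad score
s ∈ {0 (PD), ½ (T), 3 (NPD)}.

With three linked markers the assay also measures **crossover
interference**: the distance of a test interval is computed separately in
tetrads *without* a crossover in the adjacent interval (X<sub>wo</sub>) and
*with* one (X<sub>wi</sub>), giving the ratio `R = X_wo / X_wi` (positive
interference ⇒ R > 1).  Ratios from two conditions are compared by

```
Z = |R₁ − R₂| / sqrt(Var R₁ + Var R₂),
Var R = R² · (Var X_wo / X_wo² + Var X_wi / X_wi²)
```

(covariance taken as zero: the two partitions are disjoint tetrad sets).

Around the linkage core, the package covers the companion measurements of a
temperature-shift recombination experiment: per-cell MLH1 / RAD51 / γH2AX
focus counts and viable-pollen counts (group means and Welch's t-tests), and
ΔΔC<sub>T</sub> qPCR fold changes with one-way ANOVA and Tukey's HSD.

## The simulator

`ftlmap.synthetic` generates meioses under the two-pathway crossover model:
interfering **Type I** chiasmata from a stationary gamma-renewal process
(shape ν; ν = 1 is Poisson, larger ν spaces events more evenly) and
non-interfering **Type II** chiasmata from a homogeneous Poisson process,
both calibrated so an X cM interval sees X/50 expected chiasmata at baseline.
Each chiasma involves one chromatid from each homolog (no chromatid
interference); the four spores are read off the four chromatids.  The same
configuration drives foci counts (γH2AX/RAD51 around a homeostatic ~200 DSBs
per meiocyte, independent of the Type I rate; MLH1 counting the meiocyte's
genome-wide Type I events) and qPCR plates (CT = baseline − log2 expression
with technical/biological noise and an untouched endogenous control).
Genotype and temperature scenarios (`WT`, `msh4`, `mus81`, `fancm`, `spo11`;
20°C/28°C) are presets over this model.

## Worked example

```python
import ftlmap as fm
from ftlmap.classify import tabulate
from ftlmap.linkage import perkins_distance, compare_distances

results = {}
for temp, seed in (("20C", 1), ("28C", 2)):
    cfg = fm.scenario_config("WT", temp, n_meioses=8000, seed=seed)
    dataset = fm.simulate_tetrad_dataset(cfg, fm.I3A_MAP, "WT", temp)
    counts = tabulate(dataset, ("G", "R"))
    results[temp] = perkins_distance(counts)
    print(temp, counts, results[temp].X, results[temp].SE)

z, p = compare_distances(results["20C"], results["28C"])
```

prints (counts abridged):

```
20C: PD=7255 T=744 NPD=1   X = 4.69 ± 0.17 cM  (n = 8000)
28C: PD=7115 T=883 NPD=2   X = 5.59 ± 0.18 cM  (n = 8000)
z = -3.666, p = 0.0002
```

The 28°C condition raises the Type I chiasma intensity by the calibrated
factor 1.228, and the recovered map distance of the ~4.8 cM interval rises
accordingly; the Z test on the two Perkins estimates flags the increase.
The same pattern appears in simulated cytology — MLH1 foci at observed
sample sizes give means 9.11 (n = 57) vs 11.66 (n = 41), Welch's
t = −6.39, df = 93.7, p = 6.2×10⁻⁹ — while γH2AX means stay at ~200
regardless of the Type I factor (DSB homeostasis).

The same pipeline runs from the shell:

```
ftlmap simulate --config cfg.yaml --out tetrads.csv
ftlmap map      --config cfg.yaml --in tetrads.csv --out map.json
ftlmap fixtures --out examples/      # small example inputs for every reader
```

Each command writes its output plus a `<out>.log.json` recording inputs,
seed, versions and every computed statistic.

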