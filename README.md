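# chemoscreen

Analysis pipeline for identifying and characterizing chemoresistance genes
in drug-modifier RNAi screens, with the downstream microtubule-stability
readouts used to explain *why* a hit changes drug response. It covers the
full quantitative chain of a taxane-resistance study in triple-negative
breast cancer cells: scoring an siRNA × paclitaxel viability screen with
the sensitization index, fitting dose–response curves for IC50, scoring
tubulin fractionation blots and turbidity polymerization curves,
quantifying microtubule networks in fluorescence images, tracking EB1
plus-end comets for growth rates, and testing clinicopathologic
associations. Every stage ships with a seeded synthetic-data generator
that emits its ground truth, so the whole pipeline is testable end to end
without any external data.

## The core statistic

For each siRNA target, with CCK-8 absorbances *R*<sub>c</sub>
(knockdown, vehicle), *C*<sub>c</sub> (nontargeting control, vehicle),
*C*<sub>d</sub> (control, drug) and *R*<sub>d</sub> (knockdown, drug),
the **sensitization index** is

```
SI = (Rc/Cc) · (Cd/Cc) − Rd/Cc
```

the Bliss-style multiplicative expectation for the combined
knockdown + drug condition minus the observed combined viability, both
normalized to the untreated control. A nontargeting siRNA scores exactly
0; SI > 0 means the knockdown sensitizes cells to the drug beyond
independence. Per-target SI values are averaged across triplicates and a
target with mean SI strictly above 0.1 is called a synergistic hit;
gene-level scores average the gene's targets.

Downstream modules quantify the mechanism: percent assembled tubulin
100·P/(P+S) from pellet/supernatant blots, Hessian-eigenvalue
("tubeness") ridge filtering for the polymerized fraction of the cell
area, 4PL fits `y = bottom + (top−bottom)/(1+10^(hill·(log₁₀d − log₁₀IC50)))`,
EB1 comet growth rates in µm/min, H-score (0–12, ≥8 = high) expression
classes and Pearson chi-square association tests.

## Worked example

```python
>>> from chemoscreen import simulate, screen
>>> plate, truth = simulate.simulate_screen_plate(true_si={"gene01": 0.3},
...                                               noise_cv=0.02, seed=11)
>>> res = screen.score_screen(plate, threshold=0.1)
>>> res[res.hit][["target_id", "si_mean", "gene_si_mean"]].round(3)
    target_id  si_mean  gene_si_mean
0  gene01_si1    0.290         0.288
1  gene01_si2    0.281         0.288
2  gene01_si3    0.293         0.288
```

The plate was generated with one gene programmed to a true interaction
SI of 0.3 under 2% multiplicative well noise; all three of its siRNA
duplexes are recovered near 0.3 and called hits, while all other targets
stay near 0 and are not.

```python
>>> import numpy as np
>>> from chemoscreen.clinical import chisq_association
>>> subtype = np.array([[64, 21], [43, 14], [33, 21], [15, 21]])
>>> r = chisq_association(subtype)
>>> round(r.chi2, 1), r.df, r.p_rounded
(15.7, 3, 0.001)
```

This is the transcriptomic-subtype row of a published 232-patient
cohort table recomputed from its printed low/high expression counts:
the subtype distribution differs between expression groups
(χ² = 15.7 on 3 df, p = 0.001).

A command-line surface wraps each stage, e.g.

```bash
chemoscreen simulate comets --out demo --seed 1
chemoscreen comets --movie demo/movie.tif --px 0.065 --dt 2
# -> 37 tracks, mean rate 9.96 µm/min -> tracks.csv
```

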