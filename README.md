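# glycoevo

Individual-based eco-evolutionary simulation of a core yeast glycolysis
pathway.

## The problem

Glycolysis has a "turbo" design: ATP is invested in upper glycolysis (UG)
before lower glycolysis (LG) repays it with interest.  At high glucose this
makes the pathway bistable — besides the productive balanced steady state
there is a self-sustaining *imbalanced* state in which UG outruns LG, the
intermediate FBP accumulates, and ATP and cytosolic phosphate stay low
("substrate-accelerated death" when it persists).  Why has evolution not
eliminated such a costly failure mode?  One hypothesis: expression patterns
that risk imbalance under ample glucose are precisely the ones favoured when
glucose is scarce or fluctuating — fast uptake first, pathway balance
second.

`glycoevo` lets you test this quantitatively.  It simulates populations of
cells, each carrying the four-reaction core pathway

* v_up = v_max,up [Glc][ATP] / ((K_M,glc+[Glc])(K_M,atp+[ATP](1+[ATP]/K_i,atp)))
* v_lo = v_max,lo [FBP][ADP][P_i] / ((K_M,fbp+[FBP])(K_M,adp+[ADP])(K_M,p+[P_i]))
* v_atp = k_atp [ATP]
* v_p = k_p ([P_i]_vac − [P_i]),  with a buffered, depletable vacuolar store

coupled to health-gated volume growth, division with individual variability,
log-normal mutation of the four rate constants (the cell's genotype, a proxy
for enzyme expression levels), and either a chemostat (cells deplete the
shared glucose, wash out at rate D) or an imposed-glucose "NCG" environment
(removal rate d·N²).  Analysis tools quantify phenotypic balancedness
(glucose–ATP covariance B_p,cov, ON/OFF ATP contrast B_p,phs), genotypic
balancedness B_g, reproduction rates, and two-genotype competition.

It is aimed at researchers in systems biology and eco-evolutionary dynamics
who want a reproducible, tested reimplementation of this model class to run
scaled experiments, parameter scans or methodological variations.

## Worked example

Evolve a small population under a square-wave glucose supply (period
40 min) without competition for glucose, then ask whether the survivors are
balanced or imbalanced:

```python
import numpy as np
from glycoevo import (SimulationConfig, EnvironmentConfig, GlucoseSchedule,
                      presim_calibrate, run, metrics)

env = EnvironmentConfig(mode="ncg", D=5.0, d=2e-5,
                        schedule=GlucoseSchedule(kind="square_wave",
                                                 glc0_on=2.0, glc0_off=0.01,
                                                 T_on=20.0))
cfg = SimulationConfig(N0=10_000, N_star=500, N_tr=100,
                       t_s=0, t_ms=1_000, t_me=16_000, t_e=26_000,
                       seed=1, track_start=25_600)

env = presim_calibrate(cfg, env)        # sets d so the population ~ N_star
result = run(cfg, env)

b = []
for tr in result.tracks:
    try:
        b.append(metrics.balancedness_phase(tr, result.schedule))
    except ValueError:   # cell did not live through a full ON and OFF phase
        pass
print(f"N = {result.population.N}, tracked survivors = {len(b)}")
print(f"mean B_p,phs = {np.mean(b):.2f} mM, "
      f"fraction imbalanced = {np.mean(np.array(b) < 0):.2f}")
```

Output (a ~1 minute computation):

```
N = 2040, tracked survivors = 388
mean B_p,phs = -1.66 mM, fraction imbalanced = 0.96
```

Under this fast-fluctuating supply nearly all surviving lineages are
imbalanced (negative B_p,phs): they hold ATP *low* while glucose is present,
hoarding FBP, and convert it to ATP during starvation.  Re-running with
`T_on=100.0` (period 200 min) flips the sign — slow fluctuations favour
balanced growers.

The same experiment is available from the shell:

```bash
glycoevo simulate --preset ncg_square_T40 --seed 1 --out out/
glycoevo balancedness --tracks out/tracks.csv --mode phs \
    --preset ncg_square_T40 --seed 1 --out out/bphs.csv
```

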