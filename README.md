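# motorlab

Analysis and simulation toolkit for single-molecule studies of a viral
DNA-packaging ring-ATPase — the pentameric terminase motor (gp17) of
bacteriophage T4 — aimed at researchers quantifying motor stoichiometry,
subunit coordination and packaging dynamics from fluorescence and
optical-trap recordings.

The package implements, as tested reusable code, the quantitative chain
behind the finding that the packaging motor is a *flexibly coordinated
pentamer*: a motor that tolerates catalytically dead subunits by pausing,
slipping and re-adjusting its grip on DNA rather than arresting.

## What it computes

**Stoichiometry from photobleaching** (`motorlab.stoich`).  Donor-channel
intensity trajectories are smoothed with an edge-preserving nonlinear
forward–backward filter, segmented into a bleaching staircase by penalized
changepoint detection, and the pooled per-trace step counts `k` are fitted
with a (zero-truncated) binomial model

    s(k) = C(n, k) p^k (1 − p)^(n−k)

over candidate ring sizes `n`, where `p` is the labelling efficiency.  The
maximum-likelihood `n` is the motor stoichiometry.

**Coordination activity model** (`motorlab.coordination`).  Assembling
motors from a pool with inactive-monomer fraction `p` gives a binomial
composition f(k, p) over `k` active subunits.  If packaging requires at
least `k_min` active subunits, each contributing 1/n of the activity, the
normalised ensemble activity is

    Activity(k_min, p) = (1/n) Σ_{k = k_min}^{n} k f(k, p),

ranging from the uncoordinated limit `1 − p` (k_min = 1) to strict
coordination `(1 − p)^n` (k_min = n).  `fit_kmin` selects the coordination
level that best matches activity-vs-doping data.

**DNA-engagement kinetics** (`motorlab.engagements`).  Acceptor-channel
trajectories are idealized into engagement events, classified as transient
(< 2 s), semi-transient (2–10 s) or long-lived (> 10 s, complete
encapsidation), and dwell/lifetime distributions are fitted with
right-censored exponential mixtures (τ_avg = Σ wᵢτᵢ), with BIC model-order
selection, per-class frequencies, class-transition matrices and
packaged-DNA counts.

**Optical-trap packaging traces** (`motorlab.trap`).  Extension at constant
force is converted to unpackaged base pairs through the extensible
worm-like chain, tethers are screened against the model, velocities come
from a running 0.1-s window, pauses (> 0.1 s below a variance-based
threshold) are detected and classified as plateaus or unpackaging events,
and per-trace metrics (pause-free velocity, pauses per kb, start time) are
derived.

**Kinetic Monte Carlo packaging model** (`motorlab.kmc`).  Packaging is a
Gillespie 1-D walk: 2-bp packaging steps compete with exponential slips
(mean 0.5 bp) at probability p_pause&slip (0.65 for an all-active motor,
0.75 with 1–2 inactive subunits), with event-time means of 10 and 2
arbitrary units.  A trajectory succeeds when the 3400-bp substrate (30–40
bp pre-packaged) is fully encapsidated and fails if the DNA slips out.
A strict-arrest variant contrasts the flexible-bypass grip rule with a
strictly coordinated motor.

**Synthetic data** (`motorlab.synth`) generates all three classes of
recordings with exact ground truth, so every stage is testable without any
experimental download.

## Worked example

```python
import numpy as np
from motorlab import synth, stoich

rng = np.random.default_rng(0)
comp = synth.MotorComposition(per_subunit_label_prob=0.66)
labels = synth.sample_zero_truncated_binomial(5, 0.66, 486, rng)
traces = [
    synth.gen_photobleach_trace(comp, 100.0, noise_sd=100 / 3, seed=rng,
                                n_labels=int(k))[0]
    for k in labels
]
counts = np.array([r.n_steps for r in stoich.count_steps_dataset(traces, 60.0)])
fit = stoich.fit_binomial_stoichiometry(counts[counts >= 1], (3, 4, 5, 6, 7, 8))
print(fit.n_hat, round(fit.p_hat, 3))
```

prints

```
5 0.634
```

i.e. from 486 synthetic photobleaching trajectories generated with a
pentameric motor at 66% labelling efficiency, the pipeline recovers a
stoichiometry of 5 subunits and a labelling efficiency of 0.634.

The full synthetic pipeline (generate → analyze → report for every stage)
runs from the shell:

```bash
motorlab demo --seed 1 --out demo_out
```

and writes a `summary.json` collecting the headline numbers (stoichiometry
n̂/p̂, fitted k_min, τ_avg, pause metrics, and the kinetic Monte Carlo
velocity ratio).

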