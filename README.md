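# refback

Diffusion-decision-model (DDM) analysis of working-memory control costs
in the **reference-back task**.

## The scientific problem

Working memory (WM) must balance *stability* (shielding its contents
against interference) and *flexibility* (updating them when goals
change).  The reference-back task isolates the control operations
behind this trade-off: on every trial a probe (X or O) is judged
"same"/"different" against the WM referent; a red frame cues updating
the referent with the probe (*reference* trial), a blue frame cues
maintenance (*comparison* trial).  Crossing updating × switching ×
match yields 8 design cells and six canonical cost contrasts —
updating, comparison, switching, gate opening, gate closing and
substitution — each a slow-minus-fast difference between matched cells.

Those costs live at the level of mean RT and accuracy.  This package
decomposes them into latent decision processes by fitting the
two-boundary diffusion model: within a trial, evidence accumulates at
drift rate *v* from start point *z·a* toward boundaries 0 and *a*
("different"/"same"), and the response time adds a non-decision time
*t*₀.  Across-trial variability in drift (Gaussian SD *sv*) and start
point (uniform width *sz·a*) are included; drift criterion and
non-decision-time variability are fixed at 0 and the diffusion
coefficient at *s* = 1 for scaling.  Four factorial model variants are
compared: a **top** model with cell-specific *v* and *t*₀ and
mode-specific *a* (21 free parameters), and constrained variants fixing
the threshold (20), drift (14) or non-decision-time (14) effects.

Estimation is Bayesian: per-subject differential-evolution MCMC
(DE-MCMC), or a fully hierarchical fit with truncated-normal population
distributions that shrink subject estimates toward the group.  Model
selection uses the deviance information criterion, DIC = D̄ + p_D with
p_D = D̄ − D(θ̄).  Posterior contrasts of the six cost measures on each
parameter are summarized by the posterior mean M, SD, Z = M/SD and a
one-tailed Bayesian *p* (the posterior mass opposite the most-sampled
direction).  Because trial-level reference-back datasets are not
publicly archived, the package ships a synthetic-data generator that
reproduces the task design (512 trials in 4 blocks, equiprobable
stimuli and frames, red block-initial trials) from known group- and
subject-level parameters, supporting parameter-recovery and
posterior-predictive validation end to end.

## Worked example

```python
import refback as rb

# a synthetic 8-subject study with planted control costs
group = rb.default_group()                       # truncated-normal population
ds = rb.simulate_dataset(group, n_subjects=8, n_trials=512, n_blocks=4, seed=1)
trials, report = rb.clean(ds.trials)             # drop first trials, RT < 150 ms or > 3 s

costs = rb.canonical_costs(rb.cell_summary(trials))
print(costs.round(3))

model = rb.HierarchicalReferenceBackDDM(trials, variant="top")
res = model.fit(config=rb.SamplerConfig(n_chains=42, n_burn=300, n_keep=200), seed=2)
eff = rb.effect_posterior(res, "updating", "v", rhat_tol=None)
print(f"updating drift effect: M={eff.mean:.2f}, Z={eff.z:.2f}, p={eff.p:.4f}")
```

Output from this exact script:

```
        measure  rt_cost  acc_cost
0      updating    0.111     0.027
1    comparison    0.113     0.129
2     switching    0.027     0.030
3  gate-opening    0.032     0.029
4  gate-closing    0.023     0.031
5  substitution    0.001     0.036
updating drift effect: M=-0.55, Z=-2.27, p=0.0114
```

The planted reference-cell drift deficit and non-decision-time cost
surface as a positive updating RT cost (111 ms in this sample) at the
behavioral level, and the hierarchical posterior recovers the drift
deficit as a reliably negative updating drift effect.

A command-line interface mirrors the library
(`refback simulate|costs|fit|select|ppc|effects|recover|idiff`); see
`refback --help`.

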