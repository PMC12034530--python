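# nirsfusion

Analysis pipeline for a 14-channel prefrontal fNIRS study of **binocular
color fusion vs. rivalry**. When the two eyes receive similar colors the
percept fuses into one; when the colors differ strongly the percepts
alternate (rivalry). The package re-implements the complete analysis chain
used to characterize prefrontal activity under these two regimes and a
mid-gray baseline:

1. **Preprocessing** of raw dual-wavelength (730/850 nm, 20 Hz) light
   intensities: interval exclusion, motion-artifact detection
   (moving-window range tests: `std_thr = 6` on a standard-deviation
   reference, `amp_thr = 0.5` on optical density) with spline correction,
   zero-phase 0.01–0.2 Hz band-pass, and modified Beer–Lambert conversion
   to ΔHbO/ΔHbR (DPF = 6).
2. **Functional connectivity**: the channel-pair Pearson matrix
   R = (r_ij) per condition and its mean strength
   r̄ = (1/N) Σ_{i≠j} r_ij over the N = 91 channel pairs.
3. **Activation GLM**: Y = Xβ + ε per channel, condition regressors built
   by convolving block boxcars with the canonical double-gamma HRF
   h(t) = g(t; a₁, b₁) − c·g(t; a₂, b₂) (a₁=6, b₁=1, a₂=16, b₂=1, c=1/6).
4. **Exact non-parametric statistics**: Friedman test
   χ²_F = 12/(nk(k+1)) Σ R_j² − 3n(k+1); Wilcoxon signed-rank
   W = min(W⁺, W⁻) with the exact two-sided p by enumeration of all 2ⁿ
   sign assignments; Benjamini–Hochberg FDR (p_crit = (i/m)·α); paired
   Cohen's d = mean(dᵢ)/SD(dᵢ); post-hoc power from the noncentral t
   distribution (ncp = d√n, df = n−1).
5. **Reaction times** of the rivalry-detection key presses, with the
   accuracy check that responses occur only in rivalry blocks.

A seedable synthetic-session generator (block protocols, HRF responses,
condition-dependent shared-drive coupling, physiological oscillations,
drift, spike/shift artifacts) makes every stage testable without data
downloads, and the study's printed per-participant tables ship as fixtures.

## Worked example

Reproduce the published statistics from the packaged fixtures:

```bash
nirsfusion reproduce --outdir reproduction
```

prints

```
Friedman statistic = 24, p = 6.1e-06
significant channels: CH12, CH13, CH14
  CH12: W = 3, corrected p = 0.01139, d = 1.09, power = 0.93
  CH13: W = 1, corrected p = 0.00684, d = 1.28, power = 0.98
  CH14: W = 1, corrected p = 0.00684, d = 1.36, power = 0.99
reproduction OK: all published values matched
```

Reading: across 12 participants the mean connectivity strength differs
strongly between conditions (Friedman χ²_F = 24 is the maximum attainable
at n = 12, k = 3 — every participant showed fusion > rivalry > gray), and
channel-wise comparison of the fusion vs. rivalry GLM coefficients leaves
exactly three channels significant after FDR correction: CH12 (dorsolateral
prefrontal cortex) and CH13/CH14 (frontal eye fields), with large paired
effect sizes (d ≈ 1.1–1.4) and post-hoc power ≥ 0.92 at n = 12.

The same stages run on synthetic sessions:

```bash
nirsfusion simulate --protocol exp1 --seed 7 --out-prefix session
nirsfusion preprocess --raw session.csv --events session.events.tsv --out hemo.csv
nirsfusion fc --hemo hemo.csv --events session.events.tsv --out fc.csv
```

or from Python:

```python
import nirsfusion as nf

protocol = nf.make_protocol_exp1()
rec = nf.simulate_session(protocol, nf.SubjectParams(), seed=7)
hemo = nf.run_preprocess(rec)
for res in nf.condition_connectivity(hemo, protocol):
    print(res.condition, round(res.mean_strength, 3))
# GRAY 0.559  FORG 0.949  RORG 0.843   (fusion > rivalry > gray)
```

## Layout

- `src/nirsfusion/synthetic.py` — protocols and the forward model
- `src/nirsfusion/preprocess.py` — Exclude → Motion → Filter → Hemo
- `src/nirsfusion/connectivity.py` — Pearson FC matrices and r̄
- `src/nirsfusion/glm.py` — HRF, design matrices, per-channel OLS
- `src/nirsfusion/stats.py` — Friedman, exact Wilcoxon, BH-FDR, d, power
- `src/nirsfusion/rt.py` — reaction-time analysis
- `src/nirsfusion/io.py`, `cli.py`, `fixtures.py`, `reproduce.py` — I/O,
  command line, packaged tables, golden-value reproduction

See `docs/methods.md` for the modeling choices and their rationale.
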