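# neoms — microstate analysis of neonatal sleep EEG

`neoms` implements the full EEG **microstate** analysis pipeline for
neonatal sleep recordings: from multichannel scalp EEG epochs tagged with a
sleep state — active sleep (AS) or quiet sleep (QS) — to dominant microstate
templates, microstate sequences and metrics, transition-syntax statistics,
topographic comparisons and narrow-band frequency-scaling analysis.  It is
aimed at researchers studying large-scale brain dynamics in newborns (and
anyone who wants a tested, scriptable microstate pipeline on plain-text or
EDF inputs).

## The method

A microstate is a brief period (tens to hundreds of ms) during which the
scalp potential topography stays quasi-stable.  The pipeline follows the
standard peak-based approach:

1. **Preprocessing** — 0.15–45 Hz zero-phase Butterworth band-pass
   (7th-order high-pass + low-pass cascade, forward–backward),
   down-sampling to 100 Hz, common-average reference.
2. **Global field power (GFP)** — the spatial standard deviation at each
   sample, `GFP_t = sqrt(Σ_j (v_jt − v̄_t)² / C)`; its local maxima are the
   moments of highest topographic signal-to-noise.
3. **Template identification** — two-step polarity-invariant modified
   k-means on GFP-peak topographies (maps are assigned by maximal squared
   spatial correlation r²; templates are re-estimated as the dominant
   eigenvector of the assigned maps' outer-product sum), first per subject
   and then across subjects.  The number of templates K is selected with
   the Krzanowski–Lai (KL) criterion on the dispersion curve
   `W(k)`, with `KL(k) = |DIFF(k)/DIFF(k+1)|`,
   `DIFF(k) = (k−1)^{2/C} W(k−1) − k^{2/C} W(k)`.
4. **Backfitting** — each GFP peak takes the template with the highest
   |r|; samples between peaks inherit the nearest peak's label.  Outputs:
   global explained variance `GEV = Σ (GFP_t r_t)² / Σ GFP_t²`, and per
   template the mean **duration** (ms), **occurrence** (runs/s) and
   **coverage** (%).
5. **Syntax** — observed transition probabilities `P_{X→Y}` on the run
   sequence vs the occurrence-driven expectation
   `P*_{X→Y} = P_X P_Y / (1 − P_X)`, summarized by the chi-square distance
   `D = Σ (P_{X→Y} − P*_{X→Y})² / P*_{X→Y}` with an observed/expected
   label-swap randomization test, plus per-pair directional predominance
   `P_{X→Y} − P_{Y→X}` (FDR-corrected one-sample t-tests).
6. **Topography** — global dissimilarity
   `GD(u,v) = sqrt(1/N Σ (u_i/GFP_u − v_i/GFP_v)²)` (for zero-mean maps
   `GD² = 2(1−r)`), and TANOVA: a permutation test on the GD between
   group-mean normalized maps.
7. **Narrow bands** — the whole pipeline re-run in delta (0.5–4 Hz), theta
   (4–8), alpha (8–13), beta (13–25) and gamma (25–45 Hz), with log–log
   regression of band-mean metrics on band midpoint frequency (a slope of
   −1 for duration means duration ∝ 1/f).
8. **Group statistics** — two-way repeated-measures ANOVA
   (sleep state × template) with Greenhouse–Geisser correction and partial
   η², Bonferroni paired post-hocs, Benjamini–Hochberg FDR.

Because no suitable neonatal cohort is publicly deposited, the package
ships a synthetic-cohort generator (`neoms.synthetic`) that plants known
templates, a first-order Markov syntax, duration laws and 1/f^α noise, so
every stage is validated by recovery experiments with known ground truth.

## Worked example

```python
import numpy as np
from neoms import (default_scenario, two_step_cluster, cohort_metrics,
                   transition_stats, randomization_test)

# simulated two-state cohort: 5 subjects, shared templates, QS slower than AS
cohort = default_scenario(seed=7, n_subjects=5, epoch_length_s=30.0, k=4)
templates = two_step_cluster(cohort.epochs, k=4, n_restarts=10, seed=0)
metrics, gev, labelings = cohort_metrics(cohort.epochs, templates)

print(metrics.groupby(["state_tag", "template"])[
    ["duration_ms", "occurrence_hz", "coverage_pct"]].mean().round(1))
print(f"\nmean GEV: {gev.gev_pct.mean():.1f}%")

stats = [transition_stats(l) for l in labelings if l.state_tag == "AS"]
res = randomization_test(stats, n_reps=5000, seed=1)
print(f"AS syntax: D = {res.chi_square_distance:.4f}, "
      f"p = {res.p_value:.3f} ({res.n_randomizations} randomizations)")
```

prints

```
                    duration_ms  occurrence_hz  coverage_pct
state_tag template
AS        A               109.8            2.3          24.9
          B               110.3            2.2          24.0
          C               109.2            2.5          27.5
          D               108.8            2.2          23.6
QS        A               151.2            1.6          24.1
          B               155.3            1.6          25.5
          C               150.1            1.7          25.3
          D               147.2            1.7          25.2

mean GEV: 98.1%
AS syntax: D = 0.0022, p = 0.805 (5000 randomizations)
```

The planted AS/QS mean durations were 110 ms and 150 ms: the recovered
table reproduces both the values and the AS/QS ordering (longer duration,
lower occurrence in QS), the templates explain ~98% of the GFP-weighted
topographic variance at this SNR, and the syntax test correctly finds no
transition structure (the scenario's planted chain is occurrence-driven).

The same stages are scriptable from the shell via the `neoms` CLI
(`neoms simulate`, `neoms preprocess`, `neoms cluster`, `neoms run
--config study.yaml` for the full orchestrated pipeline).

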