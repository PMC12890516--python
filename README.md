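# myofiber

Analysis toolkit for two complementary readouts of skeletal-muscle myofiber
state:

1. **Myosin relaxed-state kinetics** from Mant-ATP chase experiments.
   Resting myosin heads populate two biochemical states — the
   disordered-relaxed state (DRX, "ON", fast ATP turnover) and the
   super-relaxed state (SRX, "OFF", ~10-fold slower).  The normalized
   fluorescence decay of chased Mant-ATP is fitted with the two-state model

   ```
   F(t) = 1 − P1·(1 − e^(−t/T1)) − P2·(1 − e^(−t/T2)),   T1 < T2
   ```

   giving the DRX/SRX amplitudes P1, P2 (%) and turnover time constants
   T1, T2 (s).  From these the package scores a theoretical myosin ATP
   consumption per cell, assuming 220 μM intrafiber myosin:

   ```
   ATP = P1/100 · 220 · 60/T1  +  P2/100 · 220 · 60/T2     [μM·min⁻¹]
   ```

   (a `verbatim` variant dividing both terms by T1 is also provided; see
   `docs/methods.md`).

2. **Single-fiber proteomics**: equal-total-abundance normalization,
   missingness filtering, mixed KNN/MinProb imputation for left-censored
   (MNAR) intensities, per-protein t-tests with Benjamini–Hochberg FDR and a
   fold-change gate, restoration-set logic for treatment designs
   (maintained / restored / emergent / discordant hits), hypergeometric
   enrichment, PCA summaries, and MYH-based fiber typing (≥80% purity rule).

A synthetic-data module generates decay cohorts (subjects within groups,
fibers within subjects) and abundance matrices (group effects, treatment
restoration, abundance-dependent missingness) with ground truth, so every
stage is testable without instrument data.

Intended users: muscle physiologists quantifying DRX/SRX populations and
proteomics analysts working with small-n single-fiber designs (myopathy
models, pharmacological ON/OFF-state modulation).

## Worked example

```python
import myofiber as mf

# one noisy decay trace on the standard 40-frame grid (0–90 s every 5 s,
# then every 10 s to 300 s), generated from known parameters
trace = mf.gen_decay_trace(28, 37, 20, 190, noise_sd=0.01, seed=42)

fit = mf.fit_double_exponential(trace)
atp = mf.theoretical_atp_consumption(fit)
print(f"P1 = {fit.p1:.1f}%  T1 = {fit.t1:.1f} s   (DRX)")
print(f"P2 = {fit.p2:.1f}%  T2 = {fit.t2:.1f} s  (SRX)")
print(f"ATP consumption = {atp.value:.1f} uM/min per cell")
```

prints

```
P1 = 27.8%  T1 = 19.0 s   (DRX)
P2 = 37.7%  T2 = 196.0 s  (SRX)
ATP consumption = 218.3 uM/min per cell
```

i.e. ~28% of myosin heads sit in the fast-turnover DRX state (19 s time
constant), ~38% in the slow SRX state (196 s), and the fitted amplitudes and
rates combine to ≈218 μM ATP consumed per minute in the fiber — close to the
generating truth (28 / 37 / 20 / 190).

The same analysis runs from the shell:

```sh
myofiber simulate cohort --out-dir cohort --seed 1
myofiber fit --traces cohort/traces.tsv --out-dir fits
myofiber stats --fits fits/fits.full.tsv --out comparisons.tsv
```

`fits/fits.tsv` holds one row per fiber (P1, P2, T1, T2, plateau, rss,
convergence flag, ATP score in both variants); `comparisons.tsv` reports
Welch / ANOVA+Tukey contrasts at both the fiber and the subject-average
level.  The proteomics arm is the `myofiber proteome` subcommand
(`--case/--control/--treated-case` plus optional `--annotation`), and
`myofiber simulate matrix` produces a matching synthetic input.

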