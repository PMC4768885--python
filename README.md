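# trapcam

Fly detection on trap-surface camera imagery and the statistics of
attractant-trap capture efficiency.

Attractant-based traps — for instance Jackson traps baited with trimedlure
for the Mediterranean fruit fly *Ceratitis capitata* — are the backbone of
pest detection and eradication programmes. A trap's usefulness is the
product of its attraction (does it bring flies in?) and its capture
efficiency (does it keep the flies that arrive?). `trapcam` implements a
complete, testable workflow for studying that second quantity from
trap-surface camera sequences and replicate capture counts:

- **synthetic trap-camera simulator** — 640×480 8-bit grayscale sequences
  at one frame per 6 s: a textured static background, optional linear
  illumination drift and Gaussian pixel noise, and flies rendered as dark
  ellipses whose occupancy follows a per-frame birth–death process. Every
  rendered blob is recorded as ground truth, so the detector can be
  benchmarked without manual annotation. A companion generator produces
  replicate capture tables from overdispersed (negative-binomial) counts.
- **detection pipeline** — scene model as a linearly weighted average of a
  50-frame window (weights rising toward the most recent frame), absolute
  difference imaging, 8-bit conversion, Otsu (or fixed) thresholding,
  binary opening + closing with a 3×3 element, and 8-connected particle
  analysis with an inclusive 150–950 px area gate.
- **validation metrics** — fraction of images where the automatic count is
  within 1 (and within 3) of the manual count, and the Pearson correlation
  between the two, overall and per group, with a t-transform significance
  test.
- **capture statistics** — column Mean±SD summaries (n−1 denominator),
  one-way ANOVA of ln(x+1) counts between treatments, two-way ANOVA
  (bait × surface, with interaction; Type I on balanced designs, Type II
  flag for unbalanced), Fisher LSD post-hoc comparisons, and a one-sample
  Kolmogorov–Smirnov normality check.

A seven-replicate Jackson-trap capture-count dataset (trimedlure only,
trimedlure + DDVP insecticide strip, and unbaited control) ships with the
package as `trapcam.load_capture_counts()`.

## Worked example

```python
import trapcam as tc

table = tc.load_capture_counts()
summary = tc.summarize(table)
print(tc.format_mean_sd(summary, "tml_trapped"))      # 324.1±134.7
print(tc.format_mean_sd(summary, "tml_ddvp_in_tub"))  # 91.6±53.4

for response in ("trapped", "in_tub", "total"):
    a = tc.log1_transform(table[f"tml_{response}"])
    b = tc.log1_transform(table[f"tml_ddvp_{response}"])
    tab = tc.one_way_anova(a, b)
    print(response, round(tab.loc["treatment", "F"], 2),
          round(tab.loc["treatment", "p"], 3))
# trapped 0.43 0.524
# in_tub 6.73 0.023
# total 1.5 0.244
```

Reading: the sticky-panel catch and the combined total do not differ
between the two baited arms (F(1,12) = 0.43 and 1.50), but significantly
more flies are found dead in the tub under the insecticide trap
(F(1,12) = 6.73, p ≈ 0.02) — flies killed by the vapour before they reach
the sticky panel, i.e. a loss of capture efficiency rather than a gain.

The detection side on synthetic imagery:

```python
config = tc.SimConfig(n_frames=200, arrival_rate=0.1, departure_rate=0.05,
                      noise_sd=0.0, seed=42)
stack, truth = tc.generate_image_sequence(config)
counts = tc.count_flies(stack)
print((counts["count"].to_numpy() == truth.counts).mean())  # 1.0
```

On a noiseless static scene the pipeline recovers the true per-frame count
in 100% of frames; with pixel noise of 4 intensity units agreement stays
above 95%. The `examples/` directory holds one short narrative script per
capability, and a thin CLI (`trapcam simulate|detect|validate|stats|all`)
wraps the same functions for shell use.

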