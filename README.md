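# lfaquant

Quantification of smartphone-imaged lateral-flow assays (LFAs) and dot
blots, for assay developers who need numbers — not just a visible
line — from cheap fluorescence or colloidal-gold readouts.

A lateral-flow strip reports a sandwich immunoassay: capture antibody
on nitrocellulose binds the analyte, a labelled detection reagent binds
on top, and the test zone's signal grows with concentration until the
prozone (hook) regime, where excess analyte saturates both binders
separately and the signal collapses. `lfaquant` implements the full
densitometric analysis chain for such images, plus a seeded synthetic
image generator with ground truth to validate every stage:

* **Quantification** — channel selection (red for fluorescence, green
  for gold), automatic zone detection, baseline from flanking column
  averages, total signal over (or under) baseline, exposure scaling.
* **Calibration** — per-concentration means, prozone screening (drop
  post-peak concentrations whose mean falls >10% below the peak), and
  the log-log power fit `y = a·c^b` with fold change
  `(c_high/c_low)^b` over a stated range.
* **S/NSB** — the signal-to-nonspecific-binding slope ratio: paired
  dilution series of dye spots vs dye-soaked blocked strips, one OLS
  slope each, ratio unitless and detector-independent — a dye quality
  metric for choosing reporters.
* **Photobleaching** — log-linear decay fit, `t½ = ln 2 / k` with `k`
  the negative slope of ln(signal) vs time.

## Worked example

```python
import lfaquant as lq

# Simulated R-PE fluorescence titration: four-fold series
# 0.063 -> 16,515 ng/mL, triplicate, default camera noise.
res = lq.run_dose_response_experiment(seed=1)
fit = res["power_fit"]
print(fit.excluded)           # ((16515.072, 'prozone'),)
print(round(fit.b, 4))        # 0.7285
print(round(res["fold_change"], 1))  # 820.1

sn = lq.run_snsb_experiment("rpe", seed=1)
print(round(sn["ratio"], 2))  # 56.45   (generative truth: 50)

bl = lq.run_bleach_experiment("rpe", seed=1, noiseless=False)
print(round(bl["half_life_s"], 1))  # 2034.4  (generative truth: 2000 s)
```

Reading the output: the prozone screen excluded exactly the top
concentration of the series (16,515 ng/mL), the calibration exponent
`b ≈ 0.73` gives a fitted signal ratio of ≈820 between 4,000 and
0.4 ng/mL, the recovered S/NSB ratio for the R-PE fixture is within
~13% of its generative value on this single seed, and the
photobleaching half-life is recovered within ~2% from a noisy 30-frame
stack.

The same pipeline runs from the shell:

```bash
lfaquant simulate --fixture rpe_default --seed 1 --out run/imgs
lfaquant quantify --images run/imgs --out run/quant.csv
lfaquant series   --quant run/quant.csv --out run/series.json
lfaquant --show-config   # all defaults as JSON
```

Subcommands `snsb`, `bleach` and `report` cover the other experiments;
every command writes CSV/JSON artifacts and exits nonzero with an error
JSON on failure. Images are PNG/TIFF with JSON metadata sidecars; all
concentrations are ng/mL.

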