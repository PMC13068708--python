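# durdisc

Simulation and analysis of two-interval visual duration-discrimination
studies, focused on stimulus-order effects on discrimination sensitivity
(Type B effects: `DL_sc - DL_cs`).

The package provides:

- **`durdisc.models`** — generative observer models: the Thurstonian
  difference model (`D = X1 - X2`), the internal-reference model
  (`I_n = g*I_{n-1} + (1-g)*X1_n`, `D_n = I_n - X2_n`), and the
  sensation-weighting model (`D = [s1*X1 + (1-s1)*R1] - [s2*X2 + (1-s2)*R2]`),
  all with normal sensory noise `sigma(d) = sigma0 + weber*d` and the
  closed-form psychometric function of the difference observer.
- **`durdisc.designs`** — method-of-constant-stimuli session builder
  (9 comparison levels x 2 orders x 2 repetitions x 20 blocks = 720 trials;
  80 and 500 ms standard presets) and a weighted up-down staircase engine
  targeting the .25/.75 points, including the bias-prone dialect options
  (floor at 0 ms, prohibition of crossing the standard, blocked runs,
  reversal-mean or last-20 estimation) and trial-wise interleaved tracks.
- **`durdisc.estimation`** — psychometric tables, weighted
  pool-adjacent-violators monotonization, the Spearman-Kärber PSE/SD/DL/WF
  estimator with anchor assumptions (0/160 ms short, 200/800 ms long),
  quartile-based DL, and Type B effects.
- **`durdisc.inference`** — balanced repeated-measures two-way and one-way
  ANOVAs with Mauchly-gated Greenhouse-Geisser correction and partial eta
  squared, a 2x2x2 mixed ANOVA (one within, two between factors), and
  noncentral-F power analysis for two-level within designs.
- **`durdisc.synthetic_data`** — full synthetic cohorts (40 observers, both
  duration regimes, flat-function exclusion with replacement, ANOVA battery),
  the staircase-bias study (blocked staircases vs. constant stimuli on the
  same observers), and grid-search recovery of the internal-reference weight
  `g` via a composite marginal likelihood.
- **`durdisc.cli_io`** — versioned CSV trial serialization and the `durdisc`
  command-line interface.

## Command-line usage

```sh
# simulate a 40-observer internal-reference cohort (both regimes, 720 trials each)
durdisc simulate --preset E1 --model irm --n 40 --seed 1 --out run1

# Spearman-Kärber estimates and the ANOVA battery from the trial file
durdisc estimate --trials run1/trials.csv --out run1
durdisc analyze  --trials run1/trials.csv --out run1

# staircase bias demonstration (short standard, bias-prone dialect)
durdisc bias-study --n 200 --g 0.5 --standard 50 --seed 1 --out bias1

# recover g from simulated trials; power of the design
durdisc recover --trials run1/trials.csv --g-step 0.05
durdisc power --eta2 0.08 --n 40 --alpha 0.05
```

Every subcommand writes a `run_manifest.json` with the resolved
configuration next to its outputs; runs are reproducible from the seed.

## Key simulation results reproduced on synthetic observers

- Internal-reference observers produce null Type B effects at `g = 0` and
  increasingly negative Type B effects as `g` grows; they cannot produce
  positive ones (`tests/test_acceptance.py::TestCriterion4ModelSigns`).
- Sensation-weighting observers produce Type B effects with the sign of
  `s2 - s1`.
- The blocked weighted up-down dialect (very short standard, floor at 0 ms,
  crossing prohibition, last-20 estimation) yields **non-negative mean Type B
  estimates** for internal-reference observers whose constant-stimuli
  Spearman-Kärber Type B effect is clearly negative — the staircase artifact
  under study (`TestCriterion5StaircaseBias`). With trial-wise interleaved
  tracks the staircase recovers the negative effect.
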