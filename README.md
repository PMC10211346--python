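# betapipe

Sensor-level analysis pipeline for beta-band (16–30 Hz) MEG power during
explorative vs. exploitative choices in a two-alternative probabilistic
reward task — driven entirely by a synthetic-data generator, so the whole
analysis chain is testable end to end without recordings.

Stages:

1. **Task & agent simulation** (`betapipe.task_sim`) — 6 blocks × 40 trials,
   70/30 (blocks 1–5) and 60/40 (block 6) gain probabilities, six point
   schemes, quasirandom outcome sequences with exact gain counts and a run
   cap; a two-phase agent (learning, then stable exploitation with rare
   isolated explorative choices) with log-normal, choice-type-dependent RTs.
2. **Trial taxonomy** (`betapipe.taxonomy`) — learning criterion (a run of 4
   advantageous choices, then >65% advantageous), the HP / pre-LP / LP /
   post-LP choice-type classification, RT exclusion (<300 ms, >4000 ms),
   feedback and previous-feedback factors.
3. **Synthetic epochs** (`betapipe.synth_meg`) — 102 combined-sensor
   response-locked epochs (−1750…2750 ms at 300 Hz) of band-limited noise
   whose amplitude envelope carries configurable condition-dependent
   ERD/ERS effects, plus fixation-locked baseline epochs.
4. **Beta power** (`betapipe.tfr`) — DPSS multitaper band power (n_cycles =
   f/2 → 500-ms windows; time-bandwidth 4 → 8-Hz smoothing; 25-ms steps),
   planar-gradiometer pair combination, 10·log10 transform, and a fixed
   per-subject baseline from the HP fixation window (−350…−50 ms).
5. **Mass screening** (`betapipe.screen`) — 17 × 200-ms frames, per-cell
   mixed models (power ~ ChoiceType × Feedback + (1|subject)),
   Benjamini–Hochberg FDR over the 1,734-cell grid, persistence-based
   cluster extraction with neighbor pruning, ERD/ERS splitting.
6. **Effect models** (`betapipe.effects`) — pooled-window mixed models with
   Tukey HSD contrasts, the RT model, the beta~RT regression, the
   previous-feedback triple-interaction model, and the LP-loss → post-LP
   cross-trial regression.

The mixed-model engine (`betapipe.lmm`) is a fast profiled-REML
random-intercept fitter with sum-coded Type-III Wald F tests and
studentized-range (Tukey) contrasts on estimated marginal means; it is
validated against statsmodels/scipy oracles in the test suite.

## CLI

```bash
betapipe run --config config.yaml --out-dir out/        # end to end
betapipe simulate --out-dir out/                        # behavior (+epochs)
betapipe label --trials raw.tsv --out labeled.tsv       # taxonomy only
betapipe tfr --epochs-dir out/epochs --trials out/trials_labeled.tsv --out frames.h5
betapipe screen --frames frames.h5 --trials labeled.tsv --out screen.json
betapipe effects --frames frames.h5 --trials labeled.tsv --screen screen.json --out result.json
betapipe report --run-dir out/                          # topomaps + markdown
```

All parameters (task, agent, effect templates, multitaper settings,
windows, FDR level, seeds) live in one YAML `RunConfig`; a single master
seed makes runs byte-reproducible.

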