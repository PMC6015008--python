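# pupilswitch

Analysis pipeline for infant switch-paradigm pupillometry: from raw
120-Hz binocular gaze samples to time-resolved novelty effects, together
with a synthetic-session generator so that every stage is testable
without any recordings.

The paradigm: infants are familiarized with two audiovisual pairings and
then tested with *familiar* trials (learned pairings), *switched* trials
(learned features, recombined) and a *novel* trial (new features). Pupil
diameter is analyzed time-locked to the sound onset of each 8000-ms test
trial; looking time is summarized per familiarization block and per test
condition.

## Components

| module | role |
|---|---|
| `pupilswitch.synth` | synthetic cohorts: participant baselines, gamma-shaped dilation components (fast perceptual-novelty, slow association-novelty), Poisson/exponential blink gaps, two-state looking model |
| `pupilswitch.io` | gaze TSV dialect (one row per sample, validity flags, provenance header), trial assembly, schema adaptation for foreign exports |
| `pupilswitch.preprocess` | inclusion (<40% missing), linear gap interpolation, zero-phase 4-Hz Butterworth low-pass, binocular averaging, 1000-ms pre-sound baseline correction, 50-ms binning (86 bins), per-condition aggregation |
| `pupilswitch.looking` | proportion of looking time, familiarization block-1-vs-4 paired t, three-condition RM-ANOVA + planned one-tailed comparisons |
| `pupilswitch.stats` | per-bin repeated-measures ANOVA with partial eta-squared, consecutive-bin rule, Bonferroni post-hoc paired t, Hedges' g\_av / g\_s, max-cluster-mass Monte-Carlo permutation correction |
| `pupilswitch.cli` | `simulate` / `preprocess` / `looking` / `analyze` / `run-all` subcommands with config, logging and a checksummed run manifest |

## CLI

```bash
# end-to-end: simulate -> preprocess -> looking + analyze (+ figures)
pupilswitch run-all --seed 7 --outdir out/

# or stage by stage
pupilswitch simulate --config config.yaml --out gaze.tsv
pupilswitch preprocess --in gaze.tsv --out timecourse.tsv --report qc.json
pupilswitch looking --in gaze.tsv --out looking_summary.tsv
pupilswitch analyze --timecourse timecourse.tsv --n-perm 1000 --seed 7 \
    --out results.json --plot-prefix figs/run
```

`analyze` reports, per age group: the per-bin F / p / eta_p^2 table with
the consecutive-bin rule applied, and the supra-threshold clusters of the
omnibus and pairwise contrasts with their Monte-Carlo p-values. All
stages are deterministic under the config seed; `run-all` writes a
manifest with output checksums and per-stage counts.

Foreign gaze exports can be read by passing `--schema schema.yaml`, a
mapping from the canonical column names to the file's column names.

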