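# wheezecount

Breath-cycle and wheeze-event counting from lung-sound recordings.

A segment classifier (1-D CNN + bidirectional LSTM, implemented in pure
numpy) labels every 25-ms slice of audio as **break**, **normal** or
**wheeze** from its 128-band Mel spectrum. Two counters turn the resulting
probability stream into breath and wheeze totals:

* an **offline** counter that finds label peaks, groups them into breath
  cycles by peak spacing (≥ 100 segments ≈ 1 s), and flags a cycle as
  wheezing when its mean peak height exceeds 1;
* a **streaming** counter — a hysteresis state machine fed 0.5-s chunks: a
  run of 3 confident wheeze segments arms a toggle, a run of 3 confident
  break segments releases it and counts one wheeze event. State persists
  across chunks, so results are independent of how the audio is chunked.

A built-in lung-sound simulator generates recordings with known breath
structure (band-filtered noise breaths, optional frequency-modulated tonal
wheezes, silent pauses) plus ground-truth label tracks, so the whole
pipeline is testable without any external data.

## Command line

One entry point with subcommands (see `wheezecount --help`):

```bash
# synthesize a labeled recording (WAV + Audacity label TSV + truth JSON)
wheezecount --seed 7 simulate --out-dir sim --n-breaths 10 --wheeze-prob 0.5

# Mel features + hard labels (optionally pitch-shift augmented / denoised)
wheezecount features --wav sim/recording.wav --labels sim/labels.txt --out feat.npz

# unshuffled k-fold cross-validation; saves the best checkpoint
wheezecount train --features feat.npz --checkpoint ckpt --epochs 10 --folds 5

# offline counting (from a WAV + checkpoint, a probability CSV, or
# oracle one-hot probabilities derived from a label track)
wheezecount count --wav sim/recording.wav --checkpoint ckpt --out report.json
wheezecount count --labels sim/labels.txt --oracle --out report.json

# streaming replay at 0.5-s cadence with running counts
wheezecount stream --wav sim/recording.wav --checkpoint ckpt --out stream.json

# accuracy / F1 / one-vs-rest ROC-AUC / confusion matrices (+ trace plot)
wheezecount evaluate --features feat.npz --checkpoint ckpt --out metrics.json --plot traces.png
```

All tunables live in a YAML config (`--config file.yaml`) with
command-line flags taking precedence; unknown keys are rejected.

## Layout

| Module                      | Role |
|-----------------------------|------|
| `wheezecount.audio_io`      | WAV and Audacity label-track I/O, resampling |
| `wheezecount.synthetic`     | lung-sound simulator with ground truth |
| `wheezecount.preprocess`    | framing, Mel features, hard labels, pitch-shift augmentation, spectral gating |
| `wheezecount.model`         | CNN–BiLSTM segment classifier (numpy), unshuffled k-fold CV |
| `wheezecount.counting`      | offline and streaming counters |
| `wheezecount.evaluation`    | metrics, confusion matrices, rate comparison |
| `wheezecount.cli`           | `wheezecount` command |
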