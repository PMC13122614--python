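# wingradar

Simulation, detection and hierarchical taxonomic classification of insect
wingbeat micro-Doppler signatures from continuous-wave (CW) mmWave radar.

## The problem

Flying insects modulate a reflected CW radar signal with their wingbeats.
After quadrature down-conversion the received baseband I/Q signal decomposes
as

```
A(t) e^{jφ(t)} = s_noise(t) + s_body(t) + s_wingbeat(t)
```

where `s_body` is slow (< 50 Hz) Doppler from gross body motion and the
wingbeat component is a harmonic series of the fundamental wingbeat
frequency `f_w`:

```
s_wingbeat(t) = Σ_{n=1..N} A_n exp(j(2π n f_w t + φ_n))
```

Because wingbeat rate and harmonic envelope are species-dependent, this
harmonic structure carries taxonomic information.  `wingradar` implements
the full analysis chain for five focal hymenopteran pollinators
(*Vespula vulgaris*, *Apis mellifera*, *Bombus lapidarius*,
*B. muscorum*, *B. terrestris*):

1. **synthradar** — a seeded simulator producing labeled I/Q recordings
   with the structure above (flight bouts, per-subject `f_w` draws), so
   every downstream stage is testable without field data;
2. **preprocess** — per-recording normalization, a second-order Chebyshev
   high-pass at 50 Hz, and overlapping 2 s Hann frames (1 s overlap);
3. **detection** — the harmonic ratio `η_HR = max_{k∈[K0,K]} Ψ(k)`, the
   maximum of the normalized autocorrelation over lags from the first zero
   crossing `K0` up to `K = 0.04·Fs` (40 samples at 1 kHz); frames with
   `η_HR > 0.4` are retained as micro-Doppler segments;
4. **features** — exactly 70 named features per segment: 14 MFCCs with
   deltas and delta-deltas, three fundamental-frequency estimators
   (`PEF_F0`, `WT_F0`, `NCF_F0`), the harmonic ratio, nine 50 Hz band-power
   fractions, and fifteen spectral/temporal descriptors;
5. **cascade** — subject-grouped 80/20 split, class weights, then a
   three-stage hierarchy: gradient boosting for family (Vespidae finalizes
   to *V. vulgaris*), gradient boosting for genus within Apidae (*Apis*
   finalizes to *A. mellifera*), extremely-randomized trees for the three
   *Bombus* species; per-class precision/recall/F1
   (`F1 = 2PR/(P+R)`), cumulative confusion matrices and a
   signal-duration sweep (2 s down to 0.1 s);
6. **attribution** — exact interventional Shapley values: a brute-force
   coalition-enumeration oracle plus a closed-form per-leaf algorithm for
   the tree ensembles, with feature rankings by mean |attribution|.

## Worked example

```python
import wingradar as wr

# 1. simulate a labeled cohort: 5 species x 4 subjects, 60 s at 1 kHz
recordings, manifest = wr.generate_cohort(
    wr.DEFAULT_PROFILES, n_subjects_per_species=4, seed=7)

# 2. detect wing-flap segments (harmonic ratio > 0.4 on 2 s Hann frames)
segments = [s for rec in recordings for s in wr.run_detection(rec)]
print(f"{len(segments)} segments retained from {len(recordings)} recordings")

# 3. 70-feature table, subject-grouped 80/20 split, cascade fit + evaluate
dataset = wr.build_dataset(segments)
train, test = wr.subject_grouped_split(dataset, wr.SplitSpec(seed=1))
model = wr.fit_cascade(train, wr.CascadeConfig(seed=1))
pred = wr.predict_cascade(model, test.X)
report = wr.evaluate(pred["species"].to_numpy(), test.species)
print(report.accuracy)

# 4. Shapley feature ranking over 20 test rows
results, _ = wr.cascade_attributions(model, test.X[:20], train.X,
                                     max_background=50, seed=1)
print(wr.rank_features(results, top=5).to_string(index=False))
```

prints

```
410 segments retained from 20 recordings
{'species': 1.0, 'genus': 1.0, 'family': 1.0}
          feature  mean_abs_attribution
    peakFrequency              0.058109
           NCF_F0              0.055382
           PEF_F0              0.055314
bandPower_100_150              0.052570
            WT_F0              0.050441
```

All 410 two-second segments come from the scheduled flight bouts; the
held-out subjects (one per species) are classified perfectly because the
five synthetic species are well separated in fundamental frequency
(120–300 Hz) and harmonic envelope, and the attribution ranking confirms
that wingbeat-frequency features drive the species decision.

A `wingradar` CLI wraps the same steps
(`simulate`, `detect`, `extract`, `train`, `evaluate`, `sweep`, `explain`);
run `wingradar --help`.

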