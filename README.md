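# wristpd

Digital-biomarker analysis of wrist-worn accelerometry in Parkinson's
disease (PD), built for researchers evaluating whether consumer-grade
wearables plus symptom diaries can quantify motor symptoms.  The package
re-implements a complete home-monitoring analysis chain as a tested,
reusable pipeline driven by a synthetic-data generator with known ground
truth, so every stage is verifiable without access to clinical
recordings.

The chain:

1. **Blocks** — 50 Hz tri-axial recordings are cut into 65536-sample
   blocks (21.8 min) with a half-block hop ("double cover"); blocks with
   timestamp gaps or clock drift are rejected and accounted.
2. **Spectra** — per block, log-binned dB power spectra (eleven
   log-spaced bins, 0.25–25 Hz) on the device axes (x, y, z), on
   gravity-aligned channels (g, dg, ddg from a causal 0.1 Hz low-pass
   gravity estimate), and on rotation-invariant principal-oscillation
   channels (per-frequency singular values of [Re c, Im c]).
3. **Cohort separation** — per (channel, bin) Welch z-score over pooled
   blocks, `z = (m_P - m_C)/sqrt(v_P/n_P + v_C/n_C)`, plus
   leave-one-subject-out L2-logistic classification with Mann–Whitney
   AUC on x-channel subject-mean spectra.
4. **Symptom envelopes** — diary events (tremor vs other; durations > 2 h
   rejected) are centred on their midpoints and the surrounding
   time x frequency x channel tensor of log-amplitudes is fitted with the
   rank-1 factorial model `L_itfc ~ N(u_t v_f w_c + b, sigma^2)` by
   alternating least squares, yielding temporal (u), spectral (v) and
   channel (w) symptom envelopes.
5. **Accelerometer scores** — per symptom (tremor, bradykinesia,
   dyskinesia), an L2-regularised proportional-odds regression maps
   spectral features of task replicates to 0–4 observer scores; the
   standardised linear predictor is the "accelerometer score", and a
   mixed model (task x drug fixed effects, subject/session random
   intercepts) with subject-level bootstrap gives per-task ON–OFF
   levodopa contrasts.
6. **VAE movement states** — a fully connected variational autoencoder
   (1500-400-20, symmetric decoder, NumPy implementation) embeds 10-s
   windows; an MLP(50, 50) classifies movement tasks from the 20-dim
   latent means under subject-grouped five-fold CV and under
   cross-cohort transfer.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

The numbered drivers under `analysis/` run the studies end to end and
write their tables under `results/`:

```bash
python analysis/03_cohort_separation.py
```

prints (seed 1, the default):

```
largest |z| = 20.6 on channel x in the bin centred at 5.78 Hz
leave-one-subject-out AUC = 1.000
```

meaning: on the default scenario (8 patients with injected 5 Hz tremor
and mild constitutive motor load, 8 controls, 8 h each) the strongest
patient-vs-control spectral contrast falls exactly in the frequency bin
containing the tremor, and held-out per-subject classification from the
x-channel spectrum alone separates the cohorts.

```bash
python analysis/05_ordinal_scoring.py
```

prints:

```
tremor        ON-OFF delta -1.06 [-1.40, -0.68]
bradykinesia  ON-OFF delta -1.16 [-1.27, -0.97]
dyskinesia    ON-OFF delta +0.93 [+0.80, +1.05]
```

the levodopa polarity recovered from accelerometer scores alone: tremor
and bradykinesia scores drop in the ON state, dyskinesia rises, with
bootstrap CIs excluding zero (scores are standardised, so deltas are in
within-study SD units).

```bash
python analysis/06_vae_movement_states.py
```

prints:

```
windows: 3240, chance 0.167
within-cohort grouped five-fold accuracy: 0.636
same-family confusion 0.226 vs cross-family 0.050
cross-scenario transfer accuracy: 0.298
```

task identity is recoverable from the 20-dim VAE embedding well above
chance, misclassifications cluster within movement families (walking vs
its variant, sitting vs standing), and the representation transfers to a
freshly generated cohort.

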