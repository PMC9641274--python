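# thzburn

Wavelet-packet entropy analysis of terahertz time-domain burn imaging.

## The problem

The clinical assessment of burn depth — superficial partial-thickness
(SPT), deep partial-thickness (DPT) or full-thickness (FT) — and the early
prediction of whether a wound will re-epithelialise are notoriously
unreliable by visual examination. Reflection-mode terahertz time-domain
spectroscopy (THz-TDS) is sensitive to the water content and structure of
skin: a handheld scanner pressed against the wound through an imaging
window records, at every pixel of a mm-pitch raster, the electric field of
a picosecond THz pulse containing two overlapping reflections (air/window
and window/tissue). This package implements, end to end, a pipeline that
turns such image cubes into burn-severity grades and healing predictions,
for researchers working on THz diagnostics and for anyone who needs a
fully synthetic, reproducible testbed for the method.

No in-vivo data ships with the package; a first-class simulator
(`thzburn.synthdata`) emulates the measurement geometry, severity-dependent
tissue response, biopsy artifacts, mechanical drift and noise, so every
stage is testable offline.

## The method

1. **Conditioning** — traces are band-passed to 0.1–1 THz (zero-phase),
   aligned on the air/window reflection, biopsy pixels are flagged by
   their Fabry–Perot echo energy (median + k·MAD rule), the window/tissue
   reflection is isolated with a 25-ps Blackman gate, and non-overlapping
   5×5-pixel regions of interest are averaged into observations.
2. **MODWPT** — the maximal-overlap discrete wavelet packet transform
   decomposes each gated trace at level J into 2^J equal-bandwidth,
   sequency-ordered sub-bands, each retaining all N time samples:

       W(j,n,t) = Σ_k u(k) · W(j−1, ⌊n/2⌋, (t − 2^(j−1) k) mod N)

   with u the Daubechies scaling filter g̃ when n mod 4 ∈ {0,3} and the
   wavelet filter h̃ otherwise (filters rescaled by 1/√2, which makes the
   transform exactly energy-preserving).
3. **ESER features** — per sub-band, the energy ratio
   E = Σ_t|W(J,n,t)|² / Σ_t|X(t)|² and the Shannon entropy
   H = −Σ_t P(t) log P(t) of the normalised coefficient energies
   P(t) = |W(J,n,t)|²/Σ|W(J,n)|² combine into ESER_n = E/H, and tissue
   features are divided by those of an identically conditioned air
   reference to cancel the instrument response.
4. **Classification** — a binary SVM predicts the healing outcome (FR:
   100% day-28 re-epithelialisation, vs NPR) and an ECOC multiclass SVM
   grades severity (H/SPT/DPT/FT, labels from dermal-burn depth:
   <60% / 60–90% / >90%). Hyperparameters *and* the wavelet/level feature
   combination (db1–db10, J = 8–13) are chosen by five-fold
   cross-validation on stratified 80/20 ROI-level splits, repeated 20
   times by default.

## Worked example

```bash
python examples/03_severity_ladder.py
```

```
class   rho   beta(1/THz)   mean deconvolved in-band ESER
H      0.85    0.3          0.9911
SPT    0.70    0.9          0.9538
DPT    0.55    1.8          0.9061
FT     0.40    3.0          0.8994
```

Each row is one simulated measurement site: `rho` is the broadband tissue
reflectivity and `beta` the spectral-tilt rate of its reflection. Deeper
burns (steeper tilt) return a narrower band, which spreads the gated pulse
in time, raises the coefficient entropy and lowers the mean in-band ESER —
the monotone contrast the classifiers exploit. Running
`examples/04_classify_burns.py` trains both models on a 210-observation
synthetic study and prints per-class sensitivity/specificity/accuracy/
ROC-AUC (100% across the board at the simulator's default effect sizes and
30-dB SNR; `examples/01_simulate_scene.py` and `02_wavelet_subbands.py`
walk through the raw scene and the sub-band bookkeeping).

The same pipeline is scriptable from the shell:

```bash
thzburn run-all -c config.yaml -o out/     # simulate → … → report.json
```

## Layout

- `src/thzburn/synthdata.py` — synthetic THz-TDS scene simulator
- `src/thzburn/preprocess.py` — band-pass, alignment, gating, ROI averaging
- `src/thzburn/modwpt.py` — maximal-overlap wavelet packet transform
- `src/thzburn/eser.py` — energy/entropy features, reference deconvolution
- `src/thzburn/model.py` — SVM tuning, repeated-split evaluation
- `src/thzburn/thzio.py` — HDF5 cubes (dotTHz-style), CSV features, JSON reports
- `src/thzburn/cli.py` — `thzburn` command-line pipeline
- `docs/methods.md` — modelling and numerical choices in detail
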