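# ampsense

Analysis pipeline for dual-enzyme amperometric microwire biosensor
recordings of extracellular glutamate (GLU) and GABA.

A three-wire platinum biosensor measures H₂O₂ oxidation current at
+0.7 V: a **GLU channel** coated with glutamate oxidase (GOx), a **GABA
channel** coated with GOx + GABASE (which needs the α-ketoglutarate
produced by the GOx/GLU reaction, so its GABA response depends on the
ambient GLU level), and an enzyme-free **sentinel channel** that sees
only electroactive interferents such as ascorbic acid. Getting from three
raw current traces to neurotransmitter concentrations — and on to
excitatory/inhibitory (E/I) balance — requires calibration, crosstalk
correction and careful peak analysis. This package implements that chain
for electrophysiologists and biosensor developers working with
stimulated brain-slice or awake-animal recordings:

1. **Calibration** — stepwise-addition sessions give each channel's
   sensitivity SS (slope of current vs concentration, pA/µM; divided by
   the 1.27×10⁻⁴ cm² wire area for nA·µM⁻¹·cm⁻² current densities), the
   linear range, the limit of detection LOD = 3·σ(baseline)/SS, the
   analyte/interferent selectivity, and the GABA-channel *line family*
   I_GABA(d) = m(GABA)·[GLU] + b(GABA).
2. **Deconvolution** — sample-wise or on peak currents:

       I_GLU        = I_RAW.GLU − I_Sentinel
       [GLU]        = I_GLU / SS_GLU
       I_GLU.in.GABA = [GLU] · SS_GLU.in.GABA
       I_GABA       = (I_GABA+GLU − I_GLU.in.GABA) − I_Sentinel

   followed by piecewise-linear inversion of the line family at the
   measured [GLU] to obtain [GABA].
3. **Peak kinetics & QC** — per-response baseline (mean of the last 10 s),
   rise time T_R (10→90% crossings), decay time T_D (90→10%), full
   duration at half maximum (FDHM), with sub-sample interpolation;
   responses below 2× baseline noise or with sentinel exceeding the raw
   GLU peak are discarded, and a slice is dropped once a control-pulse
   response falls to ≤80% of the first three controls' mean.
4. **E/I analysis** — E/I = [GLU]/[GABA] per response or behavioural
   epoch, group summaries, and independent two-sided Wilcoxon rank-sum
   tests (exact enumeration for combined n ≤ 16).

A seeded synthetic-data module generates three-channel sessions with
known ground truth — calibration runs, stimulated-slice responses with
artifacts, and in vivo behavioural scripts (interictal spikes, seizures,
sleep–wake GABA ramps) — so the whole chain is testable end to end.

## Worked example

```bash
python analysis/01_calibrate_sensor.py --seed 1
python analysis/03_invivo_interictal.py --seed 1
```

The calibration driver fits a simulated sensor and prints (abridged):

```
  GLU sensitivity (GLU wire)  128.00  nA/(uM cm2)
 GLU sensitivity (GABA wire)  144.00  nA/(uM cm2)
            GLU linear range  300.00  uM
       selectivity GLU vs AA  123.54  ratio
 family slope at 50 uM GABA    14.01  nA/(uM cm2) per uM GLU
family slope at 1000 uM GABA  146.00  nA/(uM cm2) per uM GLU
```

i.e. the fitted current-density sensitivities, linear range and the GABA
line-family slopes recover the configured sensor. The in vivo driver then
simulates a 70-s quiet-rest segment with interictal-like dips,
deconvolves it with this calibration and prints:

```
9 synchronized spikes, mean duration 463 ms at 0.129 Hz
baselines: GLU 18.0 µM, GABA 15.0 µM -> E/I = 1.20
```

— nine sub-second synchronized dips detected with their
departure-to-return durations, and an excitation-dominated resting
baseline (E/I 1.20). `analysis/02_slice_frequency_response.py` and
`analysis/04_sleep_wake_cycles.py` cover the stimulated-slice E/I versus
train frequency (E/I falls as frequency rises) and the sleep–wake balance
(inhibition dominates sleep, excitation wakefulness, pooled E/I near 1).
Tables land under `results/`.

## Layout

- `src/ampsense/` — library: `trace_io`, `synthetic`, `calibration`,
  `deconvolution`, `peaks`, `ei`, `workflows`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — models, assumptions, parameter choices, limitations
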