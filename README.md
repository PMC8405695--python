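# corneamech

Corneal biomechanical characterization from two complementary ex-vivo
measurements on mouse eyes, built for studies that compare a mutant cohort
(here a collagen-V haploinsufficient Ehlers–Danlos model, *Col5a1*⁺/⁻)
against wild-type littermates:

1. **Quasi-static phase-difference optical coherence elastography (OCE).**
   A complex OCT B-scan pair is recorded at ambient pressure and after a
   small pressure modulation Δp (−3 mmHg). The axial displacement field is
   encoded in the phase of the conjugate product R = B_ref·B_def\*; after
   boxcar smoothing, the depth-adjacent product gives the axial strain

   Δε = λ·∠(R_s(z,x)·R_s\*(z+1,x)) / (4π·n·asu),

   wrap-free below λ/(4·n·asu) ≈ 35.6 ‰. With the segmented central
   thickness `cct` and Laplace's thin-shell stress Δσ = Δp·R/(2·cct), the
   elastic modulus is E = Δσ/Δε.

2. **2D extensometry with Prony-series viscoelastic fitting.** A corneal
   button clamped over a 1.6 mm aperture is loaded by an indenter through
   pre-conditioning cycles, a 120 s stress relaxation at 0.4 N, and a
   rupture ramp. Force converts to tensile stress σ = F/(2π·R·cct) and
   indenter travel to strain through the spherical-cap arc-chord stretch.
   Relaxation is summarised by the percent stress drop after 100 s and by a
   constrained least-squares fit of the 3-term Prony series
   E(t) = E∞ + Σᵢ Eᵢ·e^(−t/τᵢ); the ramp yields the mean stress–strain
   slope between 10 % and 15 % strain.

Because the raw animal data are not public, the package ships a
first-class synthetic-data module: speckle-carrying complex B-scan
phantoms with a known imposed strain, Prony-model force traces, and
two-group cohort tables — so every analysis stage is verified by parameter
recovery, and a full study emulation (simulate → analyze → compare →
report) runs from one seeded config. Cohort comparisons use the study's
statistical workflow: Shapiro–Wilk-gated Student's t-test / Mann–Whitney U.

## Worked example

```python
import corneamech as cm

# a Col5a1+/- -like eye: 125 um thick, E = 506 kPa, dP = -3 mmHg
g = cm.LoadingGeometry(cct_um=125.0, radius_mm=1.5, delta_p_mmhg=-3.0)
strain = cm.laplace_stress(g) / 506e3          # implied uniform strain
spec = cm.PhantomSpec(cct_um=125.0, imposed_strain=strain,
                      snr_db=30.0, seed=42)
res = cm.PhaseDifferenceOCE(cm.gen_oct_pair(spec)).fit()
print(res.summary())
```

```
Phase-difference OCE results
============================
smoothing window        : 6 x 9 px
ROI mode                : physical_0.5mm
central thickness (cct) :    122.4 um
pressure modulation     :    -3.00 mmHg
Laplace stress change   :  -2451.2 Pa
mean central strain     :   -4.702 permil
elastic modulus E       :    521.4 kPa
```

The pipeline segments the cornea to 122.4 μm (the 125 μm phantom
quantised to the 4.48 μm axial grid), measures a mean central strain of
−4.70 ‰ against the −4.74 ‰ imposed, and recovers 521 kPa against the
506 kPa injected — a 3 % end-to-end error at 30 dB SNR.

```python
tr = cm.gen_relaxation_trace(cm.TraceSpec(prony=cm.WT_PRONY, eps0=0.18))
print(cm.StressRelaxation.from_trace(tr, eps0=0.18).fit().summary())
```

```
Stress-relaxation Prony fit
===========================
applied strain eps0     :   0.1800
stress reduction @100 s :    45.18 %
E_inf (long-term)       :    1.180 MPa
E_1 =  0.430 MPa   tau_1 =     3.10 s
E_2 =  0.510 MPa   tau_2 =    51.00 s
E_3 =  0.880 MPa   tau_3 =   124.00 s
residual sum of squares :  8.370e-17
```

The noiseless wild-type trace refits its generating constants exactly;
its analytic 100 s stress reduction is 45.18 %.

A command-line interface mirrors the library
(`corneamech simulate|oce|extenso|cohort|report`); e.g.
`corneamech report --seed 0 --out study_out` runs the full 14 + 14-eye
study emulation and writes per-eye JSON, a cohort CSV, the group
comparison and a provenance log.

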