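# aacidcest

CEST-MRI measurement of intracellular pH with the AACID ratiometric
statistic, as a reusable, tested Python pipeline on synthetic phantoms.

Gliomas maintain a reversed pH gradient — a slightly alkaline interior
against an acidic extracellular space — and drugs that inhibit acid
extrusion (e.g. the NHE1 inhibitor Cariporide) are expected to acidify the
tumor interior. Chemical exchange saturation transfer (CEST) MRI can watch
this happen in vivo: labile amide (+3.5 ppm) and amine (+2.75 ppm) protons
exchange with bulk water at base-catalyzed, pH-dependent rates, so a
frequency-selective saturation pulse imprints a pH-sensitive dip on the
water signal. The package is aimed at imaging scientists who want a
desk-scale, fully synthetic testbed for this analysis: every stage of the
acquisition and processing chain is simulated, so ground truth is known
exactly.

## The statistic

From the B0-corrected Z-spectrum *Z(ω)* of each voxel, three readouts at
1-Hz resolution form the amine/amide concentration-independent detection
(AACID) ratio

    AACID = Mz(3.5) · (Mz(6.0) − Mz(2.75)) / [ Mz(2.75) · (Mz(6.0) − Mz(3.5)) ]

with 6.0 ppm serving as reference point. AACID is inversely related to
intracellular pH and converts to pH through the linear mouse-brain
calibration

    pH_i = −4 · AACID + 12.8

The pipeline around it mirrors a 9.4 T small-animal protocol: CEST sweep
1.2–6.6 ppm in 0.1 ppm steps plus ±1000 ppm reference frames (57 frames,
1.5 μT / 4 s CW saturation), a 41-point WASSR sweep ±0.6 ppm (0.2 μT /
100 ms) for per-voxel B0 mapping, reference normalization, repeat
averaging, smoothing-spline fitting, and pixel-wise B0 shift correction.
The simulator solves the Bloch-McConnell equations of a water + amide +
amine pool system exactly (matrix exponential for finite pulses, linear
solve for the steady state), with Rician noise and polynomial B0 fields.

## Worked example

`examples/02_process_and_map.py` simulates three noisy repeats (SNR 50) of
a 12×12 phantom with an alkaline tumor (pH 7.34) in neutral tissue
(pH 7.00), processes them and prints:

```
valid voxels: 144/144
 contralateral: AACID 1.734 ± 0.012 (SEM, n=108), calibrated pH 5.86
         tumor: AACID 1.033 ± 0.022 (SEM, n=36), calibrated pH 8.67
```

The alkaline tumor shows the lower AACID, as the inverse relation demands;
the absolute calibrated pH differs from the scripted pH because the
synthetic pools are generic literature-plausible stand-ins, not tissue
fitted to the mouse-brain calibration (see `docs/methods.md`). The other
examples cover raw-spectrum simulation, the WASSR B0 round trip (a
−0.12 ppm shift distorts AACID by +5.5% uncorrected and −0.20% after
correction), a scripted drug-injection time course, and the
repeated-measures statistics battery.

A thin CLI wraps the same library calls:

```sh
cestph simulate --spec spec.yaml --out sim/ --repeats 3
cestph process  --cest sim/cest_rep*.nii.gz --wassr sim/wassr_rep*.nii.gz --out proc/
cestph map      --in proc/ --out maps/
cestph roi      --maps maps/ --masks sim/masks --out roi.csv
cestph stats    --table table.csv --design side*time --out report/
cestph run      --config run.yaml --out results/
```

Stacks travel as 4-D NIfTI volumes with JSON sidecars carrying the offset
schedule and field strength; parametric maps use a NaN sentinel plus a
validity-mask companion.

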