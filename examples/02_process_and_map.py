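"""From raw stacks to AACID and pH maps.

Simulates three noisy repeats of a tumor phantom, normalizes each by its
±1000 ppm reference frames, averages them, estimates the per-voxel water
shift from the WASSR spectra, and computes the AACID ratio and calibrated
pH pixel by pixel.  The tumor (alkaline, pH 7.34) should show a *lower*
AACID than contralateral tissue — AACID is inversely related to pH.
"""

import aacidcest as ac

spec = ac.PhantomSpec(
    nx=12,
    ny=12,
    classes=(
        ac.TissueClass("contralateral", ph=7.0),
        ac.TissueClass("tumor", ph=7.34, shape=("ellipse", 0.4, 0.5, 0.25, 0.3)),
    ),
    noise_sigma=0.02,  # SNR 50 relative to the unsaturated signal
    seed=3,
)

cest, wassr, truth = ac.generate_phantom(spec, ac.cest_schedule(), ac.wassr_schedule(), n_repeats=3)
avg, b0 = ac.process_stacks(cest, wassr)
aacid_map, ph_map = ac.make_maps(avg, b0)

print(f"valid voxels: {int(aacid_map.valid.sum())}/{aacid_map.valid.size}")
for name in ("contralateral", "tumor"):
    mean, sd, sem, n = ac.roi_stats(aacid_map, truth.masks[name])
    ph_mean, *_ = ac.roi_stats(ph_map, truth.masks[name])
    print(f"{name:>14s}: AACID {mean:.3f} ± {sem:.3f} (SEM, n={n}), calibrated pH {ph_mean:.2f}")
print("(calibrated pH uses the linear mouse-brain relation pH = -4*AACID + 12.8;")
print(" with synthetic pools its absolute level differs from the scripted pH,")
print(" but the tumor/contralateral ordering follows the true pH contrast)")
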