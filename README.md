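# markermorph

CT-based localization and longitudinal morphometry of implanted
radiopaque soft-tissue markers.

Barium-sulfate-infused polypropylene suture knots tied to soft tissue
(for example a repaired rotator cuff tendon) image as compact bright
blobs on low-dose CT. Tracking those knots across scans turns ordinary
CT into a quantitative measuring instrument for questions such as *how
far has this tendon repair retracted since surgery?* — sub-millimetre
measurements that plain visual reading cannot provide. `markermorph`
implements the full analysis chain for such marker studies:

1. **Marker localization** — Hounsfield thresholding, 26-connected
   component labelling with a size gate (rejects specks and bone), and
   reduction of each knot to the volumetric centroid of its voxels, in
   world millimetres with sub-voxel accuracy.
2. **Anatomical frames** — right-handed (lateral, anterior, superior)
   coordinate systems for the scapula (AA/TS/AI triad) and humerus
   (head center + epicondyles) built from analyst-supplied bony
   landmarks.
3. **Rigid registration and virtual markers** — follow-up scans are
   mapped into the reference (day-of-surgery) world frame by a
   least-squares rigid (Kabsch) fit of the scapular landmarks, and
   software-only *virtual* markers placed along the rotator cuff
   footprint in the reference scan are carried into every follow-up
   through their rigid-body relationship to three humeral bone
   markers: `T = argmin Σ‖R·hᵢ + t − hᵢ′‖²` over proper rotations,
   then `vⱼ′ = T(vⱼ)`.
4. **Morphometry** — Euclidean inter-marker lengths; quadrilateral
   areas as the average of the two diagonal triangulations,
   `A = ½(△₁₂₃ + △₁₃₄ + △₂₃₄ + △₂₄₁)` with
   `△ₐᵦ𝒸 = ½‖(b−a)×(c−a)‖`; and humeral orientation as projected
   angles (abduction in the coronal plane, internal/external rotation
   in the axial plane, flexion/extension in the sagittal plane, plane
   normals taken from the scapular frame).
5. **Statistics** — repeat-scan *precision* (the mean of
   per-measurement sample SDs within each class: lengths, areas,
   angles) and *longitudinal change* (final − baseline per
   measurement, class mean ± sample SD), with medio-lateral
   virtual-to-tendon lengths singled out as the tendon-retraction
   measure.

A synthetic **phantom** module renders marker layouts into CT volumes
(partial-volume boundaries, reconstruction blur, seeded noise, rigid
repositioning, scripted retraction) so the entire pipeline is testable
against known ground truth without any scan data.

## Worked example

Emulate the repeat-scan precision protocol — three scans of the same
specimen, repositioned by 0.3 mm between scans, 20 HU noise — and the
published-table retraction statistics:

```python
import markermorph as mm
from markermorph.phantom import study_bundle, repeat_scan_script
from markermorph.pipeline import (analyze_study, tables_from_literature,
                                  load_packaged_table)

spec = mm.render_cadaver_layout(noise_sigma_hu=20.0, seed=7)
study = mm.render_longitudinal(spec, repeat_scan_script(n_scans=3,
                                                        jitter_mm=0.3, seed=7))
result = analyze_study(study_bundle(study), mode="precision")
for cls, value in result.precision.pooled.items():
    print(f"{cls:8s} precision: {value:.3f}")

retr = tables_from_literature(load_packaged_table("patient_longitudinal"),
                              mode="longitudinal",
                              measurement_class="lengths",
                              group="mediolateral")
print(f"retraction: {retr.mean:.1f} +/- {retr.sd:.1f} mm "
      f"(weeks {retr.baseline_weeks:g}->{retr.final_weeks:g})")
```

prints

```
lengths  precision: 0.057
areas    precision: 0.702
angles   precision: 0.000
retraction: 19.1 +/- 2.9 mm (weeks 0->26)
```

The pooled length precision of ~0.06 mm is the *grid/noise floor* of
the method on an ideal phantom (real repeat-scan precision also
absorbs analyst variability and tissue deformation; see
`docs/methods.md`). The retraction line reproduces the longitudinal
statistics of the bundled patient example table: the four
medio-lateral tendon lengths grew by 19 ± 3 mm over 26 weeks.

The same pipeline is scriptable from the shell:

```bash
markermorph phantom --layout cadaver --mode repeats --n-scans 3 --out study/
markermorph run --config study/config.json --mode precision --out report/
```

which writes `measurements.csv`, `summary.json` and `manifest.json`.

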