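# batmri

Quantitative water–fat MRI analysis of supraclavicular brown adipose tissue
(BAT) under cold exposure.

Chemical-shift encoded (Dixon) MRI separates the water and fat signals of
adipose tissue and yields, per voxel, a fat fraction FF = F/(F+W) and an
effective relaxation time T2\*. In cold-activated BAT the lipid stores are
combusted, so FF falls after cold exposure — but the measured change depends
strongly on *which* voxels are counted: estimated BAT volume, global FF and
tissue energy content all shift with the FF threshold range used for
segmentation. `batmri` implements the full analysis chain needed to study
this threshold dependence:

* **recon** — six-echo water–fat separation with a multi-peak fat spectrum
  and mono-exponential T2\*: variable-projection fitting over the field map
  ψ and R2\*, with a region-growing field-map initialization that resolves
  water–fat swaps; outputs FF, T2\*, ψ, water and fat maps.
* **global_analysis** — threshold-range segmentation (Vol_BAT, FF_Glob,
  T2\*_Glob), 0.5%-bin volume histograms, per-10%-bin cold-induced volume
  changes, and the full sweep of post-minus-pre changes over all
  (lower, upper) FF threshold pairs with paired t statistics.
* **mass_energy** — FF → fat/lean volume → mass → metabolizable energy
  (lipid 0.92 mg and 9.4×10⁻³ kcal per μL; lean 1.06 mg and 1.0×10⁻³ kcal
  per μL), per depot, per FF bin, and over the threshold grid.
* **local_analysis** — voxel-wise paired ΔFF/ΔT2\* tables after ROI
  transformation and 3×3 in-plane smoothing, 2-D joint histograms, and
  k-means clustering with the 95% explained-variance elbow rule.
* **roi_transform** — mask/map resampling through dense deformation fields
  (pulling convention, mm) and the neighborhood-mean smoother.
* **phantom** — a seeded digital phantom of the supraclavicular depot
  (lobular low/high-lipid texture, FF-dependent T2\*, smooth off-resonance,
  subcutaneous control region, cold-exposure response) and the six-echo
  complex acquisition simulator, so the whole pipeline runs without any
  data download.

All volumes are NIfTI (via nibabel) with JSON sidecars; tables are CSV.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from batmri.core import AcquisitionParams, ThresholdRange
from batmri.global_analysis import SubjectData, depot_summary, estimated_volume
from batmri.mass_energy import voxel_composition
from batmri.phantom import apply_cold_effect, generate_phantom, simulate_echo_series
from batmri.recon import reconstruct_maps

# unit conversions used throughout the analysis
print(round(estimated_volume(93275, 0.548)))      # 51  (mL from voxel count)
c = voxel_composition(0.5, 1.0)
print(c.fat_volume, c.lean_volume)                # 0.5 0.5  (uL fat / lean)

# phantom -> simulated echoes -> reconstructed maps
truth = generate_phantom(shape=(32, 32, 8), seed=7)
echoes = simulate_echo_series(truth, AcquisitionParams(noise_sd=0.0), seed=0)
maps = reconstruct_maps(echoes)
print(float(np.nanmax(np.abs(maps.ff - truth.ff_true)[truth.roi])))
# 1.6653345369377348e-16  (noiseless FF recovered to machine precision)

# cold-exposure effect on the depot summary, 70-100% FF range
post = apply_cold_effect(truth, seed=1)
r = ThresholdRange(70, 100)
pre_s = depot_summary(truth.ff_true, truth.t2s_true,
                      SubjectData.from_truth_pair(truth, post).roi_pre, r, "thermoneutral")
post_s = depot_summary(post.ff_true, post.t2s_true,
                       SubjectData.from_truth_pair(truth, post).roi_post, r, "post_cooling")
print(f"{pre_s.ff_glob:.1f} -> {post_s.ff_glob:.1f} %")   # 82.1 -> 79.1 %
print(f"{pre_s.vol_bat:.2f} -> {post_s.vol_bat:.2f} mL")  # 0.15 -> 0.12 mL
```

The FF_Glob of the lipid-rich compartment falls after simulated cooling and
its estimated volume shrinks, because voxels that lose lipid drop below the
70% threshold — the threshold dependence the package exists to quantify.

A command-line pipeline wraps the same stages
(`batmri run --outdir out --seed 0`, or individual subcommands
`simulate`, `reconstruct`, `transform`, `analyze-global`, `mass-energy`,
`analyze-local`, `report`); every run writes its resolved configuration
next to its outputs and regenerates them bit-identically from it.

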