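# phyllotaxis3d

3D radial spiral phyllotaxis trajectory design, phantom k-space simulation,
gridding reconstruction, opposing-spoke phase corrections, and phase-cycled
bSSFP T1/T2 mapping — a desk-scale laboratory for studying why
single-hemisphere 3D radial MRI acquisitions smear, and how acquiring nearly
opposing spokes fixes it.

## The problem

A 3D radial ("koosh-ball") acquisition samples straight lines (*spokes*)
through the center of k-space. In the spiral phyllotaxis scheme the spoke
start directions advance azimuthally by the golden angle
φ<sub>GA</sub> = π(3−√5) ≈ 2.39996 rad (137.5078°), while the polar angle θ
follows a linear schedule; spokes are grouped into K interleaves of
J = N/K spokes with the ordering n(j,k) = k + (j−1)·K. Three polar-schedule
designs are implemented:

| design | θ range | start hemispheres |
|---|---|---|
| `original` | [0, π/2] | upper only |
| `pole_to_pole` | [0, π] | both |
| `continuous` | [0, 2π) | both, returning to the start pole |

Gradient-system imperfections (B0 eddy currents, gradient delays) imprint a
phase on each spoke that is *odd* in the readout direction: a spoke acquired
along **d** and one along **−d** pick up opposite phase offsets. When every
spoke starts from the same hemisphere (`original`) these offsets never
cancel and the reconstruction smears signal along the polar axis; when
nearly opposing spokes are interleaved throughout the scan
(`pole_to_pole`, `continuous`) the errors self-compensate without any
calibration. The package simulates this mechanism end-to-end with a
parametric imperfection model

- constant per-spoke phase ψ = **c**·**d** (direction-odd, rad),
- per-axis gradient delays τ (readout-sample units) that displace the
  effective sampling positions,
- seeded complex Gaussian noise,

reconstructs with density-compensated Kaiser-Bessel gridding (using the
*nominal* trajectory, so the corruption becomes visible), and quantifies the
damage via an out-of-support artifact-energy metric, k-space-center phase
maps, and T1/T2 mapping accuracy from phase-cycled bSSFP
(S(Θ) ∝ M(1−E₂e^{−iΘ})/(1−b cosΘ), inverted per ROI for T1, T2, Δf, PD).

Two retrospective corrections close the loop: transferring each spoke's
nearest opposing spoke's k-space-center phase as a constant phase factor,
and an opposing-projection linear-phase fit that recovers gradient delays.

## Worked example

```python
import numpy as np
from phyllotaxis3d import (
    TrajectoryConfig, build_spoke_set, salt_water_ball, ImperfectionModel,
    simulate_acquisition, ReconConfig, reconstruct, artifact_metric)

phantom = salt_water_ball(radius=10.0)           # soft-edged ball, voxels
model = ImperfectionModel(phase_coeffs=(0, 0, 1))  # 1 rad odd phase along z
rc = ReconConfig(matrix_size=48)

for design in ("original", "pole_to_pole"):
    cfg = TrajectoryConfig(n_spokes=2000, n_interleaves=10,
                           design=design, samples_per_spoke=97)
    ks = simulate_acquisition(phantom, build_spoke_set(cfg), model)
    report = artifact_metric(reconstruct(ks, rc), phantom)
    print(f"{design:>13}: artifact energy = {report.artifact_energy:.4f}")
```

prints

```
     original: artifact energy = 0.0171
 pole_to_pole: artifact energy = 0.0053
```

i.e. the same 1 rad direction-odd phase error deposits ~3× more energy
outside the phantom when all spokes start from one hemisphere; the
pole-to-pole design self-compensates it. (The imperfection-free baseline of
this setup is ~0.0001.)

A command-line interface mirrors the library:

```
phyllo trajgen --design pole2pole --spokes 17800 --interleaves 89 \
    --samples 97 --out traj.h5
phyllo simulate --traj traj.h5 --phantom phantom.yaml \
    --imperfections model.yaml --seed 7 --out kspace.h5
phyllo recon --kspace kspace.h5 --matrix 48 --out vol.h5
phyllo correct --kspace kspace.h5 --method both --out corrected.h5
phyllo evaluate --recon vol.h5 --phantom phantom.yaml --out report.json
```

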