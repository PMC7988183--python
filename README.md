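# pwv4d

Quantitative hemodynamics from 4D-flow MRI of large vessels: lumen
segmentation and centerline geometry, cross-sectional flow and area
metrics, and pulse wave velocity (PWV) by the time-to-foot method — paired
with a synthetic compliant-tube flow phantom of known ground-truth wave
speed, so the whole analysis chain can be validated end to end without
scanner data.

## The problem

Aortic wall stiffening raises the speed at which the flow/pressure pulse
travels along the vessel. For a thin-walled tube of constant diameter the
Moens-Korteweg relation ties wave speed to wall properties:

    PWV = sqrt(E h / (2 rho r))

with elastic modulus `E`, wall thickness `h`, fluid density `rho`, and
lumen radius `r`. 4D-flow MRI measures the time-resolved velocity vector
field `v[x, t]` over a volume, from which PWV can be estimated
non-invasively: flow-rate waveforms

    Q_k[t] = integral over A_k of <v[x, t], n_k>

are extracted on oriented cross-sections `A_k` (center `c_k`, unit normal
`n_k`) placed every 5 mm along the descending-aorta centerline; each
waveform's **time-to-foot** (TTF) is the x-intercept of a line fitted
through the systolic upslope between 20 % and 80 % of peak flow (after
cubic-spline interpolation); and PWV_TTF is the inverse slope of the
TTF-versus-arclength regression — ordinary least squares (LSE) with a
gross-outlier exclusion rule, and RANSAC as the robust alternative. A
slope in ms/mm inverts directly to m/s.

Temporal resolution is a known confounder of this estimate, so the package
ships a phantom generator: a tapered tube (36 → 20 mm diameter) carrying a
pulsatile inflow wave (71.2 mL stroke volume at 60 bpm, pump-limited to
300 mL/s) that travels at a configurable true wave speed, with prescribed
wall compliance, velocity noise, a static gel block for eddy-current
offset correction, and frame durations of 20 / 40 / 62.5 ms.

## Worked example

Run the full pipeline — simulate, correct, segment, centerline, planes,
quantify, PWV — with the default configuration (compliant phantom, true
PWV 6 m/s, 20 ms frames, noise 3 cm/s):

```sh
pwv4d run --out demo/
# PWV (LSE): 6.07239251794422 m/s, PWV (RANSAC): 5.978108238234577 m/s (true 6.0 m/s)
```

Both estimators land within ~1 % of the programmed 6 m/s wave speed.
`demo/report.json` holds the machine-readable run report; with the default
configuration it contains, among others:

| quantity | value | meaning |
|---|---|---|
| `quantify.n_planes` | 40 | cross-sections every 5 mm along the analysis segment |
| `quantify.net_flow_ml_mean` | 58.2 | per-cycle net flow, reduced downstream by the programmed branch-outflow damping |
| `quantify.peak_relative_area_change` | 0.066 | systolic lumen expansion at the mid plane (> 5 %: compliant wall) |
| `pwv.lse.pwv_mps` / `pwv.lse.r2` | 6.07 / 0.986 | least-squares TTF regression |
| `pwv.ransac.pwv_mps` | 5.98 | robust RANSAC estimate |

Intermediate artifacts are standard formats: NIfTI volumes (`magnitude`,
`velocity`, `spgr`, masks), tidy CSV tables with units in the column names
(`flow_waveforms.csv`: `plane, s_mm, t_ms, Q_mLps`; `ttf.csv`,
`centerline.csv`).

The same stages are available as library functions:

```python
from pwv4d import (PhantomSpec, make_inflow_waveform, synthesize_phantom,
                   synthesize_spgr, segment_lumen, extract_centerline,
                   fit_pwv_lse, ttf_series)
```

and as individual subcommands (`pwv4d simulate|correct|segment|centerline|
planes|quantify|pwv|material`). Unknown configuration keys are rejected by
schema validation before any stage runs, and identical configurations
reproduce the run report byte for byte.

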