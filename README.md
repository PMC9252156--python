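# xpcsre

Reverse-engineering toolkit for non-equilibrium X-ray photon correlation
spectroscopy (XPCS): simulate phase-separating 2D systems, synthesize
the coherent-scattering speckle they would produce, and quantify the
two-time correlation features that encode the control parameters of the
underlying dynamics.

## The problem

XPCS on a phase-separating sample (e.g. a protein solution quenched
into liquid–liquid coexistence) yields a series of speckle frames whose
pairwise correlation at fixed momentum transfer q,

    G(q, t1, t2) = cov_p[I(t1), I(t2)] / ( sd_p[I(t1)] · sd_p[I(t2)] ),

(the average over detector pixels p with |q| in a ring q ± Δq) is the
two-time correlation function (TTC).  Non-equilibrium TTCs carry rich
structure — a *modulation* of the relaxation width along the diagonal,
off-diagonal *tails*, a frozen-in *square* block, and time-dependent
near-diagonal *contrast* — but attributing each feature to a physical
mechanism from the data alone is ambiguous.

`xpcsre` attacks this by forward simulation of deliberately simple
models whose knobs are turned one at a time:

* a **Cahn–Hilliard phase field** for spinodal decomposition after a
  quench, ∂u/∂t = ∇·[m(u)∇(u³ − a·u − κ∇²u)] with quench depth
  a = (T_c − T)/T_c, constant or gel-like (suppressed-in-dense-phase)
  mobility, plus field-level modifications (binarization, boundary
  dilation);
* a **particle-based heuristic model** — domains as disks/ellipses with
  programmable radius, shape, concentration and random-walk schedules;
* **speckle synthesis** as |FFT2(u − ⟨u⟩)|² with q-maps in simulation
  units or physical nm⁻¹ from a detector geometry, additive
  constant-amplitude noise;
* **TTC analysis** — the estimator above, contrast profiles, g2 cuts,
  relaxation times (1/e or Kohlrausch fits), tail detection, the
  integer-multiple length ladder ξ_XPCS = n·2π/q, square-feature
  strength, ξ_USAXS = 2π/q_peak and coarsening power-law fits
  (ξ ~ t^(1/3) for diffusive coarsening).

See `docs/methods.md` for models, conventions and accuracy limits.

## Worked example: reading domain sizes off a TTC

One hundred identical disks grow at constant speed; the TTC contrast
revives each time the mean diameter crosses (approximately) an integer
multiple of the probed length 2π/q, turning tail times into a size
ladder:

```python
import numpy as np
import xpcsre as xr

spec = xr.build_scenario("linear_growth", box_n=512, n_particles=100,
                         duration=120.0, growth_rate=0.15, seed=5,
                         overrides={"radius_mean": 5.0})
speckle = xr.speckle_series(xr.simulate(spec, 120))
q = 2 * np.pi / 3.4
ring = xr.make_q_ring(speckle, q, 2 * 2 * np.pi / 512)
ttc = xr.compute_ttc(speckle, ring)
profile = xr.contrast_profile(ttc, offset=1)
tails = xr.detect_tails(profile, prominence=0.05)
points = xr.xi_from_tails(tails, q, n0=4)
```

Output of the accompanying print statements:

```
ring: 3768 pixels at q = 1.848  (probe length 2*pi/q = 3.4 px)
10 tails detected; first at t_age = 8.5, anchor n0 = 4
 t_age   xi_XPCS   true mean diameter
   8.5     13.6     12.5
  20.5     17.0     16.2
  31.5     20.4     19.4
  42.5     23.8     22.8
  55.5     27.2     26.6
modulation spacing: 11.3 +/- 0.8 frames (uniform: True)
```

The ladder ξ_XPCS = (n0 + k)·2π/q tracks the true (simulation ground
truth) mean diameter to a few percent, and the uniform spacing of the
contrast maxima is the fingerprint of constant-speed growth — doubling
the growth speed halves it.

## Command line

The same pipeline is scriptable from the shell:

```bash
xpcsre simulate-particles --scenario brownian --n-frames 100 \
    --box-n 256 --out fields.h5
xpcsre speckle --fields fields.h5 --noise-fraction 0.04 --out speckle.h5
xpcsre ttc --speckle speckle.h5 --out ttc.h5
xpcsre features --ttc ttc.h5 --out features.json
xpcsre pipeline --config run.yml --seed 7 --out results/
```

Subcommands: `simulate-ch`, `simulate-particles`, `speckle`, `ttc`,
`features`, `pipeline`, `fixtures`.  Exit codes distinguish
configuration errors (2), data/format errors (3) and numeric failures
(4).  Artefacts are HDF5 (field/speckle stacks, TTCs), TIFF (frame
export), CSV/JSON (features) — schemas in `xpcsre/io.py`.

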