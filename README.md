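# sarcomech

Sarcomere morphometrics and chemo-mechanical contractility modelling
for micropatterned human iPSC-derived cardiomyocytes.

Cardiomyocytes grown on rectangular (17 × 118 μm) versus circular
(50 μm) adhesive patterns organise their sarcomeres very differently,
and a FRET tension sensor inserted into α-actinin-2 reads out the load
on the z-disk: under contraction the linker stretches and the FRET
index drops.  `sarcomech` provides, as a library:

* **`sarcomech.synth`** — a ground-truthed synthetic microscopy
  generator: two-channel (donor/acceptor) images of striated single
  cells with exact per-sarcomere spacing, orientation and FRET index,
  including acceptor-photobleaching pairs.  Because published cohort
  statistics for patterned hiPSC-CMs are built into its presets, every
  downstream measurement is testable without external data.
* **`sarcomech.quant`** — the image-analysis chain: top-hat +
  percentile-stretch preprocessing, two-scale neighbourhood
  segmentation of z-lines, per-sarcomere spacing and orientation from
  local 2-D autocorrelation restricted to the 1.2–2.8 μm periodicity
  window, ratiometric FRET index 100·A/(D+A), acceptor-photobleaching
  efficiency E = 1 − F_DA/F_D, and the nematic order parameter
  S = ⟨(3cos²θ − 1)/2⟩ with the director n̂ of maximum order.
* **`sarcomech.mech`** — a chemo-mechanical feedback model of
  contractility: free energy quadratic in strain ε and contractility ρ,
  feedback-renormalised moduli, a stress-anisotropy tensor
  σᵃ = H(σ₁/σ₂−1)σ₁ n⊗n that activates aligned contraction, a
  three-element sarcomere (actomyosin in parallel with actin, in series
  with α-actinin), and a hexahedral finite-element solver for
  cell-on-substrate geometries predicting α-actinin strain, the
  stress-derived order parameter Q = (3n⊗n−I)/2, and substrate
  tractions.
* **`sarcomech.pipeline`** / a thin `sarcomech` CLI — orchestration
  (simulate-images, quantify, model, report) with append-only run
  directories and byte-deterministic reports.

See `docs/methods.md` for the models, numerics and limitations, and
`examples/` for one short script per capability.

## A worked example

```sh
python examples/02_quantify_cell.py
```

generates one noisy live-contracted rectangular cell and measures it:

```
detected sarcomeres : 73 (truth 73)
mean spacing        : 1.631 μm (truth 1.617)
median FRET index   : 44.35 (truth 44.33)
FRET IQR            : 5.86 index units
order parameter S   : 0.993 (truth 0.992)
spacing range       : 1.50-1.80 μm
```

Every detected z-line's spacing comes from the first in-window peak of
its local autocorrelation (hence the 1.2–2.8 μm range), the FRET index
is the background-subtracted acceptor fraction, and S ≈ 1 says the
myofibrils are uniaxial — as a rectangular cell should be.

The model side (`python examples/05_cell_on_substrate.py`):

```
rect contracted  S_sim= 0.926  <eps2_kk>= 0.02787  max traction=  417.6 Pa
rect relaxed     S_sim= 0.926  <eps2_kk>= 0.00014  max traction=    2.1 Pa
circ contracted  S_sim= 0.128  <eps2_kk>= 0.01531  max traction=  445.8 Pa
circ relaxed     S_sim= 0.128  <eps2_kk>= 0.00008  max traction=    2.2 Pa
```

Rectangular cells align their principal stresses (S_sim ≈ 0.93 versus
0.13 for circles), put more volumetric strain on α-actinin when
contracted, and concentrate inward-pointing tractions at their
longitudinal ends; with the relaxed quiescent contractility (10 Pa
instead of 2 kPa) substrate loads all but vanish.

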