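# lpvsup — supervisory switching control of delayed LPV plants

`lpvsup` is a design–certify–simulate toolkit for regulating a plant whose
gain varies with a measurable scheduling parameter and whose input acts
through a transport delay.  Its running application is closed-loop mean
arterial pressure (MAP) regulation for post-surgical hypertension patients:
the patient's response to a vasoactive drug (sodium nitroprusside) is the
first-order delayed LPV model

```
xdot(t) = -x(t)/tau + theta(t)/tau * u(t - h),      M(t) = x(t) + M0,
```

with drug sensitivity `theta(t) ∈ [-9.5, -0.25]` mmHg·(ml/hr)⁻¹ varying
between and within patients, distribution lag `tau` (nominal 35 s, range
[10, 60]), transport delay `h` (nominal 40 s, range [20, 60]), and baseline
`M0 ≈ 100` mmHg.  No single LTI controller is robustly adequate over this
38-fold gain range, so the toolkit:

1. **partitions** the sensitivity range into operating regions
   `Θ_i = [θ_i⁻, θ_i⁺]` (five by default) and writes the plant on each
   region as an upper LFT of a nominal LTI part and the normalized
   time-varying gain `δ̄ = (θ - θ_i)/Δ_i`;
2. **designs** one Smith-predictor-based LTI compensator per region by
   two-block mixed-sensitivity H∞ synthesis on the delay-free plant
   `G_0(s) = θ_i/(τ₀ s + 1)`,

   ```
   min over stabilizing C of  || [ W_s S ;  W_k C S ] ||_inf ,
   S = (1 + G_0 C)^{-1},
   W_s(s) = e^{-h₀/τ₀} (s + 0.055)/(10 s + 5.5e-4),
   W_k    = e^{-h₀/τ₀} (Δ_i + 2.715 |θ_i|),
   ```

   where `W_k` is the delay-attenuated lumped bound on the additive
   uncertainty from θ, τ and h, so achieving `γ < 1` certifies robust
   stability by the small-gain theorem (and one full-range controller
   provably fails this test);
3. **supervises** the bank with hysteresis switching: controller i hands
   over only when `theta` crosses a region boundary by ±0.2, preventing
   chattering;
4. **certifies** the switched closed loop with a dwell-time argument: on
   each region the shifted Lyapunov equation
   `(A_i(θ)+λ_i I)'Q + Q(A_i(θ)+λ_i I) = -I` yields constants
   `(λ_i, μ_i, M_i, L_Qi)` on a dense θ-grid, the admissible variation rate
   `β_max = min_i (1 + 2λ_i μ_i)/L_Qi`, and the dwell time
   `h_D = max_i 2 M_i ln(M_i/μ_i)/(1 + 2λ_i μ_i - L_Qi β)`;
5. **simulates** the full switched loop (FIR-realized Smith predictors,
   input-delay buffer, actuator limits, bumpless transfer) and scores it
   against the clinical specifications: settling < 10 min, undershoot
   < 10 mmHg, steady state within ±5 mmHg, infusion in (0, 180) ml/hr, no
   sustained oscillation.

The H∞ machinery (two-Riccati γ-bisection with general direct feedthrough,
bounded-real Hamiltonian norms, balancing) is implemented in-package on
`scipy.linalg` primitives.

## Worked example

```python
from lpvsup import ToolkitConfig, run_pipeline

result = run_pipeline(ToolkitConfig())
for res in result.bank:
    print(f"Theta_{res.region.index+1} = [{res.region.lo:5.2f}, {res.region.hi:5.2f}]"
          f"  gamma = {res.gamma:.4f}  robust margin = {res.robust_margin:+.4f}")
d = result.dwell
print(f"h_D = {d.h_D:.1f} s  beta_max = {d.beta_max:.2e}")
rep = result.report
print(f"undershoot = {rep.undershoot_mmHg:.1f} mmHg, settling = {rep.settling_time_min:.2f} min")
```

prints

```
Theta_1 = [-9.50, -5.80]  gamma = 0.9432  robust margin = +0.0579
Theta_2 = [-5.80, -3.03]  gamma = 0.9660  robust margin = +0.0346
Theta_3 = [-3.03, -1.42]  gamma = 0.9813  robust margin = +0.0199
Theta_4 = [-1.42, -0.60]  gamma = 0.9953  robust margin = +0.0055
Theta_5 = [-0.60, -0.25]  gamma = 0.9972  robust margin = +0.0044
h_D = 2744.4 s  beta_max = 7.38e-04
undershoot = 16.5 mmHg, settling = 2.45 min
```

Reading this: each of the five regions achieves a stacked norm `γ < 1`, so
every compensator is robustly stable on its region with positive margin
(the margins shrink toward the low-sensitivity end, where the relative
uncertainty is largest).  The switched scenario — sensitivity ramping over
the whole range at sup-rate 0.0085 while the supervisor walks through all
five controllers — settles the 150 → 100 mmHg transient in 2.45 min and
holds the setpoint essentially exactly between ramps, but the initial
transient undershoots 16.5 mmHg: the drug already in the 40 s transport
pipeline keeps acting after the pressure reaches target, an intrinsic cost
of delayed regulation from a decaying initial offset (see
`docs/methods.md` for the analysis and for why the certified rate bound is
stricter than the scenario's rate).

The same run is available from a shell:

```sh
lpvsup pipeline --out results/       # bank + trace.csv + pipeline_report.json
lpvsup fixtures --out fixtures/      # example config + scenario trajectory
```

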