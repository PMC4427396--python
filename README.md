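# mollimap

Bloch-simulation reconstruction of myocardial T1 maps from MOLLI
(Modified Look-Locker Inversion recovery) data.

## Why

MOLLI samples the inversion recovery with ECG-gated single-shot b-SSFP
images in a 3-3-5 scheme, and the conventional post-processing fits the
11 TI-sorted samples to

    S(TI) = A − B·exp(−TI/T1*),      T1 = T1*·(B/A − 1)

(the Look-Locker correction).  Because the correction ignores T2 decay
during the b-SSFP readouts, transmit-field (B1+) deviations of the flip
angle α, and the imperfect efficacy η of the adiabatic inversion, the
standard estimate underestimates T1 — by roughly 15 % for native
myocardium at 3 T.  `mollimap` implements the corrective approach: the
full sequence is simulated with the Bloch equations
(`M_{k+1} = A·M_k + B`, composed from nutation, precession and
relaxation operators), yielding the signal `f(T1, T2, η, α, TI)`, which
is fitted to the measured samples with T1 as the only free parameter
and T2, α, η fixed from auxiliary maps (T2-prepared b-SSFP,
Bloch-Siegert B1+, Bloch-simulated η).

For whom: quantitative cardiac MR researchers who want accurate native
T1 (and downstream ECV) from MOLLI-family data, and anyone needing a
tested forward simulator of ECG-gated inversion-recovery b-SSFP.

The package contains the forward simulator, both estimators, the
adiabatic-pulse inversion-efficacy computation, mono-exponential T2 and
gold-standard IR fitters, Bloch-Siegert phase-to-flip-angle conversion,
a Monte Carlo error-propagation study, a digital phantom generator that
replaces scanner data end to end, and a CLI (`mollimap`).

## Worked example

```python
from mollimap import (AdiabaticPulse, MOLLIProtocol, TissueParams,
                      fit_simulation, fit_standard, simulate_inversion, simulate_molli)

pulse = AdiabaticPulse()
eta = simulate_inversion(pulse, TissueParams(t1=1180, t2=45))
print(f"inversion efficacy eta = {eta:.3f}")

protocol = MOLLIProtocol()                      # 3(3)3(3)5, TI1=100, dTI=80, 60 bpm
tissue = TissueParams(t1=1410, t2=41)           # native myocardium at 3 T
curve = simulate_molli(tissue, protocol, eta=0.92, alpha_actual=24.0)
print("TIs (ms):", curve.sorted().ti.astype(int).tolist())

std = fit_standard(curve)
sim = fit_simulation(curve, t2=41.0, eta=0.92, alpha_actual=24.0, protocol=protocol)
print(f"standard fit:    T1 = {std.t1:7.1f} ms  ({(std.t1-1410)/1410:+.1%} vs truth)")
print(f"simulation fit:  T1 = {sim.t1:7.1f} ms  ({(sim.t1-1410)/1410:+.1%} vs truth)")
```

prints

    inversion efficacy eta = 0.925
    TIs (ms): [100, 180, 260, 1100, 1180, 1260, 2100, 2180, 2260, 3260, 4260]
    standard fit:    T1 =  1221.3 ms  (-13.4% vs truth)
    simulation fit:  T1 =  1410.0 ms  (-0.0% vs truth)

The adiabatic passage loses ~8 % of the inversion to T2 relaxation
(η ≈ 0.92); the standard fit of a noiseless curve at the in vivo
operating point lands at 1221 ms — a 13 % underestimate — while the
simulation-based fit recovers the true 1410 ms exactly.

Map-level pipelines run from the shell, e.g.

    mollimap phantom --grid 64 --seed 1 --outdir phantom/
    mollimap fit --stack phantom/molli.nii --method both \
        --t2-map phantom/t2_true.nii --alpha-map phantom/alpha_true.nii --outdir maps/
    mollimap mc --n-samples 2000 --seed 1 --outdir mc/

See `docs/methods.md` for the model, its assumptions and limitations.

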