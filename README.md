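# hepinsulin

Kinetic modeling of proximal hepatic insulin signaling: how the *dynamics*
of insulin secretion — the first-phase burst after a meal and the ~5-min
portal-vein pulses — are decoded by the liver's IRS1/IRS2–Akt–aPKC network.

The package is built around an ODE model family in which insulin drives a
receptor cycle (activation → internalization → dephosphorylation →
reinsertion), phosphorylated receptors activate IRS1 and IRS2, both IRS
proteins activate Akt, and only IRS2 activates atypical PKC (aPKC). Three
feedbacks define the minimal model **M4**: aPKC inhibits IRS1, aPKC
auto-activates (a Hill-2 positive feedback), and Akt transcriptionally
suppresses IRS2 synthesis. Five further literature-proposed feedbacks can be
toggled to produce the variants M0–M6/M2a, whose fitted-parameter counts are
37/35/33/33/31/29/35/35.

The core prediction is a **bistable aPKC switch** under the control of
active IRS2: the equilibrium curve

```
dpkc/dt = (k_aP·irs2 + v_auto·pkc²/(K_auto² + pkc²))·(1 − pkc) − k_dP·pkc = 0
```

folds at two saddle-node (limit) points, LP1 (switch-on threshold) above
LP2 (switch-off threshold). The hysteresis gap explains why a constant
insulin infusion keeps aPKC on (IRS2 settles above LP2) while the same dose
delivered as 5-min pulses switches it off (IRS2 troughs cross LP2), and why
the aPKC switch-off time — not the activation level — carries the
information in insulin dose, first-phase shape and pulse amplitude.

Who is it for: modelers studying hepatic insulin resistance or hormone-pulse
decoding who want a tested, reusable implementation of the model family, its
input designs, the differential-evolution fitting with AICc/mAICc selection,
and the identifiability workflow — all runnable on synthetic data.

## Worked example

```python
from hepinsulin import (default_truth, feeding_profile, simulate,
                        detect_switch_events, compute_diagram)

params, m4 = default_truth()            # curated minimal-model ground truth
diagram = compute_diagram(params)
print(diagram.lp1.irs2, diagram.lp2.irs2)
# 0.3382 0.2829  -> switch-on threshold above switch-off threshold

traj = simulate(m4, params, feeding_profile(1.0), t_end=120.0)
print(detect_switch_events(traj))
# SwitchEvents(pkc_on=14.9, pkc_off=90.2, irs1_rebound=80.5, akt_rebound=92.2)
```

Reading: after refeeding, aPKC switches on ~15 min after the meal and off at
~90 min; IRS1 and Akt dip while aPKC is on and rebound around the switch-off
— the model's signature temporal separation of IRS2-phase (glucose-production
control) and IRS1-phase (lipogenic/mitogenic) signaling. Scaling the feeding
insulin to 85% or 115% shifts these times earlier/later while leaving the
activation plateaus essentially unchanged.

The numbered scripts under `analysis/` run the full study and write tables
under `results/`: input design (`01`), dose–timing (`02`), bifurcation and
infusion regimes (`03`), first-phase/pulse-amplitude experiments (`04`),
fitting and variant ranking on synthetic data (`05`), and the
identifiability pipeline (`06`). A `hepinsulin` CLI exposes the same steps
(`simulate`, `bifurcate`, `fit`, `identify`, `generate-data`, `profiles`).

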