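"""Simulate the membrane-fed plug-flow reactor at one residence time.

Shows the oxygen balance at work: the membrane supplies O2 along the
channel as the oxidase consumes it, so conversion proceeds without the
dissolved O2 collapsing.  Also prints the dispersion diagnostics that
justify treating the channel as plug flow for small molecules but not for
the enzyme itself.
"""

from titrkin import (
    EnzymeLoad,
    GOX_REFERENCE_PARAMS,
    ReactionState,
    ReactorSpec,
    dispersion_diagnostics,
    saturation_fraction,
    simulate_pfr,
)

params = GOX_REFERENCE_PARAMS["titr_combined"]
spec = ReactorSpec()  # 155 uL, I.D. 230 um, kLa = 6 /min
load = EnzymeLoad(concentration_mg_mL=0.05, catalase=True)
o2_sat = 1.3  # mM, pure O2 at ~1 atm

flow = 25.0  # uL/min
tau = spec.residence_time_min(flow)
out = simulate_pfr(ReactionState(S=400.0, O=o2_sat), tau, load, params, spec, o2_sat)
print(f"flow {flow:.0f} uL/min -> residence time {tau:.2f} min")
print(f"outlet: glucose {out.S:.2f} mM, product {out.P:.3f} mM, O2 {out.O:.3f} mM")
print(f"conversion {out.P / 400:.2%}; O2 held at {out.O / o2_sat:.1%} of saturation")

print(f"\nenzyme-free saturation at fastest flow (tau=1.55 min): "
      f"{saturation_fraction(spec, 1.55):.2%}")

for label, D in (("small molecule", spec.D_small_m2s), ("enzyme", spec.D_enzyme_m2s)):
    d = dispersion_diagnostics(spec, 50.0, D)
    print(f"{label}: dispersion number {d['dispersion_number']:.2e} "
          f"-> plug flow {'OK' if d['low_dispersed'] else 'VIOLATED'}")
print("The enzyme would disperse ~100x more, which is why its feed is held")
print("constant instead of being treated as a plug-flow solute.")
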