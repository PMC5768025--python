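# titrkin

An in-silico tube-in-tube reactor (TiTR) for characterizing the kinetics of
oxygen-dependent enzymes, with the full estimation stack needed to turn
flow-reactor time-series into kinetic parameters.

## The problem

Oxidases such as glucose oxidase are hard to characterize because oxygen is
a substrate you can barely dose: air-saturated water holds only ~276 μM O₂,
while oxygen Michaelis constants of industrially relevant oxidases sit at
or above that level. Experiments confined to air saturation can only reveal
*apparent* constants. A pressurized tube-in-tube reactor solves this: the
liquid flows through a narrow gas-permeable membrane tube (I.D. 230 μm)
and pressurized O₂/N₂ in the annulus supplies bubble-free oxygen all along
the channel, giving dissolved-O₂ setpoints up to ~25-fold above air
saturation. Operated in the low-dispersed laminar regime the channel
behaves as a plug-flow reactor, and slowly ramping the flow rate down
converts a single transient into a full concentration-vs-residence-time
profile ("time-series" data, one initial rate per ~1.4 mL of reagent).

`titrkin` is a digital twin of that instrument plus the statistics on top,
aimed at reaction engineers and enzymologists who want to design, simulate
and analyze such campaigns before (or instead of) building the hardware.

## The model

The rate law is the ping-pong bi-bi expression for an oxidase with glucose
(S) and dissolved oxygen (O) as substrates:

$$ r_E = \frac{k_\mathrm{cat}\, S\, O}{S O + K_{MO}\, S + K_{MS}\, O} $$

with specific rates per mg of liquid enzyme formulation. Catalase coupling
removes H₂O₂ instantaneously, returning half a stoichiometric equivalent
of O₂, so the net oxygen balance along the reactor (residence time τ) is

$$ \frac{dO}{d\tau} = -\tfrac{1}{2} r_E E + k_La\,(c_\mathrm{sat} - O), $$

where `kLa` lumps the membrane mass transfer and `c_sat` follows Henry's
law from gas pressure and composition. The package covers:

* **equilibrium** — anchored Henry's-law calibrations (air at 1 atm →
  0.276 mM; pure O₂ at 6 bar → 7.13 mM; or an explicit constant);
* **kinetics** — the rate law, apparent-constant algebra, catalase
  stoichiometry;
* **reactor** — steady plug-flow integration with membrane supply, the
  flow-ramp method with a quasi-steady validity flag, Taylor–Aris
  dispersion diagnostics, RTD simulation and first-moment volume
  calibration;
* **estimation** — initial-rate extraction, multi-start nonlinear least
  squares for (k_cat, K_MO, K_MS) with linearized/bootstrap 95 % CIs,
  joint two-campaign fits for enzyme-degradation scaling, and
  Fisher-information comparison of experimental designs;
* **synthetic** — seeded generators reproducing the study design
  (glucose 25/100/200/400 mM; O₂ 0.14–1.3 mM at 1 atm and 0.9–7.13 mM at
  6 bar; 3 % multiplicative noise).

## Worked example

Simulate a noisy two-pressure campaign and refit the parameters
(`examples/04_fit_kinetics.py`):

```text
48 simulated initial-rate observations (two pressure campaigns)
kcat  =   17.732 +/-  0.444 umol/min/mg  (truth 17.82)
K_MO  =    0.519 +/-  0.024 mM           (truth 0.52)
K_MS  =   73.094 +/-  3.331 mM           (truth 74.57)
ill-identified: False  (n = 48, RSS = 0.03211)
```

Each parameter is recovered within its 95 % interval; the oxygen Michaelis
constant is tight only because the design spans dissolved O₂ from ~K_MO/4
up to ~14·K_MO — run `examples/06_design_identifiability.py` to see the
Fisher-information comparison against an atmospheric-only design. The
other examples cover the oxygen solubility window, the reactor twin, the
flow-ramp method, and RTD volume calibration; each prints what it computes
and what the numbers mean.

A thin CLI mirrors the workflow (`titrkin synth|rates|fit|rtd|design|twin`),
e.g.:

```bash
titrkin synth --seed 1 --out out/
titrkin fit out/rates_combined.csv --seed 2 --out out/fit.json
```

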