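# The toy plant: network and hand-derived photon optima

This note records, on paper, the photon minima of the four bundled scenario
presets.  The values are frozen in
`multigem.toyplant.HAND_DERIVED_PHOTON_OPTIMA` and the test suite requires
the LP solver to reproduce them to 1e-6.  All stoichiometry is integer or
simple rational, so every step below is exact arithmetic.

## Network (default `ToySpec`)

| reaction | lumped chemistry | photon bookkeeping |
|---|---|---|
| `EX_hv` | photon uptake | the objective |
| `LIGHT_ATP` | 1 hv + ADP + Pi → ATP | 1 photon per ATP |
| `LIGHT_NADPH` | 1 hv + NADP⁺ → NADPH | 1 photon per NADPH |
| `RUBISCO` | CO₂ + 3 ATP + 2 NADPH → sugar | 5 photons per sugar (leaf, day) |
| `RESP_ATP` | sugar → 4 ATP | respiratory yield y = 4 |
| `RESP_NADPH` | sugar → 4 NADPH | y = 4 |
| `NR` + `NiR` | NO₃⁻ + 4 NADPH → NH₄⁺ | 8 electrons per nitrogen |
| `GS` + `GOGAT` | NH₄⁺ + 2-OG + ATP + NADPH → Glu | |
| `AKG_SYNTH` | sugar → 2-OG | carbon skeleton |
| `STARCH_SYN` / `STARCH_DEG` | sugar + ATP ↔ starch | storage costs 1 ATP |
| `BIOMASS` | 2 sugar + 1 Glu + 2 ATP → growth | fixed at 0.1 per tissue and period |

Scenario presets: mass fractions ω_leaf = 1/2, ω_stem = ω_root = 1/4; equal
12 h day/night periods (ω_d = ω_n = 1/2); leaf phototrophic, RuBisCO closed
in stem and root; N uptake in the root only; leaf starch is the only storage
pool; sucrose, glutamate, nitrate and water move through the leaf–stem and
stem–root common pools.  The objective is the time-fraction-weighted photon
flux; with ω_d = ω_leaf = 1/2 the objective value equals the extrinsic
(whole-plant) photon flow during the day, which is what is tabulated below.

## Unit photon costs

Working in extrinsic flows (intrinsic per-gram fluxes times mass fraction).
Per period, whole-plant biomass demands are: sugar 0.2, glutamate 0.1,
ATP 0.2 (each tissue grows at 0.1 with ω summing to 1).

ATP / NADPH, one mole, by place and time (passive transport):

| | leaf day | stem/root day | any tissue, night |
|---|---|---|---|
| sugar | 5 | 5 | 6 (day fixation + 1 ATP storage) |
| ATP | 1 | 5/4 | 6/4 = 3/2 |
| NADPH | 1 | 5/4 | 3/2 |

A glutamate costs 5 NADPH + 1 ATP + 1 sugar (4 NADPH for nitrate→ammonium,
1 for GOGAT) plus the nitrate itself (free at the root).  Ammonium nutrition
skips the 4-NADPH reduction: 1 NADPH + 1 ATP + 1 sugar.

## Passive presets (pw = 0; translocation free)

Cheapest assimilation site: leaf by day (NADPH at 1 photon), and at night all
tissues tie at 15 photons per glutamate (everything is starch-respired at the
same yield).  Nitrate, per period:

* sugar: day 0.2·5 = 1.0; night 0.2·6 = 1.2
* biomass ATP: day 0.1·1 + 0.05·5/4 + 0.05·5/4 = 0.225; night 0.2·3/2 = 0.3
* glutamate: day 0.1·(5+1+5) = 1.1; night 0.1·(7.5+1.5+6) = 1.5

**Z(nitrate, passive) = 1.0 + 1.2 + 0.225 + 0.3 + 1.1 + 1.5 = 5.325 = 213/40**

Ammonium (assimilation forced to the root, where NH₄⁺ enters):
glutamate day 0.1·(5/4 + 5/4 + 5) = 0.75; night 0.1·(3/2 + 3/2 + 6) = 0.9.

**Z(ammonium, passive) = 1.0 + 1.2 + 0.225 + 0.3 + 0.75 + 0.9 = 4.375 = 35/8**

Day starch accumulation equals the night sugar draw (extrinsic):
nitrate 0.2 + 0.05 + (0.125 + 0.025 + 0.1) = 0.5 → intrinsic (per g leaf)
**1.0**; ammonium 0.2 + 0.05 + (0.025 + 0.025 + 0.1) = 0.4 → **0.8**.

## Active presets (pw = 1 on sucrose, glutamate, nitrate exports)

Every export now burns 1 ATP in the exporting tissue, at that tissue's ATP
price, which itself depends on delivered-sugar prices.  Delivered sugar:

* day: leaf 5; stem 5 + ATP_leaf = 6; root 6 + ATP_stem = 6 + 6/4 = 7.5
* night: leaf 6; stem 6 + 3/2 = 7.5; root 7.5 + 7.5/4 = 9.375

and ATP_tissue = sugar_tissue / 4 away from the leaf (leaf day 1, leaf night
3/2).  Summing the demands with the cheapest assimilation route per tissue
(nitrate climbing root→stem→leaf pays the exporters' ATP):

* sugar: day 0.1·5 + 0.05·6 + 0.05·7.5 = 1.175;
  night 0.1·6 + 0.05·7.5 + 0.05·9.375 = 1.44375
* biomass ATP: day 0.26875; night 0.3609375
* glutamate, nitrate source: day 0.05·14.375 + 0.025·15.375 + 0.025·16.875
  = 1.525; night 0.05·19.21875 + 0.025·20.71875 + 0.025·22.59375 = 2.04375
* glutamate, ammonium source (root assimilates, exports upward):
  day 0.05·14.625 + 0.025·13.125 + 0.025·11.25 = 1.340625;
  night 0.05·18.28125 + 0.025·16.40625 + 0.025·14.0625 = 1.67578125

**Z(nitrate, active) = 1.175 + 1.44375 + 0.26875 + 0.3609375 + 1.525 +
2.04375 = 6.8171875 = 4363/640**

**Z(ammonium, active) = 1.175 + 1.44375 + 0.26875 + 0.3609375 + 1.340625 +
1.67578125 = 6.26484375 = 40095/6400**

## Reduction scenario

One tissue (ω = 1), one all-day period (ω = 1), nitrate only, growth 0.1:
0.1·(2·5) + 0.1·(5+1+5) + 0.2·1 = **2.3** photons.

## Qualitative contrasts encoded by these numbers

* nitrate > ammonium in photons (5.325 vs 4.375 passive; 6.817 vs 6.265
  active) — the 8-electron reduction bill;
* nitrate > ammonium in day starch (1.0 vs 0.8 per g leaf) — the night share
  of that bill is paid from starch;
* at pw = 0 nitrate is assimilated in the leaf (root nitrate reductase is
  forced silent at the optimum); by pw = 4 the root's own glutamate is
  cheaper made in place (45 vs 51 photons per mole delivered from the leaf),
  so root nitrate reduction becomes obligatory and leaf glutamate export
  ceases.
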