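# ecllquant

Quantification pipeline for **ex-vivo electrochemical lipolysis (ECLL)**
experiments. ECLL injects saline into subcutaneous adipose tissue, inserts
needle electrodes and applies a few volts: electrolysis of the saline creates
an acid front at the anode and a base front at the cathode, lysing adipocyte
membranes and saponifying triglycerides (TGs). This package implements the
three quantification stages such a study needs, plus a synthetic-data
generator so every stage is testable with known ground truth:

1. **pH-front width mapping** (`ecllquant.ph_mapping`) — a photograph of a
   halochromic-dye-stained tissue cross-section is converted to CIE 1976
   L\*a\*b\*; a user-supplied ROI inside each colored band yields the band's
   mean color μ and the distribution of Euclidean color distances within the
   ROI (mean m, SD s). Pixels with distance ≤ m + k·s (default k = 1) form the
   band mask, which is hole-filled and debris-filtered; the front width is
   the mean mask-pixel count per occupied row × the mm-per-px scale.
2. **Fluorescence particle quantification** (`ecllquant.fluorescence`) —
   median despeckle → intensity threshold → distance-transform watershed →
   per-particle areas in µm². Bodipy particles containing Hoechst nuclear
   signal are counted as adipocytes, those without as free lipid droplets;
   Calcein / Hoechst / EthD-1 channel areas summarize the live/dead assay.
   Also extracts mean-temperature-vs-time traces from infrared frame stacks.
3. **Electrochemical dosimetry** (`ecllquant.dosimetry`) — trapezoidal charge
   integration and the Faraday water budget (m = Q/F · ν · M(H₂O), ν = 0.5
   H₂O per electron for net water splitting); membrane-lysis inversion
   f = [K⁺]_released / [K⁺]_intracellular with [K⁺]_intracellular = 130 mM,
   giving treated volume V = f·V_tissue/n_electrodes and damage-cylinder
   radius r = √(V/(π·d)) at insertion depth d = 12 mm; and the TG
   saponification fraction
   h = c_treated / (c_positive · V_per-electrode/V_sample)
   from free-glycerol concentrations.

## Worked example

The built-in worked example re-derives the potassium/glycerol dosimetry table
from the measured concentrations:

```
$ ecll reproduce-table1 --out /tmp/t1
[PASS] volume_per_electrode[dc_3V]: computed 61.54 vs published 61 (tol 2)
[PASS] volume_per_electrode[cathodic]: computed 146.2 vs published 146 (tol 2)
[PASS] volume_per_electrode[anodic]: computed 46.15 vs published 47 (tol 2)
[PASS] volume_per_electrode[positive_control]: computed 1000 vs published 1000 (tol 2)
[PASS] volume_per_electrode[negative_control]<10: computed 7.692 vs published 10 (tol 0)
[PASS] cylinder_radius[cathodic]: computed 1.969 vs published 2 (tol 0.2)
[PASS] lysed_fraction_pct[cathodic]: computed 14.62 vs published 15 (tol 0.5)
[PASS] lysed_fraction_pct[anodic]: computed 4.615 vs published 5 (tol 0.5)
[PASS] saponified_fraction[cathodic]: computed 0.4086 vs published 0.4 (tol 0.02)
[PASS] saponified_fraction[anodic]: computed 0.4815 vs published 0.48 (tol 0.02)
all checks passed
```

Reading the numbers: cathodic treatment released 19 mM K⁺ per mL of a 3 mL
tissue sample through 3 electrodes, so 19/130 ≈ 14.6 % of the tissue was
lysed — 146 µL per electrode, a damage cylinder of radius
√(146.15/(π·12)) ≈ 1.97 mm around each 12-mm electrode. The treated sample's
4.3 mg/L of free glycerol is 40.9 % of what complete hydrolysis of the
treated volume fraction would yield (72 mg/L × 0.146), so ~40 % of the
liberated TGs were saponified.

End-to-end on synthetic data:

```
$ ecll simulate --seed 3 --out /tmp/sim --anode-width-mm 2.0 --cathode-width-mm 3.0
$ ecll phmap --image /tmp/sim/ph_map.png --anode-roi 60,180,160,181 \
      --cathode-roi 60,180,215,246 --scale-mm-per-px 0.05 --out /tmp/ph
anode 1.93 mm, cathode 2.92 mm
```

Other subcommands: `particles` (adipocyte/droplet counts), `livedead`
(per-channel signal areas), `dose` (charge + water budget from a current
trace CSV), `thermal` (ROI temperature trace).

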