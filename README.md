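# hydrotraits

Quantitative analysis of tree hydraulic traits: sigmoidal xylem-vulnerability
and stomatal-closure curves, pressure–volume analysis of leaf water
relations, conduit/pit anatomy indices, conductance-based flow quantities,
extreme-value operating traits, and assumption-gated two-sample statistics —
plus seeded synthetic-measurement generators so every stage can be verified
end to end without external data.

## Modules

| Module | What it does |
| --- | --- |
| `hydrotraits.sigmoid_curves` | Exponential-sigmoid percent-response model `100/(1+exp(a(P−P50)))`, least-squares fitting, closed-form inversion to 12/50/88% thresholds |
| `hydrotraits.pressure_volume` | 1/Ψ vs. water-saturation-deficit analysis per leaf: osmotic-line/turgescent-parabola segmentation, Ψ_osat, Ψ_TLP, elasticity index |
| `hydrotraits.flow` | Centrifuge PLC series, specific conductivity k_s, native-embolism PLC, root-conductance aggregation |
| `hydrotraits.anatomy` | Circular-equivalent diameters, hydraulically weighted diameter Σd⁵/Σd⁴, wall reinforcement (t/b)², histograms, hierarchical (per-sample-first) means |
| `hydrotraits.stomata_traits` | Percent-g_s normalisation, closure thresholds (Ψ at 88/50/12% g_s), extreme-value g_smax/Ψ_lmin, safety margins, threshold sequencing |
| `hydrotraits.stats_gate` | Two-sample comparison gated by Kolmogorov–Smirnov normality and Levene variance checks (Welch vs. pooled Student) |
| `hydrotraits.synthetic_data` | Seeded generators for vulnerability curves (percent or raw-conductance mode), mechanistic PV leaves, log-normal conduit populations, diurnal gas-exchange courses |
| `hydrotraits.io`, `hydrotraits.report`, `hydrotraits.cli` | Validated CSV readers/writers, full synthetic-campaign pipeline with trait table + gate log, command-line interface |

Conventions: water potentials are stored as **negative MPa** (readers offer
`--auto-negate`); conductances default to kg s⁻¹ MPa⁻¹ with water density
1 g cm⁻³ for the k_s conversion.

## Command line

```bash
# generate synthetic series
hydrotraits simulate vc --a 0.95 --p50 -5.0 --noise-sd 3 --seed 1 --out vc.csv
hydrotraits simulate pv --psi-osat -2.56 --w-tlp 0.1381 --out pv.csv

# analyses
hydrotraits fit-vc vc.csv                 # a, p50, p12, p88, sse per series
hydrotraits fit-pv pv.csv                 # psi_osat, psi_tlp, a_ela per leaf
hydrotraits flow plc-series shoots.csv    # conductance -> PLC series
hydrotraits flow ks --k 1e-4 --length-cm 8 --area-cm2 0.1
hydrotraits anatomy summarize --diameters conduits.csv --walls walls.csv
hydrotraits stomata closure gs_course.csv
hydrotraits stats compare values.csv --group-col treatment --value-col p50

# full synthetic campaign -> trait table + gate/fit log
hydrotraits report --seed 1 --out-dir report/
```

CSV schemas are documented in the `hydrotraits.io` docstrings; validation
errors name the offending file, row and column.

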