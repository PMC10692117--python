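# conflict-spectroscopy

Granular "spectroscopy" of armed-conflict violence: fit discrete power
laws to the severity (battle-death) distributions of conflict events
across space–time segments of a conflict, test each fit with a bootstrap
Kolmogorov–Smirnov procedure, judge whether segment-level exponents are
genuinely distinctive with a random-subsampling null, and interpret the
exponent through a two-population coalescence–fragmentation model of
conflict-actor grouping dynamics.

The package is aimed at conflict researchers working with georeferenced
event data in a UCDP-GED-like schema (one row per violent event: date,
department, actor dyad, best fatality estimate, geo-precision code), and
at modellers studying how actor strength ratios shape severity
distributions.

## The model

Event severities `x` (battle deaths, integers ≥ 1) above a threshold
`x_min` are modelled by the discrete power law

    p(x) = x^(−α) / ζ(α, x_min),          x = x_min, x_min+1, …

where `ζ(α, x_min)` is the Hurwitz zeta function. On a log–log plot the
complementary CDF `P(x) = Pr(X ≥ x)` is asymptotically a straight line of
slope `−(α − 1)`. The pipeline estimates `α` by maximum likelihood,
chooses `x_min` by minimising the KS distance between the empirical and
model tail CDFs (the Clauset–Shalizi–Newman procedure for discrete data),
and computes a goodness-of-fit P-value by a semiparametric bootstrap
(5000 iterations by default); the power law is accepted when P ≥ 0.1.

To ask whether a region's exponent means anything, the subsampling null
draws 50 random same-sized subsets of the period's pooled events, refits
each, and flags the region when its actual `α` falls outside the draws'
25th–75th-percentile band and outside mean ± 1 SD.

The coalescence–fragmentation simulator gives the exponent a mechanistic
reading: two populations `N_a` (government) and `N_b` (insurgents) form
armed groups that merge when same-side agents meet and fight when
opposing agents meet, with losses scaled by attrition coefficients
`C_S`/`C_L` applied to the smaller engaged group. Balanced strengths
reproduce `α ≈ 2.5`, the value repeatedly reported for insurgency-type
conflicts; growing asymmetry `N_a : N_b` steepens the fitted exponent, so
`α` acts as a proxy for the local strength ratio.

## Worked example

Generate the bundled synthetic fixture (3517 raw rows shaped like a
three-decade national conflict: 3303 valid events across 7 regions and
three periods, plus 214 planted low-geo-precision rows) and run the
pipeline on it:

```python
from conflict_spectroscopy import FilterConfig, RunConfig, run_full_analysis
from conflict_spectroscopy.synthetic import make_colombia_fixture, write_fixture

table, manifest = make_colombia_fixture(seed=11)
write_fixture(table, manifest, "events.csv", "manifest.json")
cfg = RunConfig(
    input_path="events.csv", output_dir="results",
    filter_config=FilterConfig(actor_whitelist=frozenset(manifest["actors"])),
    n_boot=1000, seed=11, scopes=("country", "region"), run_subsampling=False,
)
bundle = run_full_analysis(cfg)
print(bundle.fits[bundle.fits.scope == "country"].to_string(index=False))
```

```
  scope unit period  n_total  n_tail  xmin    alpha  ks_stat  p_value
country  ALL    ALL     3303    1635     2 2.341660 0.016410    0.052
country  ALL     P1      776     209     3 2.636430 0.029072    0.474
country  ALL     P2     2221    1176     2 2.315560 0.008381    0.834
country  ALL     P3      306     306     1 2.353732 0.023532    0.140
```

Each row is one space–time segment: `n_total` events, of which `n_tail`
lie at or above the selected threshold `xmin`; `alpha` is the fitted
exponent, `ks_stat` the tail KS distance, and `p_value` the bootstrap
GOF P-value (≥ 0.1 ⇒ the power law is plausible). Per-period exponents
near 2.3–2.6 with high P-values are exactly what the generator planted;
the filter audit (`results/audit.json`) reports the 214 planted
low-precision rows removed:

```
audit: {'n_input': 3517, 'n_kept': 3303, 'removed_geo_precision': 214}
```

The simulator is available from the shell:

```sh
$ spectroscopy simulate --na 5000 --nb 5000 --steps 5000000 --burn-in 1000000 --seed 1 --out sim.csv
2000677 events -> sim.csv
alpha=2.506 xmin=18 n_tail=5967 D=0.02333
```

— a balanced run whose two million battle events carry the α ≈ 2.5
signature. `spectroscopy run --config cfg.yaml` drives the full event
pipeline from a YAML config, and `spectroscopy synth` emits the fixture.

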