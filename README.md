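# ontopace

Tools for studying the **ontogeny of movement behaviour** in juvenile
birds from GPS telemetry — written around the natural experiment offered
by conservation releases of Egyptian vultures (*Neophron percnopterus*),
where wild-hatched birds fledge about one month before their first
migration while captive-hatched birds are released four (spring) or nine
(winter) months before departure. The package is for movement ecologists
and biostatisticians who want a tested, scriptable version of this
analysis chain, from raw fixes to group-level inference, plus a synthetic
data generator so the whole pipeline can be exercised and validated
without field data.

## What it computes

**Daily maximum displacement.** GPS fixes are resampled to a common
60-minute interval; days with fewer than 10 locations are dropped;
fledging is the first day a bird is ≥ 200 m from its nest; each retained
day's displacement is the furthest great-circle distance from the day's
first fix (the assumed night roost).

**Performance curves.** Log displacement `y = log(km)` versus day `t`
since fledging/release is fitted with five competing families,

- null: `y = c`
- linear: `y = a + b·t`
- exponential: `y = a·e^{k·t}`
- asymptotic (rise-to-limit): `y = plateau − (plateau − init)·e^{−k·t}`
- four-parameter Weibull sigmoid:
  `y = lower + (upper − lower)·exp(−exp(slope·(log t − log t_infl)))`,
  increasing for `slope < 0`

and the most parsimonious family is selected by BIC: among models within
2 BIC units of the minimum, the one with fewest parameters wins.
Population-level curves are estimated on the median (L1 objective,
robust to the heavy scatter of pooled data); individual curves on the
mean (L2). Threshold crossings (e.g. the day the curve reaches 2 km, or
the 8.1 km wild-bird benchmark) are extracted with bracketing/bisection,
and confidence bands come from a cluster bootstrap that resamples whole
birds.

**Variability.** Between-individual spread per group is the median
absolute deviation (MAD) of displacement pooled over a 3-day moving
window, smoothed with a fixed-df regression spline on the log scale, and
compared across groups by confidence-interval overlap.

**Group comparison.** Log displacement in the first 20 days after
fledging/release and the last 20 days before migration is modelled with
group-specific quadratic day trends, per-individual random intercepts
and slopes whose covariance is grouped by rearing type, and
group-specific residual variances, fitted by maximum likelihood.
Distributions of days-to-benchmark are compared with a Brown–Forsythe
(median-centred Levene) test and a Kruskal–Wallis test.

## Worked example

```python
import ontopace as op

res = op.run_study(seed=1)          # simulate all three groups, run everything
print(res.population_selection)
print({g: round(c, 1) for g, c in res.crossing_2km.items()})
print(res.window_fits["post_fledge"].group_means.round(2))
```

prints

```
{'wild': 'asymptotic', 'spring': 'exponential', 'winter': 'weibull4'}
{'wild': 0.6, 'spring': 54.2, 'winter': 149.9}
    group  mean_km  ci_low_km  ci_high_km
0  spring     1.22       0.93        1.51
1    wild     8.33       6.74        9.92
2  winter     0.58       0.42        0.75
```

Read: the wild group's pooled median curve is an asymptotic rise that
passes 2 km within its first day, while the spring- and winter-released
groups (exponential and late-sigmoid curves) take ~54 and ~150 days to
reach the same distance; in the first 20 days wild birds average 8.3 km
per day against ~1 km for released birds — the time-constraint pattern
the study design builds in. The same object carries the MAD smooths, the
pre-migration window model (where the group means converge), individual
classifications and the latency tests.

The same stages are available from the shell:

```sh
ontopace simulate --group winter --n 17 --seed 42 --out disp.csv
ontopace fit-curves --displacement disp.csv --level population --out fits.csv
ontopace variability --displacement disp.csv --out mad.csv
ontopace compare-groups --displacement disp.csv --out summary.json
```

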