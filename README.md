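# icuqa — scoring engine for a rapid ICU quality-of-care checklist

`icuqa` implements, as a scriptable and tested engine, a quality-of-care
assessment instrument for intensive care units in resource-limited settings:
a checklist of **44 structure and process indicators** that an external
assessor can collect during a one-hour ICU visit by three methods — direct
observation (A), chart review (B), and interview with the responsible
physician or nurse (C) — together with its **26-point scoring protocol**.
The instrument was developed for level-II COVID-19 ICUs in Lebanese public
hospitals and deliberately excludes outcome measures (mortality is too
case-mix-sensitive for rapid unit-level comparison); it covers the structure
and process arms of the Donabedian framework across six domains: staffing,
infrastructure, equipment/drugs, clinical management, protocols, and
training & development.

## The scoring protocol

Of the 44 indicators, 33 can be dichotomized against a minimum standard
(e.g. nurse/patient ratio ≥ 0.5, arterial-blood-gas turnaround ≤ 15 min,
head-of-bed elevation ≥ 80% of intubated patients, > 12 charted blood-pressure
values). These form 26 one-point **score items**: 22 singletons and 4 groups
(of 3, 4, 2, and 2 indicators) that earn their point only if *all* members
pass. For a visit with item scores `s_i ∈ {0, 1}`:

```
total = max(0, Σ s_i − Σ p_i),        percentage = 100 · total / 26
```

where `p_i = 1` for every item containing a missing response (the item also
earns zero) — the *missing-data penalty*. Per-domain subscores (maxima
3/5/2/12/2/2) localize quality gaps.

The package ships the instrument as a versioned YAML registry, reads visit
records as long-format CSV or JSON, and adds comparison/trend reporting,
duplicate-collector concordance (percent agreement and Cohen's kappa on the
dichotomized classifications), and a seeded synthetic-visit generator with
low- and high-resource archetypes for testing and calibration.

## Worked example

```python
import icuqa

reg = icuqa.default_registry()
prof = icuqa.shipped_archetypes()["low_resource"]
visit = icuqa.generate_assessment(prof, reg, seed=7)
report = icuqa.score_assessment(visit, reg)
print(report.total_points, report.max_points, report.percentage)
print(dict(report.domain_subscores))
print(icuqa.gap_summary(report)[["domain", "item_id", "reason"]].head(4))
```

prints

```
12 26 46.2
{'staffing': (2, 3), 'infrastructure': (1, 5), 'equipment_drugs': (1, 2),
 'clinical_management': (6, 12), 'training_development': (1, 2), 'protocols': (2, 2)}
                domain item_id        reason
0  clinical_management   CLM11        failed
1  clinical_management    CLM2        failed
2  clinical_management    CLM3  missing data
3  clinical_management    CLM5        failed
```

— this simulated under-resourced unit earned 12 of 26 points (46.2% of
maximum); the gap list names the items to target, here mostly clinical
management, including one item (CLM3, the charted-vital-signs documentation
group) lost to the missing-data penalty rather than to an outright failure.

The same is available from the shell:

```bash
icuqa validate                      # -> registry OK: 44 indicators, 26 items
icuqa simulate --profile low_resource --n 1 --seed 7 --out visits/
icuqa score --in visits/icu-low_resource-000.csv --out report.json
icuqa compare --in report1.json --in report2.json
icuqa agreement --in collector1.csv collector2.csv
```

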