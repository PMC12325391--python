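# ssdcompliance

Heavy-metal limit-value screening of agricultural topsoil under the EU Sewage
Sludge Directive (86/278/EEC).

Spreading sewage sludge on farmland is banned wherever the concentration of
one or more regulated heavy metals (As, Cd, Cr, Cu, Hg, Ni, Pb, Zn) in the
soil exceeds a limit value (LV). Member States transposed the Directive's
Annex IA limits in different ways — some fixed, some banded by soil pH, some
by soil texture — so whether a given field may receive sludge depends on which
limit set applies. This package is for environmental scientists and policy
analysts who need to screen per-sample topsoil survey data (LUCAS-style
records with pH, particle-size fractions, and aqua-regia pseudototal
concentrations in mg kg⁻¹ dry matter) against those regimes and quantify how
national transpositions compare with the EU baseline.

## The indices

For metal *i* with measured concentration *Cᵢ* and applicable limit *LVᵢ*, the
single **Contamination Rate Index** is

    CRIᵢ = 100 · Cᵢ / LVᵢ      (capped at 100)

and the per-sample **Overall Contamination Rate Index** is the one-out-all-out
maximum

    OCRI = max_i CRIᵢ .

A sample *exceeds* when some concentration is strictly above its limit
(CRIᵢ raw > 100); a concentration exactly at the limit gives OCRI = 100
without exceedance. Limits are resolved under four strategies:

* **EU_LL / EU_UL** — the Directive's fixed lower/upper limits (As = 25.5 and
  Cr = 100 mg kg⁻¹ are cross-national average substitutes, as the Directive
  sets none);
* **EU_PH** — the Directive's pH-banded limits (pH ≤ 6 / 6 < pH ≤ 7 / pH > 7;
  six metals only — no As or Cr);
* **NATIONAL** — the 48 national and regional transpositions, several banded
  by pH (e.g. Carinthia, Bulgaria, Portugal) or by texture category (Germany,
  Poland, Czech Republic; USDA texture classes collapsed onto each country's
  categories).

The per-sample **compliance grade** is the ratio OCRI_Nat / OCRI_EU on the
six-metal subset: < 0.80 means the EU limits are stricter, > 1.30 means the
national limits are stricter, and [0.80, 1.30] is a good balance. Censored
concentrations (below the limit of quantification) enter all indices at half
the LOQ. Limit values themselves can be screened against published median
soil screening values at negligible / intermediate / unacceptable risk
levels.

## Worked example

```python
import ssdcompliance as ssd

samples = ssd.filter_agricultural(ssd.fixture_small())
reg = ssd.default_registry()

r = ssd.compute_ocri(samples[1], ssd.Strategy.EU_LL, reg)
print(r.sample_id, r.ocri, r.limiting_metal.value, r.exceeds)
# F02 100.0 Ni True
print(r.cris[ssd.Metal.Ni].cri_raw)    # 150.0  (Ni 45 vs limit 30)

grades = ssd.grade_samples(samples, reg)
g = next(g for g in grades if g.sample_id == "F15")
print(round(g.ratio, 3), g.category.value)
# 5.0 national_stricter
```

Sample F02 carries 45 mg kg⁻¹ nickel against the EU lower limit of
30 mg kg⁻¹: its raw Ni index is 150, capped to an OCRI of 100 with an
exceedance flag — no sludge may be spread there. Sample F15 is a Danish
record whose national Ni limit (15 mg kg⁻¹) is far stricter than the EU
pH-banded one (75 mg kg⁻¹ at its pH), so its compliance ratio of 5.0 grades
`national_stricter`.

The same analysis is available from the shell:

```sh
ssd-compliance generate --seed 1 --out data/          # synthetic survey + truth labels
ssd-compliance assess --strategy EU_LL --input data/samples.csv --out ocri.csv
ssd-compliance compliance --input data/samples.csv --out grades.csv
ssd-compliance aggregate --strategy NATIONAL --input data/samples.csv --out nuts0.csv
ssd-compliance report --input data/samples.csv --outdir report/
ssd-compliance limits show UK
ssd-compliance limits screen EU
```

Exit codes: 0 success, 1 data or resolution error (diagnostics name the
offending row/code), 2 usage error. Machine CSVs keep full float precision;
the text report rounds for display.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a seeded synthetic multi-country
survey — generation, CSV round-trip, agricultural filtering, CRI/OCRI under
all four strategies, per-metal exceedance tables, NUTS0/NUTS2 aggregation,
and compliance grading — and writes the results JSON to `--out`.

## Layout

| Module | Role |
| --- | --- |
| `sample_model` | record types, CSV I/O, validation, half-LOQ imputation, land-cover filtering |
| `texture_classifier` | USDA texture triangle; German/Polish/Czech category mapping |
| `limit_registry` | all limit-value sets (packaged transcription) and per-sample resolution |
| `contamination_indices` | CRI/OCRI, capping, one-out-all-out exceedance |
| `compliance_assessment` | OCRI_Nat/OCRI_EU grading; risk-level screening of limits |
| `aggregation_reporting` | NUTS0/NUTS2 means, SDs, exceedance rates; report files |
| `synthetic_lucas` | seeded survey generator with censoring and planted exceedances |
| `cli` | `ssd-compliance` command-line interface |

See `docs/methods.md` for the modelling and numerical conventions.
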