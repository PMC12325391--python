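# Methods

## Model

The package implements a regulatory screening, not a statistical model: each
topsoil record is compared against the heavy-metal limit values (LVs) that
govern sludge spreading at its location, and the comparison is summarised as
ratio indices.

For metal *i* with effective concentration *Cᵢ* (mg kg⁻¹ dry matter,
aqua-regia pseudototal) and resolved limit *LVᵢ*:

* single index `CRIᵢ = 100 · Cᵢ / LVᵢ`, capped at 100;
* overall index `OCRI = maxᵢ CRIᵢ` over the evaluated metals
  (one-out-all-out);
* exceedance is strict: a sample exceeds iff some raw `CRIᵢ > 100`.
  A concentration exactly at its limit yields OCRI = 100 *without*
  exceedance — the Directive bans spreading where a concentration *exceeds*
  the limit, so equality is compliant. Ties for the limiting metal break on
  the fixed metal ordering (As, Cd, Cr, Cu, Hg, Ni, Pb, Zn).

Capping is applied at the CRI level, before any maximum or regional mean, so
aggregated values stay in (0, 100] and a region where every sample exceeds
averages to exactly 100.

Metals that were not measured (e.g. mercury missing from one country's
records) or that have no limit under a regime (As/Cr under the pH-banded EU
regime) are *excluded* from the maximum, never treated as zero, and the set
of metals actually evaluated is recorded on every result.

### Assumptions

* Concentrations are pseudototal (aqua-regia) values in mg kg⁻¹ dry matter;
  no bioavailability correction is attempted, mirroring how the limit values
  themselves are defined.
* Below-LOQ censoring is handled by half-LOQ substitution, the convention of
  the large harmonised European topsoil surveys. Default LOQs (mg kg⁻¹):
  As 2.84, Cd 0.07, Cr 0.32, Cu 0.26, Hg 0.054, Ni 0.27, Pb 1.16, Zn 2.12;
  overridable per run.
* A cell beginning with `<` is censored; its numeric tail is ignored in
  favour of the configured per-metal LOQ (one fixed LOQ per metal governs
  the substitution).

## Limit-value resolution

The registry ships as a plain-text transcription (`data/limit_values.csv`,
one row per limit set) so it can be reviewed independently of code. It holds
the EU lower/upper sets, the three pH-banded EU sets, and 48 national or
regional sets.

* **pH bands** copy the printed endpoint conventions literally: "6 ≥ pH" is a
  closed upper endpoint, "6 < pH ≤ 7" half-open, "pH > 7" open below.
  National regimes use their own cut points (Carinthia 5.5/6.5, Bulgaria 7.4,
  Slovenia 6, Spain 7, Portugal 5.5/7, Malta 6/7). Registry construction
  verifies that each regime's bands partition (0, 14) with every cut point
  owned by exactly one band.
* **Texture bands** (Germany: sand / loam–silt / clay; Poland: light /
  medium / heavy; Czech Republic: coarse sands vs common soils) are resolved
  by first classifying the sample's sand/silt/clay fractions on the USDA
  texture triangle, then collapsing the twelve classes by general texture
  group: {sand, loamy sand} → coarse, {sandy clay, silty clay, clay} → fine,
  the seven intermediate classes → medium. The Czech "common soils" category
  is the complement of its coarse group, so Czech fine-textured soils use the
  common-soils limits.
* **Substituted values**: the Directive sets no As or Cr limits, so the EU
  sets carry cross-national average substitutes (As 25.5, Cr 100 mg kg⁻¹),
  stored as given constants and flagged `substituted`, never recomputed —
  the averaging set behind them is not reconstructible from the printed
  table. National entries marked as "data not found, average used" carry the
  same flag. A few transcribed oddities are deliberate: Slovenia's
  above-pH-6 limits are *lower* than its acid-soil limits, and the Austrian
  rest-of-regions row has non-round substituted values; both are kept
  verbatim. No ordering between national and EU limits is assumed anywhere
  (Denmark's national limits sit below the EU lower set).
* **Jurisdiction**: a sample's `region_code` wins when it names a regional
  regime (Austrian Länder, Belgian regions); otherwise the country code is
  used, with ISO aliases GR→EL and GB→UK accepted. Austria without a matching
  region falls back to the rest-of-regions set; Belgium has only regional
  regimes, so a Belgian sample without a region code is a resolution error.

## USDA texture classification

`classify_usda` implements the canonical triangle inequalities with a fixed
evaluation order, so boundary compositions resolve deterministically.
Fractions must lie in [0, 100] and sum to 100 within 1 percentage point; they
are renormalised to sum exactly 100 before classification (survey fractions
are rounded). The classification is total and unique: all 5,151 integer
compositions receive exactly one class (verified by enumeration in the test
suite).

The commonly printed per-class min–max range tables are bounding boxes, and
three of them understate the canonical polygons (loamy sand reaches sand 90,
sandy loam sand 85, silt loam silt 88 on the integer grid); the
implementation follows the triangle, not the boxes.

## Compliance grade

The grade is computed **per sample and then averaged** for country reports
(not as a ratio of averages): `ratio = OCRI_Nat / OCRI_EU` on the six-metal
subset {Cd, Cu, Hg, Ni, Pb, Zn} (As and Cr have no pH-banded EU limits), with
categories

* `eu_stricter` — ratio < 0.80,
* `balanced` — 0.80 ≤ ratio ≤ 1.30 (both boundaries inclusive),
* `national_stricter` — ratio > 1.30.

The ratio is always defined: half-LOQ imputation with positive limits keeps
every OCRI strictly positive. When a metal is missing on one side, its
per-metal ratio is absent rather than imputed.

## Risk screening

Limit values are banded against median soil screening values at three risk
levels (negligible / intermediate–warning / potentially unacceptable), e.g.
Cd 0.7/3.0/6.0, Ni 35/140/175, Pb 83/195/450 mg kg⁻¹. Intervals are
lower-exclusive and upper-inclusive — fixed so that a Cd limit of exactly
3.0 classifies between negligible and intermediate. One consequence worth
noting: a Ni limit of 30 classifies *below* the negligible median of 35,
even though loose readings sometimes group the 30–75 Ni range as a block.

## Aggregation

NUTS0/NUTS2 summaries are arithmetic means of capped OCRI values with
*sample* standard deviations (n−1 denominator; the convention is not
universal, but is the common reporting choice) and exceedance percentages.
SD is absent for single-sample regions rather than zero. NUTS codes are
opaque strings: no geometry or NUTS-version remapping is performed.

## Synthetic data generator

The generator emulates the *structure* of a harmonised topsoil survey so the
pipeline is testable without the registration-gated real data:

* per-country lognormal metal concentrations (log-mean/log-sd configured per
  metal);
* truncated-normal pH spanning the acid/neutral/alkaline bands;
* Dirichlet sand/silt/clay fractions, rounded and repaired to sum to exactly
  100;
* censoring applied after drawing (draw, then compare with the LOQ),
  mimicking the measurement process;
* optional planted exceedances: a configured fraction of samples draws the
  target metal's concentration uniformly in (1, 2] × its resolved limit, so
  exceedance status is true by construction and recorded in a truth table.

Randomness uses one global seed with per-country substreams derived from a
CRC of the country code, so adding a country never perturbs the draws of
existing ones.

Default magnitudes (geometric means As 7, Cd 0.25, Cr 40, Cu 16, Hg 0.05,
Ni 18, Pb 22, Zn 55 mg kg⁻¹ with log-sd 0.6–0.8) are test scaffolding chosen
once so that Ni and Cd straddle the EU lower limits and Hg straddles its LOQ;
they are **not** estimates of real European soil distributions. The generator
produces no spatial autocorrelation and no realistic marginal distributions,
so a green test establishes the pipeline's arithmetic and plumbing, not
agreement with any real survey's exceedance rates.

## Numerical choices and edge cases

* Validation: pH must lie in (0, 14); texture fractions in [0, 100] with sum
  100 ± 1.0; negative concentrations rejected. Invalid rows are rejected
  individually with a per-row diagnostic; a missing column is a schema error
  naming the column.
* A sample is never dropped for a missing metal; the measurement is simply
  absent and propagates as such.
* CSV round-trip is exact: floats are written via `repr`, so
  `write_samples(read_samples(f))` reproduces all field values bit-exactly.
* Report text rounds to one decimal; machine CSVs keep full precision.

## Known limitations

* The registry reflects the transpositions as compiled around the 2009
  survey; post-2009 national legislative updates are out of scope.
* Sludge composition limits (Annex IB) and annual load limits (Annex IC) are
  not modelled.
* No map rendering, spatial interpolation, or NUTS geometry handling.
* The national-vs-EU comparison inherits whatever inconsistencies the
  underlying national tables contain; the package reports them rather than
  harmonising them.
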