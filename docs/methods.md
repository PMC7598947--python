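# Methods

## Scope and data model

The toolkit analyses one retrospective year of a de-facto census: persons
enumerated with completed age in years (integer), sex, household key and
socio-demographic covariates; birth events keyed to mothers; and death
records from two sources, the census interview itself and burial-association
registers. Ages are completed years throughout, because every terminal-digit
index requires integer ages. Age bands are closed-open [x, x+n) with an
open-ended terminal band (default 85+). Validation flags problem records
(missing or unparseable age, birth flags outside women 15–49) and keeps
them: silent deletion is itself a bias mechanism in surveillance data.
Records without an age are excluded only from age-dependent indices.

## Indicators

Crude rates use the full enumerated population as the mid-year denominator.
ASFRs are kept in per-woman units (the per-1000 form is a display scale);
TFR = 5 × ΣASFR holds as an exact identity. GRR splits births into
daughters by the observed infant sex ratio, applied proportionally across
maternal age bands. NRR discounts GRR by survivorship to the ASFR-weighted
mean of the band midpoints, interpolated linearly on l(x); when no external
survivorship is supplied, it comes from a life table built on the input
data itself. The 1–4 child mortality proxy is deliberately expressed per
1000 live births — the source surveillance convention, unconventional but
reproduced as stated; an exposure-based alternative
(`child_mortality_conventional`) is provided. Median age uses the
lower-value convention on ties. Display rounding (rates to 1 decimal,
reproduction rates to 2, sex ratios to integers) lives only in
`IndicatorReport.rounded()`; full precision is retained internally.

## Age-reporting quality

Whipple's index is evaluated on ages 23–62 (the standard convention; the
digit-specific variant scales the denominator by 1/10 per digit so 100
remains the no-preference baseline, 1000 the single-digit maximum). Myers'
blended index uses the equal-decade-span formulation: over a range of D
whole decades, the digit sums run over the first D−1 and the last D−1
decades, are blended with weights d+1 and 9−d, and the index is half the
sum of absolute deviations of the blended percentages from 10. This is the
variant for which a rectangular age distribution scores exactly 0 and
total concentration on one digit scores exactly 90; formulations with
unequal spans do not have the zero property. The UN joint score is
3 × (mean absolute successive difference of band sex ratios) plus the mean
absolute deviations of male and female age ratios from 100, with age
ratios defined against the arithmetic mean of the flanking bands and
terminal bands excluded; bands run from 0–4 up to the last band fully
below 70. Classification bands: Whipple <105 highly accurate, <110 fairly
accurate, <125 approximate, <175 rough, else very rough; joint score <20
accurate, 20–40 inaccurate, >40 highly inaccurate.

## Abridged life table

Central death rates m(x) = D(x)/P(x) convert to probabilities via
q(x) = n·m/(1 + (n−a)·m) with a(0) = 0.3, a(1–4) = 1.5 and n/2 elsewhere —
the usual high-mortality defaults, configurable per band because published
surveillance tables rarely state their a(x) choices and e0 can shift by a
few tenths of a year between conventions. Radix 100,000; the open interval
takes q = 1, L = l/m, e = 1/m, so it requires a positive death count (or a
substituted fallback rate). Survivorship lookups interpolate l(x) linearly
between exact ages; they are exact at band boundaries.

## Sensitivity scenarios

External infant/child mortality rates substitute into the 0 and 1–4 bands
against those bands' mid-period populations — band population, not live
births, is the exposure that makes external per-1000 rates commensurate
with the band death counts they replace. Expected counts round half-up to
integers; gaps are expected − observed and additive across bands. Scenario
life tables rebuild the full table with only the substituted D(x) changed,
so substituting the observed rates is an exact fixed point. Where a
published comparison count is arithmetically inconsistent with its own
rate and denominator, the computed value is reported and the discrepancy
flagged rather than matched.

## Two-source death reconciliation

Burial registers carry only names, sex and dates, so matching is a
deterministic desk proxy for field verification: keys are case-folded,
diacritic- and punctuation-stripped, whitespace-collapsed; a pair matches
on equal key and sex with dates within a configurable window (default 30
days); matching is greedy one-to-one in ascending date distance with
record-order tie-breaks, hence fully reproducible. The deduplicated union
is treated as the working death set — no capture-recapture correction is
applied, so "missed by census" = (union − census)/union is a lower bound
on true omission (deaths absent from both sources stay invisible).
Age-class fractions use union records with known age; unknown-age records
are counted and warned about.

## Crude odds ratios and wealth index

Crude ORs are cross-products with Woolf CIs; zero cells take the
Haldane–Anscombe +0.5 correction and are flagged. Single-covariate logistic
Wald intervals are asymptotically identical to Woolf, so published CIs fit
to ±0.01–0.02 regardless of which was used. The multivariable logistic fit
delegates to statsmodels' IRLS GLM with dummy coding against stated
reference levels; |coefficient| > 15 flags probable separation. The wealth
index is the first principal component (scikit-learn) of the standardised
binary asset matrix, sign-oriented so more assets score higher, binned
into equal-count quantiles (sizes differ by ≤ 1); constant asset columns
are dropped with a warning.

## Synthetic census generator

The generator states a single-year world: households (size 1 + Poisson,
mean 4.9 persons), ages drawn from the stable distribution
p(a) ∝ l(a)·e^(−ra) implied by the mortality schedule (default growth
r = 0.025), sex at birth 105 males per 100 females, and covariates with
field-realistic marginals (17% urban, 89% protestant, 96.5% Sidama).
Default ASFR is the observed southern-Ethiopian schedule (TFR ≈ 2.87);
default mortality is a high-infant, low-adult profile giving a CDR near
5–6 per 1000. Each woman 15–49 bears a birth with her band ASFR passed
through a logistic link shifted by any configured covariate coefficients;
the default covariate model is empty, since adjusted effect sizes for this
population are not established — association recovery tests plant explicit
coefficients. Each person carries a retrospective death event with the
age-banded rate; deaths reach the census source with probability
1 − omission(age) and the register with an independent coverage
probability. Default omission ({<1: 0.8, 1–4: 0.6, 5+: 0.3}) and coverage
(0.95) are illustrative magnitudes consistent with field reports of
infant deaths being several-fold under-reported; they are not estimates.
Heaping rounds ages ≥ 23 (the Whipple range floor; child ages are usually
documented) to the nearest multiple of 5 with probability 0.5 by default —
the value a combined Whipple near 300 implies under this operator
(index ≈ 100 + 400·h). True ages are retained in the truth record.

What the generator does **not** emulate: migration, multi-year dynamics,
stillbirth/neonatal misclassification, correlated household mortality, or
digit preference other than multiples of five. A green recovery test
therefore establishes correctness of the estimators under the stated
error mechanisms, not robustness to every field pathology.

## Numerical and testing choices

Everything random flows from one `numpy.random.Generator` seed; fixtures
are byte-stable. Monte-Carlo recovery tests state their tolerances in
advance (TFR mean within 0.1 over 50 seeds at n ≈ 25,000; omission
probability within 4 binomial standard errors pooled over seeds) and run
the fertility recovery with heaping disabled, because heaping is a
separately-tested mechanism whose band-migration bias would otherwise
contaminate the fertility check. Ensemble sizes in tests are scaled to
keep the suite under a few minutes on one CPU.

## Known limitations

Index values computed on heaped data depend on the (unknown) true age
distribution, so published index values from other sites are
classification anchors, not exact targets, unless their single-year counts
are available. The reconciliation "missed" fractions are lower bounds (no
capture-recapture). Life-table e0 from one year of a ~25,000-person census
carries sampling error of roughly ±2 years, dominated by sparse old-age
death counts.
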