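# Methods

## Natural-history model

Untreated cervical disease is modelled as a discrete-time Markov cohort
over seven states — UNTESTED (disease-free), HPV infection, CIN 1, CIN 2,
CIN 3, CANCER, DEAD — with one fixed annual transition matrix; there is
no age- or time-dependence and no individual-level microsimulation (the
cohort occupancy vector carries expected counts, possibly fractional).
DEAD is absorbing; CANCER cannot regress. The bundled matrix gives, for
example, an annual 0.123 probability of acquiring HPV infection from the
disease-free state, 0.04 CIN 3 → cancer progression, and 0.239
cancer-specific annual mortality (equivalently a 0.761⁵ ≈ 25 % five-year
survival). Validation on input enforces entries in [0, 1], row sums
within 1e-6 of 1 (absorbing the 3-decimal rounding of published
matrices; re-normalisation is off by default), the absorbing DEAD row
and the non-regressing CANCER row.

The simulation horizon is 15 one-year cycles: roughly the ten years
precancerous lesions take to progress plus a five-year survival window.
Occupancy is counted at the **end of each cycle** with no half-cycle
correction; the plain vector–matrix iteration is the stated procedure
and a half-cycle convention would be an unverifiable embellishment. All
derived series use the same convention: follow-up year *j* (1-based) is
described by the end-of-cycle-*j* occupancy, onset age
`start_age + j − 1`, and incident deaths `DEAD(j) − DEAD(j−1)`.

Convergence: the live 6×6 block of the bundled matrix has dominant
eigenvalue ≈ 0.9972, so live mass decays like 0.9972ⁿ and falls below
1e-3 per starting person only around n ≈ 2,500 cycles; the property
suite checks full absorption at n = 3,000.

## DALYs

DALY = YLL + YLD in the GBD-1996 age-weighted, continuously discounted
form. The burden of `L` years at disability weight `D` from onset age
`α` is the closed form of
`∫₀ᴸ D·C·(α+x)·e^{−β(α+x)}·e^{−γx} dx`
with γ = 0.03 (social discount rate), β = 0.04 (age weighting) and
C = 0.1658 (age-weighting correction constant as used in the study
calibration; the more common GBD value 0.16243 can be supplied as
data). The unweighted/undiscounted K = 0 variant (β + γ = 0) is
deliberately out of scope and raises.

Disability weights: 0 below CIN 2, 0.1238 (CIN 2), 0.1941 (CIN 3),
0.307 (cancer), 1 (death). YLD accrues one burden term per state-year
of end-of-cycle occupancy with `L = 1` at the then-current age — the
yearly sum approximates a single longer-`L` call to within the curvature
of the age-weighting function, and matches the yearly state resolution
of the Markov model. YLL assigns each incident death the residual life
expectancy at its age, linearly interpolated from the bundled female
life table (a standard high-longevity reference table with e₀ = 82.5,
shipped as replaceable CSV data); ages outside the table raise rather
than extrapolate. Every DALY-dependent output is therefore
**life-table-dependent** and flagged as such in reports.

Averted DALYs of a screening arm are the counterfactual burden of its
confirmed cases left untreated: each case enters the model in its
diagnosed state and runs for the full horizon; treated cases are
assigned zero residual burden, so the averted total equals the whole
counterfactual. No burden accrues beyond the horizon except the YLL
projection through residual life expectancy.

The cohort's starting age is a required input; the study profile uses
45 years, the midpoint region of the 35–65 eligibility window, since no
per-case ages are available in the calibration aggregates. The
profile's CUR denominators are the study's published per-arm DALY
totals (50.624 / 17.603 / 42.301), carried as *reference data*: they
depend on per-case ages and life-table values not recoverable from the
printed inputs. The model always also computes its own burden
(`computed_dalys`), and `daly_source="computed"` switches CUR onto it.

## Costing

Treatment costs split into direct medical (surgery tariffs 2,400 /
5,650 / 8,500 RMB for CIN 2 / CIN 3 / cancer, plus 54,823.3 RMB
radio-chemotherapy per cancer case), direct non-medical and indirect
(social) costs. Social costs are per hospital day:
`(2·diet + accommodation + transport) = 23.5 RMB` non-medical and
`2 × wage = 187.6 RMB` indirect — the factor 2 encodes one accompanying
family member (two persons eat; two daily wages lost). Both
multipliers are configurable; their defaults are forced by exact
agreement with all six published social-cost cells. Hospital stays:
5.8 / 7.5 / 12.3 / 26.3 days for CIN 1 / 2 / 3 / cancer. CIN 1 cases
receive follow-up only and are costless; their stay duration is kept in
the schedule for completeness.

The *early* scenario costs each confirmed case at its diagnosed grade;
the *non-early* counterfactual costs every ≥ CIN 2 case as one full
cancer case (surgery + radiochemo + cancer-length stay). The benefit of
an arm is non-early minus early total. Tabulated treatment costs are
undiscounted — the published cells are exact undiscounted products and
the study found discounting moved results by ≤ 0.19 % — but a
present-value `discount(amount, years, rate)` operation is provided for
costs scheduled in future years.

Rounding: internal arithmetic is unrounded; the reporting layer rounds
half-up to 0.1 RMB (rates 2 dp, BCR 2 dp, DALYs 3 dp) and table totals
are sums of rounded components, matching the published tables'
convention. Half-up rounding snaps binary floats to 6 decimals first so
exact decimal products such as 12.3 × 23.5 = 289.05 round to 289.1.

## Indicators

Per arm: CER = screening cost / confirmed positives; NPV = benefit −
screening cost; BCR = benefit / screening cost (cost-beneficial ⇔
NPV > 0 ⇔ BCR > 1); CUR = screening cost / DALYs averted. Effectiveness
rates: detection = confirmed / screened, PPV = confirmed / initial
screen positives, referral = referred / screened. Referrals are
intentions: loss to follow-up (2 / 12 / 13 per arm in the calibration)
reduces colposcopy attendance but not referral counts or denominators.
In the HPV arm the initial positives (146) funnel through a triage
split summarised by its aggregate referral count (53); the calibration
PPV is 7/146 = 4.79 %. No pairwise incremental ICERs are computed — the
design compares per-arm average ratios.

## Sensitivity analysis

Univariate: one parameter perturbed, full pipeline re-run per delta,
variation ratio (perturbed − baseline)/baseline tabulated per arm and
indicator, with normalized perturbed/baseline curves and a ranking
check. Radio-chemotherapy cost varies multiplicatively (±5 %, ±10 %);
the discount rate varies additively in percentage points (0.03 →
0.04 under +1 %). Because reference DALY totals are external constants,
the discount-rate sweep evaluates CUR from the model's *computed*
burden on both sides of the ratio; its CUR variation is therefore a
property of this package's burden model, not of the study's
unreproducible baseline, and the ranking assertion is limited to the
radiochemo perturbations. Probabilistic sensitivity analysis and
tornado diagrams over unvaried parameters are out of scope.

## Synthetic cohort generator

Emulates the trial structure: 3,086 women aged 35–65, participation
0.979 (3,021 screened), arms of 1008 / 1012 / 1001, per-arm initial
positivity, referral, attendance and confirmation probabilities
calibrated as ratios of the realized counts, and grade distributions
over confirmed cases ({8,3,3} CIN 1/2/3; {2,0,1}; {2,1,3} + 1 cancer).
Deterministic mode rounds expected counts at every stage (largest-
remainder apportionment for grades) and reproduces the calibration
exactly for any seed; stochastic mode draws binomials/multinomials per
stage. Ages are uniform on [35, 65] (only the range is known). Not
emulated: the cluster structure of sampling, HPV genotypes, the three
HPV-arm triage sub-groups (collapsed into one aggregate referral
fraction), and any correlation between age and disease state — so
passing pipeline-closure tests on synthetic data demonstrates correct
aggregation and costing arithmetic, not epidemiological realism.

## Numerical and design notes

* Matrix row-sum tolerance 1e-6 on input; mass conservation asserted at
  1e-9 relative per step; simulate ≡ matrix-power oracle at 1e-12 for
  horizons ≤ 15.
* Closed-form burden vs adaptive quadrature agrees to 1e-6 relative
  over the tested (D, α, L) grid.
* `murray_burden` is monotone increasing in `L` and `D` and strictly
  decreasing in γ; these are regression-tested invariants.
* Problem sizes: the evaluation itself is tiny (three arms, 15 cycles);
  property tests use cohorts up to 10× arm size and a one-off
  3,000-cycle absorption check.
* Known limitations: no treated-arm morbidity model (averted = full
  counterfactual), one fixed matrix for all ages, CIN 1 follow-up
  uncosted, no currency conversion or reimbursement modelling, and the
  published per-arm DALY totals / YLD-YLL series serve as reference
  inputs rather than reproduction targets.
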