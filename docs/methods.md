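# Methods

## The screening problem

Most low back pain (LBP) is non-specific and transient, but a minority of
individuals progress to persistent disabling pain. Two short self-report
instruments target that minority from different angles:

* the **STarT Back Screening Tool (SBT)** asks nine yes/no questions — four
  physical (referred leg pain, neck/shoulder pain, walking disability,
  difficulty dressing) and five psychosocial (fear of movement, anxiety,
  catastrophizing, feelings of depression, bothersomeness). The overall
  score is the number of endorsed items (0–9); the psychosocial subscale is
  the sum of the last five (0–5). Risk of a worse prognosis is **high** if
  the psychosocial subscale is ≥ 4, otherwise **medium** if the overall
  score is ≥ 4, otherwise **low**. Because the subscale is contained in the
  total, the three rules partition every response pattern exactly once.
* the **pain mannequin** pairs a single chronicity question (any ache or
  pain lasting more than three months during the past twelve months) with a
  body chart of 18 predefined regions. Under the ACR-1990 convention a
  respondent has **chronic widespread pain (CWP)** when chronic pain covers
  the axial skeleton, both body sides, and both body halves; chronic pain
  without that distribution is **chronic regional pain (CRP)**; no chronic
  pain is **NCP**. Marking ≥ 7 regions is **multisite pain (MS)**, and
  CWP together with multisite pain (**MS-CWP**) is the mannequin's marker
  of high risk.

The **combined triage** flags an individual as high risk when *either*
screen does (SBT high OR MS-CWP). Missing inputs propagate by Kleene
three-valued OR: a triggering screen decides high on its own, but a single
non-triggering screen cannot rule high out, so the combined outcome is then
missing. An alternative rule in which MS-CWP upgrades only SBT-medium
respondents is available (`combine_variant="medium_gate"`) for sensitivity
analysis; the default is the plain OR.

## Region map

The widespread-pain rule is attribute-driven. The shipped 18-region map has
four axial midline regions (head, neck, upper back, lower back) and seven
bilateral pairs (shoulder, elbow, wrist/hand, hip, thigh, knee,
ankle/foot); upper half = head, neck, upper back, shoulder, elbow,
wrist/hand; lower half = lower back, hip, thigh, knee, ankle/foot (low back
counts as lower-segment pain, following the ACR convention). Any
alternative chart can be supplied as a YAML config; all classification
logic reads only the attributes. A respondent who reports chronic pain but
marks no region is classified CRP (chronic, demonstrably not widespread)
with a warning, since the combination is internally inconsistent and has no
canonical treatment.

## Statistics

Group comparisons use Student's **pooled-variance two-sample t-test**
(s² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), df = n₁+n₂−2, two-sided) and
**Pearson's chi-square without continuity correction**. These are the
variants that exactly reproduce the published p-values of this design when
recomputed from printed group summaries (Welch's t and Yates-corrected
chi-square do not). The t-test operates on summary statistics, so printed
table rows are valid inputs. Expected cell counts below 5 raise a warning,
not an error, because the published analyses themselves have such cells.
P-values are rendered to three decimals with values below 0.0005 printed
"< 0.001"; percentages are rounded half-up to integers. No multiple-testing
adjustment is applied.

Missingness is handled per instrument and per PRO (complete case within
each analysis): a partially answered SBT or mannequin voids that whole
instrument, never yielding a prorated score, while each patient-reported
outcome (PRO) is missing independently. This is what produces the shifting
denominators across the four report tables, and the pipeline log records
every per-instrument exclusion count so the denominators are auditable.

## Synthetic cohort generator

The generator emulates a two-group population sample: 52 individuals
answering yes to "low back pain during the last week", 67 answering no, and
7 leaving the question blank (drawn from either group's parameters). A
single standard-normal latent severity zᵢ per individual drives all
instruments through one coupling coefficient ρ (default 0.6); conditional
on severity the instruments are independent.

* **Chronic pain** is probit-coupled: chronic iff
  Φ(ρzᵢ + √(1−ρ²)·η) > 1 − p_chronic, preserving the marginal prevalence.
* **Region count** for chronic individuals follows a zero-truncated
  negative binomial whose top bin (18) absorbs the tail; its underlying
  mean is solved so that p_chronic × E[count] equals the configured
  group-marginal mean. The count is coupled to severity through a Gaussian
  copula whose driver is ranked through its *conditional* CDF given chronic
  status (computed by Gauss–Hermite quadrature) — without that correction
  the severity selection inherent in being chronic would inflate counts and
  CWP prevalence by several standard errors at n = 5000/group.
* **Widespreadness** is decided given the count k with probability
  min(1, c·g(k)), where g(k) is the exact inclusion–exclusion probability
  that a uniform k-subset of the map satisfies the ACR criterion
  (conditioned on a forced lower-back region for the share p_lower_back of
  chronic individuals), pinned to 1 where every k-set is widespread and 0
  where none is. The constant c is solved once per configuration so the
  configured marginal CWP prevalence is honored exactly in expectation;
  P(CWP | k) remains increasing in k, so widespreadness keeps its emergent,
  count-driven character and MS-CWP overlaps multisite pain the way the
  screening problem requires. The marked set itself is then constructed to
  match (k, widespread-or-not): a minimal attribute cover (or a deliberate
  avoidance of one attainable attribute category) filled uniformly.
* **SBT items** are independent Bernoulli given severity with logistic
  probability expit(αⱼ + 2ρzᵢ); each intercept αⱼ is solved by quadrature
  so the marginal endorsement probability matches its configured value,
  hence the expected SBT total equals the configured per-item sum.
* **PROs** use moment-matched *censored-rounded normal* marginals: draw
  N(μ, σ), clip to the instrument range, round to the instrument
  granularity (integers for NRS/RMDQ/HAD/FABQ, 0.001 for the EQ-5D index).
  (μ, σ) are solved numerically so the mean and SD *of the discretized
  law* equal the configured values. The censoring point mass at the scale
  floor is essential: several reference-group scales (e.g. pain NRS with
  mean 1.2 and SD 2.4) are overdispersed beyond what any truncated normal
  can realize, but a mostly-at-zero censored normal reproduces them — and
  is also what pain scores of a largely pain-free group look like. EQ-5D
  is coupled inversely to severity (higher = better health).

### Default parameters

Group sizes, PRO means/SDs, CWP prevalences (53% / 18%), percent women
(65% / 57%), region-count marginal means (5.0 / 1.9) and per-instrument
missingness (SBT 9/119, mannequin 5/119, group question 7/126) are the
study conditions the package reproduces. Quantities with no published
value were fixed once as realistic for a chronic-pain-enriched population
subsample and are not tuned:

| parameter | LBP | reference | rationale |
|---|---|---|---|
| p_chronic | 0.80 | 0.35 | the sampled frame was enriched for chronic pain |
| p_lower_back (given chronic) | 0.95 | 0.30 | current LBP implies low-back marking almost surely |
| region-count NB size | 5 | 25 | matches the printed count SDs (4.2 / 3.0) approximately |
| SBT item probabilities | sum 2.4 | sum 0.7 | physical items more endorsed than psychosocial; sums equal the printed SBT means |
| coupling ρ | 0.6 | 0.6 | strong enough that the SBT-low × MS-CWP cell is well populated, as observed |
| PRO missingness | 0 | 0 | per-PRO denominators were not published |

### What the generator does and does not emulate

It reproduces group-level marginals and a plausible one-factor dependence
structure. It does **not** model: item-level PRO structure (totals are
drawn directly), multi-factor dependence (e.g. distinct physical and
psychosocial severities), age/sex effects on any outcome, spatial
contiguity of marked regions, or longitudinal dynamics. Tests passing on
synthetic cohorts therefore validate the *pipeline arithmetic and the
calibration contract*, not any claim about the real study population.

## Numerical choices

* Marginal solver: 2-D root solve (`scipy.optimize.root`, hybr) on
  (μ, log σ) with a deterministic ladder of starting points; residual
  tolerance 1e-6 on both moments; unattainable targets raise.
* ZTNB mean and CWP constant c: Brent root-finding on monotone 1-D maps.
* Count copula conditional CDF: 96-node Gauss–Hermite, 4001-point
  interpolation grid on [−8, 8].
* Degenerate inputs: SD 0 yields a constant (must sit on the scale grid);
  both-SDs-zero t-tests return t = 0, p = 1 when means agree and raise
  otherwise; zero-margin contingency tables raise.
* Problem sizes: the recovery check uses 5000 per group (standard errors
  small enough to detect calibration bias of a few percent in ~2 s);
  oracle agreement uses all 256 subsets of a reduced 8-region map plus
  10,000 random subsets of the full map.

## Known limitations

* The three published table rows that are not reproducible from their own
  printed summaries (age p = 0.233; RMDQ p = 0.228 and FABQ-Work p = 0.066
  in the combined-risk comparison) — presumably because per-variable
  missingness changed the underlying n — are deliberately not asserted
  anywhere.
* The combined high-risk percentage is reported against both candidate
  denominators (the agreement-complete n = 48 and the LBP-group n = 52),
  since published usage is ambiguous between them.
* Parameter recovery is asserted at 2 SE for the CWP prevalences and via
  the |z| > 4 flag across all ~26 recovered quantities; requiring every
  quantity inside 2 SE simultaneously would fail about two runs in three
  by chance alone for a perfectly calibrated generator.
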