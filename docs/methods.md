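# Methods

## The decision model

`cyclegate` implements a knowledge-based (IF–THEN) decision procedure for
pre-cycle chemotherapy evaluation. It is deliberately not a learned model:
every recommendation is an explicit rule application over two inputs, so a
clinician can audit exactly why a tier was assigned.

For a planned cycle with infusion date *d*, the engine inspects:

* the latest lab panel — seven analytes (RBC, WBC, thrombocytes, ALT, AST,
  bilirubin, creatinine) compared **inclusively** to configured reference
  intervals `[low, high]` (a value equal to a bound is in range; either
  bound may be absent, i.e. unbounded);
* the latest symptom questionnaire — per-symptom NCI-CTCAE grades 0–4;
* the patient's baseline questionnaire — the comparison point for chronic
  symptoms.

Rules, in precedence order (first match sets the tier; the rationale lists
every code that held at the winning tier):

1. panel present, fresh, out of range → **tier 3** (`LABS_OUT_OF_RANGE`);
2. panel absent, stale, or incomplete → **tier 2** (`LABS_MISSING` /
   `LABS_STALE`);
3. questionnaire absent or stale → **tier 2** (`EPRO_MISSING` /
   `EPRO_STALE`);
4. any symptom at grade ≥ 2 **and** above its baseline grade → **tier 2**
   (`SYMPTOM_GE2_ABOVE_BASELINE`, flagged symptoms listed);
5. otherwise → **tier 1** (`ALL_CLEAR`).

Two asymmetries are intentional. First, out-of-range labs dominate missing
data: an unfit blood count always postpones, even when the questionnaire is
missing. Second, missing/stale/incomplete data never postpones — absence of
evidence routes to a human (tier 2), only positive evidence of unfitness
postpones (tier 3). A consequence used as a self-check throughout the test
suite: the tier-3 count over any cohort equals exactly the number of cycles
whose fresh panel is out of range.

**Freshness.** Data supports an automated decision only if it is at most
`max_age_days` (default 3) whole calendar days old relative to the planned
infusion date. Dates carry no time of day; age is a whole-day difference.
Future-dated observations are never fresh — the decision must rest on
pre-infusion data.

**Baseline comparison.** A symptom flags when its current grade is ≥ 2 and
strictly above its baseline grade (`exceeds`, default): a chronic grade-2
neuropathy does not block tier 1, but its worsening to grade 3 does. The
alternative reading — a symptom present at grade ≥ 2 at baseline is exempt
no matter how far it worsens — is available as
`EngineConfig.baseline_comparison = "exempt_if_present"`. We default to
`exceeds` because absolute exemption would silently ignore a 2 → 4
deterioration. When a record carries no explicit baseline, the
`first_questionnaire` policy fills it with the patient's chronologically
first questionnaire on record (`attach_baselines`).

**Overrides.** The care team can always override a tier. Overrides require a
non-empty note (attributability) and never modify the engine's recorded tier
and rationale; `effective_tier` resolves which tier drives scheduling.

## Urgency alerts

Independent of the cycle decision, a questionnaire fires an email-style
alert for (a) any symptom at grade ≥ 3 (`GRADE_GE3`) and (b) a symptom that
was grade 0 at the previous questionnaire and is grade 2 now
(`RISE_FROM_0`). At most one alert per symptom per questionnaire: a grade ≥ 3
symptom alerts once as `GRADE_GE3` even if it also rose from 0. With no
previous questionnaire, no rise can be established, so only `GRADE_GE3`
fires; first-contact grade-2 symptoms surface through the tier-2 rule
instead. A configurable variant treats any rise of ≥ 2 grades as the rise
trigger; given the `GRADE_GE3` rule it differs from the default only in
notation.

## Scheduling

Each plan generates `SEND_QUESTIONNAIRE` at *d* − 3 days and `COLLECT_LABS`
at *d* − 1 day (both lead times configurable, chosen so that data collected
on schedule is always inside the default 3-day freshness window; the true
operational lead times of such deployments are not standardised, so they
are configuration, not constants). After a decision: tier 1 notifies go;
tier 2 automates nothing (human in the loop); tier 3 moves the infusion by
`postpone_delay_days` (default 7 — one week is the conventional chemotherapy
delay unit; must be ≥ 1 so a postponement always yields a strictly later
date) and re-programs both collection events against the new date, so a
postponed cycle re-enters the same pipeline. Reservations of one patient
within `reservation_merge_window_days` (default 3) of each other are
chain-merged (transitive clustering) and only the cluster's earliest
reservation generates collection events — this prevents double questionnaire
sends when an infusion and its ambulatory-pump-removal appointment are
booked back to back.

## Reference intervals

The shipped defaults (e.g. WBC 3.0–11.0 ×10⁹/L, thrombocytes 100–450 ×10⁹/L,
ALT ≤ 50 U/L) are illustrative textbook-style adult values. They are **not**
the prespecified bounds of any particular trial or institution — those are
regimen- and site-specific (typically derived from the summary of product
characteristics of the agents in use) and must be configured. Units are
declared in config and assumed consistent between ranges and panels; no unit
conversion is attempted.

## The synthetic cohort simulator

`simulate_cohort` emulates the statistical structure the engine assumes: per
cycle, a lab panel sampled one day pre-infusion that fails with probability
`p_lab_out_of_range` (one uniformly chosen analyte placed outside its bound,
preferring a low excursion where a lower bound exists — the cytopenia-style
failure that dominates in practice); a questionnaire present with
probability `p_questionnaire_completed`, back-dated past the freshness
window with probability `p_stale_given_completed`, with per-symptom grades
drawn from configurable categorical distributions over 0–4 (default mass
0.55/0.25/0.15/0.04/0.01 — mostly absent or mild, rarely severe). Baselines
are symptom-free (all grade 0) pre-study questionnaires, one per patient,
which keeps the degenerate parameter settings exactly interpretable (all
benign ⇒ all tier 1; certain lab failure ⇒ all tier 3). Cycles are spaced 14
days apart. Everything is driven by a mandatory seed; identical seeds give
byte-identical cohorts.

What the simulator does **not** emulate: symptom correlation across symptoms
or over time (draws are independent), lab-value autocorrelation within a
patient, informative missingness (completion is independent of symptom
burden), disease progression, and dose modifications. Tests passing on
simulated cohorts therefore demonstrate the correctness of the rules and
plumbing, not clinical performance on real patients.

## The deterministic reference cohort

`build_reference_fixture` constructs a 43-patient, 339-cycle cohort whose
marginal counts reproduce a published usability evaluation of this class of
tool: 262 cycles with a fresh questionnaire (77.3 %), 221 with all grades
≤ 1 (65.2 %), 228 with labs in range (67.3 %), 843 completed questionnaires
of which 446 report fatigue (52.9 %) and 429 report peripheral sensory
neuropathy (50.9 %), and tier counts 145 / 83 / 111 when run through the
engine.

The printed marginals under-determine the joint layout, so the fixture fixes
a canonical assignment: of the 228 lab-in-range cycles, 145 carry fresh
benign questionnaires (tier 1), 41 carry a fresh questionnaire with nausea
at grade 2 above baseline, 21 a stale questionnaire, and 21 none; of the 111
lab-failing cycles, 76 carry fresh benign questionnaires, 17 stale ones, and
18 none. These splits satisfy all marginals (262 = 145+41+76 fresh,
221 = 145+76 acceptable, 77 = 42+35 missing-or-stale), and any alternative
split honouring the marginals yields the same tier counts under the engine's
precedence — the test suite asserts this by rebuilding the fixture with a
different stale/missing split. Cycle categories are interleaved across
patients by a fixed internal permutation; the fixture takes no seed and is
byte-identical across runs.

Grade 3–4 burden: the published counts (137 grade 3–4 records total with
diarrhea, n=5, and neuropathy, n=4, the most common) cannot all hold
simultaneously as symptom-record counts — 128 remaining records over 14
symptoms cannot stay ≤ 4 each. The fixture therefore embeds 137
questionnaires carrying exactly one grade 3–4 record each, with diarrhea in
5 and neuropathy in 4 of them, and spreads the remaining 128 records evenly
over the other symptoms; the total and the two named counts are preserved,
the "most common" ranking is not. All grade 3–4 records live in interim
questionnaires (completed between cycles) so they cannot perturb the
cycle-level tier counts. The 543 interim questionnaires carry the
prevalence mass up to the 843 total; per-patient baselines are not counted
among the 843 (they are pre-study assessments attached to the records).

## Metrics and rounding

`performance` recounts data availability with the same freshness rule the
engine uses and tallies tiers; `prevalence` counts a symptom as "reported"
at grade ≥ 1 (grade-0 entries denote absence) against the completed-
questionnaire denominator, and grade 3–4 records against the grade 3–4
record total. Percentages are rounded half away from zero to one decimal
(`Decimal`-based, property-tested against exact integer arithmetic). Note
83/339 is 24.5 % at one decimal; a displayed "25 %" is a second, coarser
rounding for prose and is not emitted by the report.

## Numerical and degenerate-input choices

* Dates are calendar dates; all age arithmetic is whole days.
* An empty cohort produces a zero-count report with absent percentages
  rather than NaNs.
* A questionnaire with zero reports is invalid (completion implies at least
  one answer); unanswered symptoms are absent, not grade 0.
* `validate_record` is total: it returns findings, never raises, and flags
  grade bounds, duplicate symptoms/analytes, unknown identifiers, patient-id
  mismatches and non-finite values. The engine refuses (with the findings)
  to decide on an invalid record.
* Config documents are validated by the same pydantic models that define the
  types; violations name the offending key.

## Known limitations

* The engine encodes one published rule set; dose-modification advice,
  supportive-medication logic and the content of tier-2 human evaluation are
  out of scope by design.
* No unit conversion between panels and configured ranges.
* The reference cohort reproduces marginal counts, not patient-level
  trajectories; patient-level statistics (e.g. fraction of patients ever
  needing a phone call) are not modelled because no per-patient
  decomposition is available to emulate.
* Message delivery (SMS/email), EHR/reservation-system interfaces and read
  receipts are outside the package; events are emitted as data for a
  delivery layer to consume.
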