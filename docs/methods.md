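# Methods

## Model overview

The simulator is victim-centred: each casualty is duplicated into a
*clinical facet*, advanced by the victim monitoring model, and a *logistics
facet*, moved around by the medical response model. The two facets share one
state and interact only through triggers — a time trigger (untreated
deterioration) and a treatment trigger (care delivered by a provider of a
given skill). Time is continuous (real minutes); only survival-table lookups
are binned. The event kernel is a heap-ordered queue executing events in
(time, scheduling-sequence) order, so simultaneous events fire in scheduling
order and every run is bit-reproducible under a fixed seed.

## Clinical conditions and deterioration

A victim profile is a finite state machine. The untreated (time-trigger)
pathway is total and acyclic: every non-end state has exactly one time
transition, and the chain terminates in a dead or stabilized end state. The
engine keeps exactly one pending time transition per victim; delivering a
treatment cancels it and schedules the switch onto the treatment pathway
after the transition's treatment-effect delay. A consequence of this
cancel-and-reschedule semantics is that a victim cannot die inside a
treatment-effect window; the window is short (5–10 min) relative to the
30-minute deterioration grain, and treatment is only delivered to living
victims.

Severity is the RPM score (coded respiratory rate + coded pulse rate + coded
best motor response, 0–12). The survival grid (percent, by 30-minute elapsed
time bin and RPM) ships as `src/mcisim/data/deterioration.tsv`; lookups are
left-continuous steps (the row of the largest tabulated time ≤ t, last row
beyond the end) with no interpolation. The grid is validated at load: values
in [0, 100], non-increasing in time, non-decreasing in RPM. Both tables are
configuration-overridable.

Deaths are deterministic, not Bernoulli draws: the profile generator places
the dead state at the first bin at which the victim's current-RPM survival
probability reaches 0. This removes mortality sampling noise from design
comparisons, so differences between factor levels come from queueing and
timing alone.

## Default victim profiles

Region- and casualty-specific profile data are not publicly available, so
the generator builds a documented synthetic library (three variants per
triage category) with these defaults:

| category | initial RPM (variants) | untreated RPM loss | untreated death |
|----------|------------------------|--------------------|-----------------|
| T1       | 4, 5, 6                | 1 per 30 min       | 60–90 min       |
| T2       | 8, 9, 10               | 1 per 60 min       | 180–240 min     |
| T3       | 11, 12, 12             | none (stabilizes)  | never           |
| T4       | 1, 2, 1                | 1 per 30 min       | 30–60 min       |

Treatment pathways: a physician-led team (MMT) improves RPM by 2 (capped at
12) after a 10-minute effect delay and stabilizes the victim 30 minutes
later; a nurse/paramedic team (PIT) improves RPM by 1 (8-minute effect) and
holds for 180 minutes before stabilizing; basic care (EMT, 5-minute effect)
holds the current RPM and halves the subsequent deterioration rate (the
victim can still die). Escalation transitions (PIT/MMT from the EMT pathway,
MMT from the PIT pathway) exist from every non-end treatment state. In-ED
transitions stabilize, but a victim's simulation terminates at admission, so
they are not exercised by the response model. A higher-skilled provider may
fire a lower-skill transition when no dedicated one exists (MMT ⊇ PIT ⊇
EMT): escalation is never blocked by over-qualification.

These pathways satisfy two properties the tests enforce: treatment never
lowers RPM, and the RPM trajectory on any treatment pathway dominates the
untreated trajectory from the moment of treatment.

## Scenario and response defaults

The default scenario is an airliner crash at an international airport
without fire: 250 occupants — 26 T1, 62 T2, 113 T3, 4 T4 (205 injured),
5 immediate fatalities (never enter the response flow) and 40 uninjured.
Plan anchors fixed by the doctrine modelled: walking wounded (T3) reach the
CCP by minute 3; SAR extraction of the 92 non-ambulatory victims starts at
minute 5; two extra fuselage holes at minute 21 (extraction rate ×3 — one
initial opening plus two, configurable); initial dispatch of 5 BLS
ambulances, 4 MMTs (the first to arrive commands and never treats or
transports; the second triages at the CCP; the third and fourth set up the
FMP) and 2 Red Cross teams; FMP treatment possible 8 minutes after the setup
teams arrive; CCP→FMP travel 1 minute; 38 ambulances from 32 stations and 10
MMTs in the region.

Values the plan annexes do not print are named config blocks with defaults
chosen once at design time:

* **SAR rates** (victims per 10 minutes before the holes): low 4, medium 8,
  high 16.
* **Resource levels** (ambulances / MMTs / first-wave working MMTs /
  reinforcement dispatch minute): low 12/5/3/25, medium 19/7/3/20, normal
  28/10/3/15, high 38/10/7/15.
* **Supervision levels**: `emt` (BLS crew only, never waits), `nurse`
  (satisfied by a PIT ambulance, else waits for an idle MMT),
  `physician_nurse` (always waits for an idle MMT — victims can die while
  waiting), `best_available` (takes the highest idle skill, never waits).
  Idle FMP physicians/nurses are used for transport supervision.
* **Hospital capacity** per facility (initial surge, then patients/hour):
  low 4 + 2/h, medium 8 + 4/h, high 12 + 6/h, across six facilities on an
  8–30 km ring (one trauma centre, one burn centre).
* **Durations**: triage 1 min; FMP treatment delivery 12 min (T1/T4) or
  8 min (T2); en-route care delivery 6 min; loading 2 min; unloading 1 min;
  ambulance speed 60 km/h.

Nearest-first distribution sends a victim to the closest capable hospital
with uncommitted surge capacity, falling back to the closest capable one
(an admission queue then forms); round-robin rotates proportionally to surge
capacity. Ambulances carry one urgent patient, assignments are immutable
after the pickup decision, and ambulances are released on hospital arrival
(victims awaiting admission wait at the hospital; ambulance-blocking is not
modelled — configurable choice). Non-urgent victims go by bus to the
non-urgent care area, are re-examined, and leave for a non-urgent care
facility in a capacity-8 minibus; a victim who deteriorates to T1/T2 at the
NUCA is transferred to the FMP on the clinical transition event. Uninjured
occupants are escorted away at the scene and are not simulated as entities.
Interrupted lower-skill treatment is restarted on escalation (delivery time
is not credited).

## Experiment harness

The seven factors cross to 1152 designs. Per-run seeds are
`crc32(base_seed:design_id:replication)` (31-bit), so any subset of the
sweep reproduces identically and runs are independent of sweep order. The
profile library is a fixture shared across runs; replication randomness
enters through profile mapping, attribute assignment and SAR extraction
order. ANOVA treats individual replication runs as observations (a design
choice; means-per-design is the alternative); eta-squared is
SS_factor/SS_total; Scheffé tests use the standard pairwise F with k−1
numerator degrees of freedom. Degenerate (zero-variance) data are flagged
rather than raised.

## Numerical choices

* Event ties break by scheduling sequence, then queue entries by
  (priority code, entry order, victim id) — stable FIFO within equal codes.
* The priority-code arrival field is three decimal digits; the horizon is
  validated < 1000 minutes (default 720) so codes cannot overflow.
* The survival table uses the shipped digitization; a validation pass
  rejects any override violating the monotonicity invariants.
* Travel minutes = km / (km/h) × 60 exactly; no congestion model.

## What the synthetic scenario does and does not show

The generator reproduces the documented *structure* of the case study (the
census, the plan choreography, the factor levels) but not the proprietary
annex parameters (per-victim diagnoses, regional resource tables, hospital
capacities). Absolute mortality numbers from this package therefore
characterize the shipped defaults, not the original region, and the test
suite asserts only structural invariants (conservation of victims,
determinism, queue-order and capacity laws, golden event traces) and
directional effects on the shipped defaults (triage lowers mean mortality;
faster extraction lowers mean mortality; 30 seeded replications each).
Factor-interaction modelling, in-hospital care beyond ED admission,
self-referral (the airport is a closed site) and fire/hazmat dynamics are
out of scope.
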