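# Methods

## Model

`wardflow` couples a discrete-event kernel with agent-based patients.
State changes only at event instants (arrivals, grants, task boundaries,
transports, modifier times, deadline hits); between events nothing moves.
Patients are the agents: each carries its injury group, deadlines,
attachments and position, and walks the process graph independently,
coupling to the others only through resource contention.

### Process graphs

A process is a directed graph with exactly one start and one end event.
Interior nodes are tasks or gateways. Exclusive gateways branch per
patient: either conditionally — an outgoing edge's label is matched
against the patient's injury group (directly, or via the group's
configured `branch_labels`; an unlabeled edge is the default) — or
*redundantly*, where the split is marked as a set of clinically
equivalent alternatives and the engine picks the branch with the
smallest estimated completion time. Parallel gateways fork the patient
into concurrent tokens that re-merge at the matching join; a parallel
block's nominal duration is the maximum over its branches, and the
patient's location after the join is that of the last-finishing branch
(ties go to the first-declared branch, in both the engine and the
closed-form walk, so the two always agree).

The BPMN reader supports `process`, `startEvent`, `endEvent`, `task`,
`exclusiveGateway`, `parallelGateway` and `sequenceFlow`; anything else
is an error in strict mode and skipped with a warning otherwise. Task
metadata (area, durations, demands, deltas) lives in a sidecar mapping
keyed by BPMN id — BPMN defines no schema for it, and keeping the XML
structural keeps the reader simple.

### Resources, lending, attachment

Resource types are devices or staff, portable or stationary; portable
types may be *attachable* (they stay with the patient — ventilator,
monitor, infusion pump — and move through areas with them until an
explicit detach releases them back home). Each instance is in exactly
one state — `idle`, `busy`, `in_transit`, `attached`, `blocked` — at any
instant.

A task's demands are granted **atomically**: either every demand can be
covered right now, or the request waits. Coverage uses local idle
instances first (lowest id first, for determinism); shortfalls are
borrowed from other areas in ascending order of transit time (ties:
lexicographic area id), but never below the lender's minimum stock, never
from a quarantined area, and never for stationary types. Borrowed
instances are in transit until the task start, which is delayed by the
largest borrow transit. Released borrowed instances head home
immediately. The queue is ordered by (priority desc, patient arrival
asc, patient id asc); grants are greedy in that order and
**non-preemptive** — a running task always finishes, even if a
higher-priority patient is waiting. Atomic all-or-nothing grants mean no
partial holds, hence no allocation deadlock; a request that can never be
satisfied simply starves (and the patient's TTR eventually removes them —
this is a modelled outcome, not an error).

Two timing modes are supported per demand. The default ties every
instance up for the whole task (the simplified sequence). A
`sub_interval` hold `(offset, length)` releases the instance early, at
`start + (offset + length)` scaled by the task's efficiency factor; the
acquisition itself stays atomic at task start. This captures the
fine-grained mode's resource-saving effect without non-atomic
acquisition, which would reintroduce hold-and-wait.

### Efficiency

A task's effective duration is `nominal × 100 / e`, where `e` is the
*minimum* efficiency percentage over the instances granted to it (100 if
it has no demands). Halved efficiency doubles the duration; 200 %
efficiency halves it. The min rule makes the slowest participating
resource dominate — in particular, a task that uses an unboostable CT
scanner cannot be accelerated by boosting the staff around it, which is
exactly the saturation phenomenon the emergency-plan analysis probes.

### Deadlines

TTD and TTR are absolute wall-clock deadlines,
`t_start + initial + Σ deltas of completed therapy tasks`. The clocks run
through waiting, transport and treatment — they are only ever *extended*
by explicit therapy deltas, applied at task completion (the benefit is
realized when the therapy has been delivered). A TTD hit sets the
patient's `damaged` flag and nothing else; the patient continues
unchanged. A TTR hit removes the patient: queued requests are cancelled,
running tasks abort, held and attached instances are released (starting
return transit from wherever they are), and the pending TTD event is
discarded. TTR ≤ TTD is not enforced; whichever fires first governs.

### Modifiers

Scenario modifiers are timestamped state changes with half-open
effectivity `[at, next change)`: area deactivation/reactivation,
quarantine/lift, transit-time changes, per-type efficiency changes, and
per-type outages. In-flight activity always completes under the old
parameters; flags are re-checked at release time. A *deactivated* area
(the local-blackout case) stops task execution but still lends portable
resources out; a *quarantined* area freezes everything inside it — no
lending, no dispatch out, releases settle in place as `blocked` until the
lift, after which stranded instances head home.

### Redundant-branch estimator

For a redundant split, the per-branch estimate is the sum over branch
tasks of (effective duration for the group + inbound transit) plus, per
required resource type, a wait estimate: the minutes of work currently
granted, running or queued on that type in the task's area, divided by
the number of in-service instances there (infinite if none are in
service — e.g. during an outage). Smallest estimate wins; ties go to the
first-declared branch. The estimator is deliberately myopic about
post-branch transit, and is a pluggable strategy object so alternatives
can be evaluated. On an idle hospital it reduces exactly to the nominal
branch sum, which is what makes single-patient simulations equal the
closed-form `nominal_path_duration` — the oracle test exploits this.

### Determinism and numerics

All times are continuous minutes (IEEE doubles). The event heap is keyed
by `(time, sequence-number)` with sequence numbers assigned at scheduling
time; every iteration over collections that can affect outcomes is over
sorted keys. Two runs of the same `ScenarioSpec` therefore produce
byte-identical serialized event logs, and the log auditor
(`wardflow.audit.audit_log`) independently replays any log against the
static configuration to verify conservation, min-stock safety,
quarantine hermeticity and non-preemption. Scenario files round-trip
exactly (floats are written with `%.17g` and parsed with pandas'
round-trip precision). Identity points of sweeps (outage 0, efficiency
100 %, boost 0) inject no modifier at all, so they reproduce the
unmodified run bit-for-bit; mean delays at these points are zero up to
float translation error (≈1e-13 min), which tests absorb with a 1e-9
tolerance.

## The synthetic trauma-room fixture

The bundled fixture emulates a standardized emergency-trauma-room
process: 26 tasks across five areas (ambulance, trauma room, CT,
operating room, intensive care), a staff roster of trauma leader, junior
surgeon, senior anesthetist, two surgical and one anesthetic nurse,
radiographer and radiologist, and the standard device park (portable
x-ray, ultrasound, monitors, ventilators, infusion pumps, defibrillator,
blood analyzer, one stationary CT). The true process parameterization
(derived from non-public registry data) is unavailable, so all durations
are synthetic: drawn once per task from documented uniform ranges and
frozen by the bundle seed. Only qualitative behavior is claimed.

Structure: a serial first survey (handover, briefing, airway, intubation,
circulation check), then the trauma team splits into three **parallel**
work streams — bleeding control (with a conditional chest drain for
thorax-severe groups), imaging (x-rays, FAST ultrasound), and
access/medication/second survey — then image review, CT scan and CT
review, then a **redundant** disposition split between operating room
and intensive care. Parallel team work is how real trauma teams operate,
and it concentrates the trauma leader's serial load (~27 min per
patient) so that the *unboosted* trauma room, not the CT scanner
(~15 min per scan), is the initial bottleneck under overload.

Design choices worth making explicit:

* **Severity factors** (0.70–1.30 across the six AIS-defined groups)
  apply to surgery and ICU stabilization only. The survey and the
  whole-body CT protocol are standardized procedures whose duration
  varies little with severity; a welcome side effect is that the mean
  treatment duration becomes invariant to which patient occupies which
  CT queue slot, which removes discrete noise from the emergency-plan
  response curve.
* **MCI arrivals** follow the two-batch pattern (six patients in minutes
  [3, 15], six in [39, 89], one per group per batch); within each batch
  the drawn arrival times are assigned in triage-priority order, because
  rescue services deliver the most critical patients first. Without
  this, whether a low-priority patient slips through the still-empty
  trauma room ahead of the backlog is a knife-edge that flips with tiny
  parameter changes.
* **Standard-day arrivals** (the substrate for the outage and efficiency
  sweeps) place one patient in a 30-minute window every 180 minutes — a
  realistic trauma-room census — so the undisturbed run is delay-free
  and the sweeps isolate the disruption's effect.
* **TTD/TTR ranges** (TTD 90–360 min depending on group, TTR ≥ 360 min
  or absent) are wide enough that the bundled sweep scenarios complete
  without reanimation removals; removal semantics are exercised by
  dedicated engine tests. Attachable-device stocks (8 each) are sized
  not to bind, so the scenarios isolate the staff and scanner
  bottlenecks.
* **One CT scanner** by default: the single most load-bearing premise of
  the emergency-plan comparison.

Under these conditions the bundle reproduces the qualitative shapes the
method is designed to expose: a CT outage has no effect until it
overlaps the first scan, then a steadily growing mean-duration increase;
decreasing CT efficiency degrades performance monotonically; boosting
trauma-room efficiency under overload yields large gains until the CT
saturates (sustained span-utilization of 100 %), after which further
boost improves the mean by well under 1 % per 10-point step and only a
second scanner helps. "Sustained" matters: during the handover of the
bottleneck from trauma room to CT, the scanner can be transiently
gap-free at one boost level while a gap reopens at the next; only the
regime where utilization stays at 100 % for all higher boost levels is
CT-bound.

The registry-like cohort generator emits records with a group's exact
AIS signature and monotone per-action timestamps
(arrival ≤ x-ray ≤ CT ≤ surgery), with gamma-distributed inter-action
durations (shape 9, relative SD 1/3) around deterministic per-group
means; the aggregation helper recovers mean action durations per group,
emulating the path from registry timestamps to per-group task durations.

## What the fixture does not emulate

Real registries record messy, partially missing timestamps documented
after the fact; the generator's records are complete and clean. Real
pathways adapt to the individual patient (micro-deviations, repeated
tasks, diagnostic loops); the graph here is static and acyclic. Staff
fatigue, shift changes, consumable depletion and stochastic task
durations are out of scope — durations are deterministic per group, so
cohort sampling is the only randomness and it is fully seed-controlled.
Passing tests therefore demonstrate the *mechanics* (allocation,
lending, deadlines, routing, reproducibility) and the *qualitative*
response shapes, not numeric agreement with any real hospital.

## Problem sizes

The bundled analyses run 12-patient scenarios over a ~250-minute
simulated span (a few thousand events each); the sweep drivers rerun the
full simulation per grid point from the pristine spec (9 outage points,
4 efficiency points, 21 boost levels × 2 scanner counts). The whole
acceptance computation is a few seconds of CPU.

## Known limitations

* Grants reserve instances from the grant instant; a granted-but-not-yet
  started task (waiting for a borrowed instance in transit) proceeds
  even if its area is deactivated in the meantime — only new grants see
  the flag.
* The branch estimator ignores resources that would be *lent into* an
  area (zero in-service ⇒ infinite wait), which is conservative for
  branches whose tasks rely entirely on borrowed equipment.
* A patient removed mid-transport releases attachments from the transport
  origin (their location is not interpolated).
* Exclusive joins must be explicit gateway nodes; implicit merges on a
  task are not part of the supported BPMN subset.
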