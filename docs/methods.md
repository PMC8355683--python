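# Methods

`atollnet` analyses passive acoustic-telemetry detection logs from a
fixed array of non-overlapping receivers: the kind of data produced
when animals carrying coded acoustic transmitters swim within a few
hundred metres of moored hydrophones.  The package was built around a
multi-year study of Caribbean reef sharks at a remote Caribbean atoll
(18 receivers, 77 animals across both sexes and three life-history
stages, nominal tag life 1877 d, monitoring window 2007-04-23 to
2014-05-09), and every default below is that study's setting; all are
configurable.

## Detection cleaning

Two screening rules are applied before any metric is computed.

* **False-detection removal.**  Coded transmitters occasionally produce
  spurious decodes (code collisions).  The standard field heuristic is
  used: any (animal, receiver, calendar day) group containing exactly
  one detection is discarded; groups of two or more are kept unchanged,
  which makes the rule idempotent.  A switch applies the rule per
  (animal, day) across the whole array instead; the per-receiver
  reading is the default because the rule is stated "per day at a
  receiver".  Calendar days are evaluated in UTC with a configurable
  fixed offset — the raw logs carry no timezone, and a fixed convention
  is required for reproducibility.
* **Minimum-days filter.**  Animals detected on fewer than five
  distinct days carry too little information and are excluded.  A
  "detection day" is a day with at least two detections anywhere in the
  array (the daily-occurrence rule used by the residency metrics);
  after per-receiver singleton removal any day retaining detections
  satisfies this automatically, but the threshold is switchable for
  data cleaned under the array-day rule.

Every removal is logged per rule/animal/receiver/day, so filtered
row counts are fully auditable (and testable against the synthetic
generator's bookkeeping).

## Node merging

Receivers moored less than ~1 km apart cannot be distinguished by a
moving animal whose detection range is ~250 m.  The default array
merges two such pairs (stations 15+16, at the Blue Hole, and 18+19)
into single network nodes, giving 16 nodes from 18 stations.  Station
identity is retained alongside node identity: the roaming index is
defined against the 18 physical receivers, while relocations and
movement chains operate on the 16 nodes.  Station labels run 1–19 with
17 unused, so the published pair labels exist in the synthetic array.

## Residency and roaming metrics

For an animal with `D` detection days:

* **RI** = `D / 1877`, the nominal tag life in days.  Exceptions: an
  animal reported captured is expected only through its capture date
  (denominator = days from tagging to capture); a tag detected beyond
  its rated life is credited the span from tagging to its last
  detection, capped at the study end.  Clamped to [0, 1].  RI is
  deliberately conservative: unobservable periods count against the
  animal.
* **RI_max** = `D / span`, where the span runs from tagging to the last
  detection, counted inclusively (`(last − tagged) days + 1`).  The
  inclusive convention was fixed once (the source tables do not state
  one); the test suite's span-reconstruction property is tolerant to
  ±1 day.  A single-day animal scores 1.
* **Roaming index** = distinct receivers visited / 18.  It measures
  array-wide spread, not persistence, so it shares no denominator with
  RI and the two are reported independently.
* **Monthly RI** = detection days in a calendar month / days in that
  month, tabulated from the tagging month to the earlier of tag death
  and 2012-12-31 (most tags died before the array was recovered, so
  later months would be structurally biased toward zero).

Cohort summaries report means ± sd of RI and RI_max, the share of
animals below RI 0.5, and the "site- and array-faithful" subset
(RI_max > 0.50 **and** roaming < 0.50, both strict), broken down by sex
and size class.

## Life-history stages

Size classes are assigned from sex-specific total-length breakpoints:
females — juvenile (A) < 150 cm, subadult (B) 150–180 cm, mature (C)
> 180 cm; males — A < 130 cm, B 130–160 cm, C > 160 cm.  The B ranges
are inclusive at both ends.

## Statistical comparisons

Index-on-covariate models are ordinary Gaussian-error linear models
(statsmodels OLS) with sex coded female = 0 (reference) and male = 1,
so a negative sex effect reads "males less resident".  Model selection
among {intercept, TL, sex, TL+sex, TL×sex} is by AIC.  Overdispersion
of count responses is screened with the Pearson dispersion of a Poisson
fit (flagged above 1.5, with a negative-binomial family recommended in
the output); the Gaussian fit is the one the reported coefficients come
from.  Group comparisons use the Mann–Whitney U test (tie-corrected
normal approximation; exact enumeration when both samples have ≤ 8
observations) and the Kruskal–Wallis rank-sum test, with Dunn's
pairwise rank comparisons under a Bonferroni family-wise correction as
the post hoc — the post hoc procedure was an open choice and is
recorded in the result's metadata.

## Activity spaces

Because receivers do not overlap, an animal's position is known only to
be "at" a node.  Detections are collapsed to **one relocation per
occupied 30-minute bin**, placed at the projected coordinates of the
bin's majority node (ties broken toward the node of the bin's latest
detection — deterministic, and favouring the most recent position).
No interpolation is attempted between nodes.

Coordinates are projected with a spherical azimuthal-equidistant
projection centred on the array centroid (exact at the centre; pairwise
distance error < 0.1% over a 50 km extent, verified against a
haversine oracle).

The utilisation distribution is a bivariate normal kernel density,
`f(x) = (1/n) Σᵢ N₂(x; xᵢ, h² I)`, evaluated on a 100 m grid padded by
4h around the relocation bounding box (mass leak < 1%).  Because
relocations repeat at most 16 node positions, the sum collapses to a
handful of weighted kernels, making evaluation exact and fast.  The
**p% activity space** is the smallest-area region holding p% of the
mass, found by ranking cells by density and accumulating; 50% is the
core and 95% the total activity space.  For a single cluster these
areas have the closed form `2πh² ln(1/(1−p))`, used as the analytic
oracle (grid error < 3% at 100 m cells).

The smoothing parameter in the original study was a visual choice after
trials and is unrecoverable; the default here is **h = 1000 m**, with a
Silverman-type reference bandwidth available and the value used always
reported.  Consequently absolute KD areas from raw detections are not
comparable to published per-animal values, and only statistics of the
published KD column are validated.  Eligibility: at least 3 distinct
nodes and 10 relocations (the published table carries KD values for
animals at exactly 3 receivers, so "more than three" is read as an
approximation of this threshold; both are configurable).

## Movement chains

Detections are aggregated to **hourly** presence states: each hour with
a detection is labelled with its majority node (tie → latest), all
other hours between an animal's first and last detection are ABSENT.
Sequences are not padded to tag life — padding would inflate ABSENT by
unobservable periods — but a flag allows it.  Consecutive hourly pairs
are tallied into a 17-state (16 nodes + ABSENT) count matrix whose
diagonal holds residency periods; per-animal matrices are summed within
a group (sex × stage) before row-normalising, so no artificial
transitions arise between animals.

States never observed at all are dropped (recorded); a state entered
but never left — an end-of-sequence artifact — is kept as an absorbing
self-loop so the matrix stays row-stochastic.

The **centrality** vector is the stationary distribution π (πP = π,
Σπ = 1), the long-run probability of finding an animal at each state,
computed by power iteration on Pᵀ to an ∞-norm tolerance of 1e-10
(cap 10⁵ iterations).  Numerical safeguards: a reducible chain is
restricted to its largest strongly connected component containing
ABSENT (zeros elsewhere; renormalised); if plain iteration stalls on a
periodic chain, the lazy damping P′ = 0.999 P + 0.001 I — which leaves
the fixed point unchanged — is applied.  The power-method result is
cross-checked against dense eigensolvers in the test suite to 1e-8.
Node degree counts distinct other nodes with any incident transition,
excluding ABSENT and self-loops.

## Synthetic data generator

The raw telemetry of the motivating study was never deposited, so the
generator produces cohorts with the statistical structure the pipeline
assumes, with complete ground truth:

* **Array**: 16 node positions on a ring whose chord is solved so the
  18-station mean nearest-neighbour spacing is 5.5 km; merged-pair
  stations sit 0.9 km apart (non-overlapping at a 250 m range).
* **Movement**: each animal's hourly state is drawn from its group's
  Markov kernel over nodes + ABSENT — exactly the state space the chain
  estimator works on, so parameter recovery is a clean test.  Kernels
  are built from bout parameters: the present→absent rate (inverse mean
  present bout), the absent→present rate (inverse mean absent bout), a
  within-array move rate (80% of move mass to ring neighbours), and a
  home-node re-entry bias.  Defaults per sex × stage were set once from
  the two-state occupancy closed form `π(ABSENT) = leave/(leave+exit)`
  so that long-run absent fractions span ~0.86–0.95 (mature females the
  most present, with the lowest value) and multi-day absent bouts keep
  most animals' detected-day fraction under one half — the sparse-use
  regime the study reports.
* **Detections**: each present hour emits transmission slots at the
  nominal 90 s interval (40 per hour) with a random sub-interval phase,
  each detected with probability `detection_prob` (default 0.8; 1.0 is
  the lossless setting used by exactness tests).  Merged-node hours are
  assigned to one member station per hour.  Optional **planted
  single-detection receiver-days** (Bernoulli per receiver-day, only
  where no true detections exist) exercise the false-detection screen
  with exact bookkeeping.
* **Determinism**: every quantity derives from the master seed through
  per-animal seed substreams, so output CSVs are byte-identical across
  runs and independent of generation order.

What the generator does **not** emulate: continuous-space movement and
receiver-range geometry (movement is simulated directly on the node
graph), diel/tidal detection-efficiency cycles, clock drift, tag
failure, and individual home-range heterogeneity beyond the group
kernel — in long simulations every animal eventually visits every node,
so the generator does not reproduce the wide spread of individual
roaming indices seen in real cohorts.  Passing recovery tests therefore
demonstrate correctness of the estimators under their own model
assumptions, not robustness to field artifacts.

## Validation strategy and problem sizes

Because the raw data are unavailable, validation rests on three legs:
(1) the packaged 77-row per-shark summary table, through which the
metric, grouping and regression code reproduces the published cohort
statistics at print precision; (2) closed-form oracles (bivariate
normal contour areas, two-state stationary distributions, dense
eigensolvers, rank-test enumeration); and (3) seeded synthetic cohorts
with ground truth.  Recovery tests use 10–20 animals over 90–360
simulated days (lossless detection), where the empirical transition
matrix shows the expected square-root error decay; the qualitative
absent-state check runs the full 77-animal profile over the complete
tag life.  These sizes were chosen to make the Monte-Carlo behaviour
unambiguous while keeping the whole suite fast.

## Known limitations

* Timestamps are stored at second resolution; sorting ties are broken
  by receiver id and input order.
* One animal id in the packaged table was issued to one animal of each
  sex; all fixture operations key on (id, sex).
* The Kruskal–Wallis post hoc is one of several Dunn-type variants; a
  different correction (Holm, Šidák) would change borderline pairs.
* The KD estimator is unaware of land and lagoon barriers; contours can
  cover habitat the animals cannot use.
* Chains are discrete-time with 1 h steps; dwell times inside an hour
  and multi-node transits within an hour are invisible.
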