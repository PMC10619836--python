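# Methods

## Model overview

`allosim` is a daily-time-step, continuous-space agent-based model of a
single carnivore population (allosaur agents) exploiting two meat
resource pools on a flat 70 × 70 km torus: stationary, decaying sauropod
carcasses, and mobile 2,000 kg prey. Six heritable traits partition into
a scavenging suite (carcass detection range, tail-fat storage capacity,
carcass-site dominance) and a predation suite (bite force, hearing,
binocular vision). Fitness is lifetime reproductive success; the
analysis layer stratifies the complete life-history record by trait
ability and compares reproduction probabilities across strata.

Each day runs a fixed phase order: (1) carcass spawning; (2) perception,
prey flight, movement; (3) carcass-site feeding contests; (4) predation
attempts; (5) metabolic update and starvation deaths; (6) births;
(7) carcass decay/removal; (8) prey and (if extinct) population
replenishment. A single seeded random stream drives everything and the
daily agent order is reshuffled from it, so a (configuration, seed) pair
reproduces a run bit for bit.

## Genetics

A trait gene is an ordered expression class — `extra_small`, `small`,
`medium`, `big`, `extra_big` — plus a continuous advantage factor drawn
uniformly within the class band: [0.3, 0.65), [0.65, 0.9), [0.9, 1.1),
[1.1, 1.35), [1.35, 1.7]. Bands are half-open except the topmost so that
every factor belongs to exactly one class. Founders draw classes
uniformly; offspring keep the parental class with probability 0.8 and
move to an adjacent class otherwise (0.1/0.1 for interior classes; for
edge classes the out-of-scale mass folds into the single neighbour,
giving 0.8/0.2). The chain is irreducible and aperiodic and the shortest
`extra_small → extra_big` path is 4 generations, which limits
generational leap-frogging. The offspring factor is re-drawn uniformly
within the offspring class (config `factor_mode` can instead copy the
parental factor when the class is unchanged); re-drawing realizes
individual variation, penetrance and expressivity within a class.

Abilities are linear in the factor and shipped as data (the trait table
in the configuration): tailfat 38 kg · f — the kilograms of meat an
agent can ingest and store per feeding day; carcass detection 5 km · f;
prey (binocular) detection 0.5 km · f; kill probability 0.1 · f per
attempt; dominance and hearing f − 1, dimensionless scores.

## Metabolism

Energy is tracked as body mass in kilograms of meat equivalent. The
daily requirement is the all-bird field-metabolic-rate allometry
calibrated so that a 2,000 kg endotherm needs 29 kg of wet meat per day:

    N(M) = 29 · (M / 2000)^0.681  kg/day.

The four reference points (2,000→29, 2,500→33, 4,000→46,
1,900→27.7) are mutually inconsistent at the ±1 kg level under any
single power law; this implementation privileges the bird-FMR exponent
and the 2,000→29 anchor and accepts ≤ 1 kg deviation elsewhere. Anchor
mass, anchor requirement and exponent are configuration fields.

The daily ledger feeds first, then pays: M' = M + intake − N(M)
(`feed_order="pay_first"` checks starvation between the two steps). Mass
is unbounded above — growth is limited dynamically by the intake
equilibrium M* = 2000 · (t/29)^(1/0.681) for sustained intake t — and an
agent dies when M < 1,840 kg. The floor is fixed at 92 % of the
initialization mass and does not rise as the animal grows, so fattened
agents carry genuine famine reserves: one kg of stored mass buys roughly
1/35 of a fasting day at typical sizes, and an unfed 2,000 kg agent
starves on day 6.

## Environment and carcass dynamics

Coordinates are continuous and wrap modulo 70 km (minimal-image
distances). Sauropod carcasses draw mass uniformly from 10,000–25,000 kg
and positions uniformly on the torus, spawn only during day-of-year
windows [0, 91) ∪ [182, 274) ∪ [320, 365) (quarters 1 and 3 plus the
final 45 days, 0-based), never exceed 5 concurrent, and are removed when
below 20 % of initial mass or by an independent 0.02/day hazard that
keeps the resource unpredictable. The reference description fixes the
cap, the windows, the removal hazard and an annual production of 15–28
carcasses but not the per-day spawn probability or the decay law; here

* `spawn_prob = 0.14`/day (while below the cap, inside windows) — the
  largest value for which simulated annual spawn counts stay within
  15–28 in ≥ 90 % of years under full population dynamics;
* decay is linear at 0.2 % of initial mass per day
  (`decay_model="exponential"` is available): decay exists but mass loss
  is dominated by consumption and the removal hazard, and an untouched
  fall persists for many months, consistent with the persistence of
  multi-tonne carcasses.

The world is initialized with the carcass pool at its within-window
steady state (5 standing carcasses); founding agents otherwise face an
empty landscape no later cohort ever sees.

## Behaviour

Perception is carrion-first: the nearest carcass with edible mass within
the agent's detection range wins; otherwise the nearest prey within its
binocular-vision radius; otherwise the agent wanders. Wandering is a
correlated walk — a persistent heading turned by a uniform ±15° each day
at 3 km/day — reflecting the directional travel of nomadic large
vertebrates; a memoryless daily heading would make carcass search
diffusive and ineffective at these scales. (`max_turn_deg` and
`target_preference` are configurable.)

At a carcass site, attendees feed in descending dominance order, each
taking min(tailfat cap, edible mass above the 20 % floor) once per day
(`feeding_mode="shared"`). The alternative `"exclusive"` reading — the
top-dominance animal holds the site alone and subordinates must seek an
unguarded carcass — is implemented and configurable; it was not adopted
as the default because the short-lived displaced agents it generates are
inconsistent with the reference run's total production.

A pursued prey flees directly away from its sharpest-eared pursuer at
3 · clamp(1 − hearing, 0.3, 1.7) km/day before the pursuer moves, so a
slowed prey (hearing > 0) is intercepted in open pursuit while an
equal-speed chase never closes. Within the 0.1 km capture radius a kill
attempt fires with probability equal to the bite-force ability; a kill
converts the prey into a 2,000 kg carcass at its position, a failure
frees the prey for the rest of the day. With a 0.45–0.55 km baseline
vision radius and 20 prey on 4,900 km², prey sightings are rare (of the
order of one per 65 wander-days), so predation is a marginal resource —
which is the model's point.

## Demography and recolonization

Each living agent reproduces with probability 0.02 per day while the
population is below 30; offspring start at 2,000 kg at the parent's
position with an inherited genome (reproduction is free by default;
`reproduction_cost` deducts parental mass). The population is seeded
with 12 random-phenotype founders.

The resource regime makes local extinction a normal event: carrion
spawning pauses twice a year (91 and 46 days), carcasses outlast the
pauses only occasionally, and a population of lean agents cannot fast
through a long famine. The model therefore recolonizes: when the
allosaur count reaches zero, a fresh 12-agent founding cohort immigrates
as soon as the sauropod pool has recovered to
`reseed_carcass_threshold = 3` standing carcasses — immigration tracks
the carrion pulse, as it would for wide-ranging scavengers surrounding
the modelled landscape. The reference run's own life-history table
demands this structure: its per-bin offspring counts sum to ~5,470 fewer
than total production, i.e. several hundred parentless 12-agent cohorts.
Genealogy closure holds in the generalized form
Σ offspring = N − 12 · (founding cohorts).

## Life-history records and analysis

Every agent ever created leaves one immutable record: genome (class,
factor, ability per trait), parent, birth/death day, cause (starvation
or end-of-run censoring), offspring count, and three mass summaries —
final, lifetime-mean and peak. Starvation fixes final mass at the floor
for nearly every agent, so distributional mass statistics use the
lifetime mean; the reference tables' per-bin masses (well above the
floor in high-fitness bins) are only reproducible under such a lifetime
statistic, not under mass-at-death.

The analysis layer computes: the zero-offspring fraction; reproduction
probabilities stratified by trait ability (default reading:
P(offspring = exactly 1), which matches the reference run's 0.28 overall
one-offspring share; P(≥ 1) is a switch); fitness ratios between strata
(tail-fat threshold 35 kg; "high bite force" = ability > 0.11, i.e. a
factor above the big-class threshold, since the reference leaves the
stratum undefined); per-offspring-bin trait means with the daily energy
budget N(mean mass); the mean mass and tail-fat ability of successful
agents; Gaussian kernel densities of the offspring distribution
(Silverman bandwidth, overridable); and per-year expression-class
compositions among survivors.

## Verification scope

The test suite checks the printed metabolic surface (±1 kg), the
heredity chain frequencies (χ², 10⁵ draws) and 4-generation reach, the
trait-scaling table cell by cell, torus geometry and pursuit kinematics,
carcass lifecycle invariants (conservation ledger, geometric lifetime,
annual 15–28 band), engine invariants (caps, genealogy closure, meat
conservation, bit-reproducibility), and the analysis arithmetic against
hand-computed fixtures. Ten-seed full-length ensembles check the
stochastic reproduction bands. Simulated agents face none of the real
world's costs beyond those modelled — no thermoregulation, terrain,
competition from other carnivore species, prey defence, pack behaviour
or age structure — so passing ensembles demonstrate internal consistency
of the modelled mechanism (carrion abundance relaxing selection on
predatory traits), not a quantitative claim about Morrison-formation
ecosystems.

## Known limitations

* Under the printed resource parameters (≤ 5 carcasses, 15–28
  spawns/year, 0.02/day removal) this implementation supports a mean
  agent lifespan of ~25 days; the reference run's tables imply ~38. The
  shortfall propagates: total production stabilizes near 16,000 agents
  per 279-year run (reference: 23,092) and the zero-offspring fraction
  near 0.75 (reference: 0.58). The directional selection results are
  unaffected.
* The reference run's strong penalty on bite force (a 0.46 fitness ratio)
  is not recovered: with the printed 0.45–0.55 km prey-detection radius,
  predation encounters are too rare for any bite-force-linked mechanism
  to halve a stratum's reproduction probability. This implementation
  yields a weakly negative-to-neutral ratio (~0.97).
* Several reference extreme-agent bite-force values (0.21–0.22) exceed
  the maximum the stated 0.1 × factor mapping can produce (0.17); the
  mapping is retained as stated.
* Hearing's effect on prey speed, the carcass decay law, and the
  displacement semantics are qualitative in the reference description;
  each is implemented as a configurable choice with the defaults argued
  above.
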