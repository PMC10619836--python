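# allosim

An evolutionary agent-based model of large-theropod foraging ecology.

Large Jurassic carnivores such as *Allosaurus* lived alongside sauropods
whose carcasses — "sauropod falls", by analogy with whale falls — were
enormous, calorie-dense, and recurrent. Did natural selection in such a
system favour predatory adaptations, or scavenging ones? `allosim`
simulates a population of allosaur agents with six heritable traits, half
of which aid scavenging (carcass **detection range**, **tailfat** storage
capacity, carcass-site **dominance**) and half predation (**bite force**,
**hearing**, **binocular vision**), on a flat 70 × 70 km toroidal
landscape stocked with seasonal sauropod carrion and a standing pool of
huntable 2,000 kg prey. Lifetime reproductive success is the fitness
measure; the analysis layer asks which trait classes selection favours.

## The model in brief

* **Genetics.** Each trait gene is an ordered expression class
  (`extra_small … extra_big`) plus a continuous advantage factor *f*
  drawn within the class band ([0.3, 0.65), [0.65, 0.9), [0.9, 1.1),
  [1.1, 1.35), [1.35, 1.7]). Abilities are linear maps of *f*:
  tailfat = 38 kg · *f* (daily intake cap), detection = 5 km · *f*,
  binocular vision = 0.5 km · *f*, kill probability = 0.1 · *f*,
  dominance = hearing = *f* − 1. Offspring keep the parental class with
  probability 0.8 and otherwise move one class — a nearest-neighbour
  Markov chain, so an `extra_small` lineage needs ≥ 4 generations to
  reach `extra_big`.
* **Metabolism.** Daily meat requirement follows the all-bird field
  metabolic rate allometry, N(M) = 29 · (M/2000)^0.681 kg/day, so a
  2,000 kg agent needs 29 kg/day, a 4,000 kg agent about 46.5. Agents
  grow by the surplus they store and die when body mass drops below
  1,840 kg (92 % of the initialization mass).
* **Resources.** Sauropod carcasses (10,000–25,000 kg) appear at random
  positions during the 1st quarter, the 3rd quarter and the final
  45 days of each 365-day year, at most 5 at a time and 15–28 per year;
  they decay, are eaten, vanish below 20 % of initial mass, and face a
  0.02/day random-removal hazard. Killed prey become 2,000 kg carcasses;
  the prey population is topped back up to 20.
* **Demography.** Agents reproduce asexually at 0.02/agent/day under a
  population cap of 30, starting from 12 random-phenotype founders; when
  the population dies out a fresh founding cohort recolonizes once the
  carrion pool has recovered.

## Worked example

A full-length default run (279 simulated years) takes a few seconds:

```bash
allosim run --seed 7 --out out/
allosim analyze --records out/records.csv --yearly out/yearly.csv --out analysis/
allosim report --summary analysis/summary.json
```

The run above prints `run complete: 16115 agents over 279 years` and the
analysis summary reads (abridged):

```json
{
  "total_agents": 16115,
  "zero_offspring_fraction": 0.7487,
  "tailfat_fitness_ratio": 1.2099,
  "bite_force_fitness_ratio": 0.9725,
  "successful_mean_mass": 2157.4,
  "successful_mean_tailfat": 44.70
}
```

Read it as: 16,115 agents were produced over the run and ~75 % of them
died without reproducing. Agents whose tail-fat intake capacity exceeded
35 kg/day were **1.21× more likely** to produce exactly one offspring
than the rest (fat storage is positively selected), while agents with
high bite force were slightly **less** likely (0.97×) — predation does
not pay in a carrion-rich world. Reproductively successful agents
averaged 2,157 kg of body mass (they need ~31 kg of meat per day at that
size) and evolved tail-fat capacities of ~45 kg per consumption day,
comfortably above their daily requirement. `analysis/table4_replica.csv`
gives per-offspring-bin trait means and `analysis/composition.csv` the
per-year expression-class frequencies among survivors.

Every output is reproducible: the same `--seed` gives byte-identical
CSV files, and `run_meta.json` echoes the full configuration.

Model parameters live in one flat record (`allosim.SimConfig`) and can
be set from a YAML file (`--config`) or the command line, e.g.
`--set feeding_mode=exclusive --set spawn_prob=0.12`.

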