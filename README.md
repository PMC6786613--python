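# herdnet

An agent-based simulator of nomadic pastoral households, for researchers in
human ecology, archaeology and socio-ecological modelling who want to study
how environmental conditions shape wealth inequality and hierarchical
herding networks.

One hundred households share a pasture that supports at most *K* animals
(the carrying capacity, 5,000–50,000 in the standard sweeps). Each time
step (≈ one year), every household:

1. grows its herd by 10% — but only if the system total is still below *K*
   at its randomly ordered turn (the wealthy can exhaust the remaining
   head-room: 10% of a large herd is many animals);
2. suffers an environmental disaster with probability *p* (5–20%), losing
   half its herd;
3. if poor (herd < 60), receives 60 animals from its patron, or recruits a
   patron among households with herd > 800, forming a patron–client link;
   with no patron available and herd < 2 the household dies;
4. any patron whose herd falls below 500 loses its clients.

Dependent variables per run (2,000 steps): the Gini index of herd wealth
(measured on a no-interaction variant, since patron transfers mask
inequality), the largest number of clients a single patron held
simultaneously, the number of consecutive steps that run-maximal network
stayed the largest, and the end population. The interesting dynamics hinge
on the ratio of average growth (10%) to average loss (*p* × 50%): at
*p* = 20% they cancel, herds decay and the population collapses; below
that, inequality is high and networks grow with *K*.

## Worked example

```python
import herdnet

params = herdnet.SimParams(carrying_capacity=50_000, disaster_prob=0.10)
result = herdnet.run_simulation(params, seed=1)
print(result.largest_network_size, result.largest_network_duration,
      result.end_population)
```

prints `98 262 100`: under favourable conditions (high capacity, moderate
risk) a single patron came to hold 98 of the other 99 households as
clients, reigned as the largest network for 262 consecutive steps, and
nobody died. The same model at `carrying_capacity=10_000` (seed 2) gives
`19 53 45`: a poorer pasture supports only a fragile 19-client network and
fewer than half the households survive to the end of the run.

The experiment layer batches this over grids:

```python
table = herdnet.sweep(capacities=[10_000, 50_000], probs=[0.05, 0.20],
                      n_runs=10, base_seed=0)
print(herdnet.aggregate_sweep(table))
```

and `herdnet.standardized_ols(table, "largest_network_size",
["carrying_capacity", "disaster_prob"])` fits the SPSS-style standardized
multiple regression used for sensitivity analysis.

The same experiments are available from the shell:

```bash
herdnet sweep --runs 100 --seed 0 --out results/
herdnet gini-sweep --runs 100 --seed 0 --out results/
herdnet shift --runs 20 --seed 0 --out results/
herdnet regress --runs 25 --seed 0 --out results/
```

Each command writes per-run and aggregate CSV tables plus a JSON metadata
file that records the full configuration and seed, from which every row
can be regenerated bit-exactly.

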