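# wormswarm

Agent-based modelling and analysis of *C. elegans* collective feeding:
aggregation of hyper-social worms into dense clusters, and the dynamic
swarming of those clusters across a bacterial lawn once food is locally
depleted.

Loss-of-function *npr-1* mutants aggregate on food while the solitary
laboratory strain N2 does not, and over hours the *npr-1* aggregates
crawl coherently across the lawn.  `wormswarm` implements a
phenomenological model in which both phenomena emerge from three
density-dependent individual behaviours, together with the statistical
machinery needed to fit such a model to multi-worm tracking data.

## Model

Each of N worms (default 40) is a chain of M = 18 nodes of total length
L = 1 mm in a periodic square arena. The leading node performs a
persistent random walk (rotational diffusion coefficient D_θ); trailing
nodes follow the body with inextensible spacing.  Worms interact only
through their local k-nearest-neighbour density ρ (k = 6) and short-range
contact:

- **cluster-edge reversals** — a worm whose head or tail (but not both)
  senses contact reverses with Poisson rate `r_rev = r′ ρ`;
- **speed switching** — worms switch stochastically between a slow
  (0.035 mm/s) and a fast (0.35 mm/s) crawl with rates
  `k_slow = k_s0 + k_s′ ρ` and `k_fast = k_f0 exp(−k_f′ ρ)`;
- **taxis** — neighbours within one worm length attract the heading with
  weight `f_t / r`, cumulatively over neighbours.

For swarming, a food lawn is discretised on a grid and depleted locally
by feeding; absence of food suppresses the switch to slow speeds, so
clusters disperse on exhausted ground and re-form on neighbouring food.
The free behavioural parameters (r′, k_s′, k_f′, f_t) are inferred by
rejection ABC against four spatial summary statistics: the pair
correlation function (S1), the single-linkage branch-length distribution
(S2), and the standard deviation (S3) and kurtosis (S4) of worm
positions.

## Worked example

```python
import wormswarm as ws

for label, params in [("npr-1-like", ws.npr1_reference()),
                      ("N2-like", ws.n2_reference())]:
    ds = ws.run_simulation(params, duration=1800, record_every=30, seed=1)
    stats = ws.summarize_dataset(ds)
    print(label, round(stats.s1_small_r_mean(), 2))
```

prints

```
npr-1-like 157.26
N2-like 0.84
```

i.e. after 30 simulated minutes the social parameter set shows a
~150-fold excess of short-range (< 0.5 mm) worm pairs over a uniform
distribution — dense aggregates — while the solitary set stays
indistinguishable from uniform.  `examples/` contains one short script
per capability (aggregation, summary statistics, reversal analysis,
swarming, ABC inference); each prints the numbers it computes and what
they mean.

A thin CLI wraps the library:

```bash
wormswarm simulate --config run.toml --seed 1 --out traj.h5
wormswarm stats traj.h5 --out stats.json
wormswarm swarm --seed 1 --out swarm.h5
```

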