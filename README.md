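# flocknet

Social-network analysis of RFID feeder visits for closed,
pedigree-monitored bird populations: who arrives with whom, whether
that is a stable individual trait, and whether it is under selection.

Passive-transponder feeders log thousands of detections per bird, but
a detection stream is not a social network. At a busy feeder the
classic "gambit of the group" overestimates associations (everyone
present is linked to everyone) and simple co-presence produces
chain-like artifacts. `flocknet` implements the *arrival-time*
method: an arrival is a (re)appearance after an absence of more than
ΔI = 300 s, and two birds are associated when they arrive within
Δt = 150 s of each other. Dyadic association probabilities are
Simple Ratio Indices,

    SRI_ab = x_ab / (x_ab + y_a + y_b),

and each bird's position in the weighted network is summarized by
degree d(i), strength S(i) = d(i)·ΣSRI(i)/N(V), eigenvector
centrality (max-normalized), and opposite-sex degree from the
male–female bipartite sub-graph.

Fitness comes from a multi-generational pedigree: annual and lifetime
*recruits* (offspring that themselves bred), and *de-lifed fitness* —
the change in realized population growth from removing a bird and its
offspring,

    p_ti = (ξ_t(i) − w_t) / (N_t − 1),   w_t = N_{t+1}/N_t,

which sums to zero over a closed, fully censused population (a
property the tests exploit). Repeatability R = V_id/(V_id+V_res) and
linear + quadratic selection gradients are estimated with an
MCMCglmm-style Gibbs/Metropolis sampler (Poisson log link with
additive overdispersion for recruit counts, Gaussian for de-lifed
fitness; inverse-Wishart variance priors; posterior modes and 95%
credible intervals). A node-permutation null model and Elo dominance
ratings complete the chain. A seeded synthetic-data generator stands
in for field data, so every stage is testable end to end.

## Worked example

```python
from flocknet import SimConfig, ArrivalParams, MCMCConfig
from flocknet.simulate import simulate_population, simulate_visits
from flocknet.arrivals import detect_arrivals, associate_arrivals
from flocknet.networks import build_network, compute_centralities, compute_sri
from flocknet.models import RepeatabilityModel

sim = SimConfig(n_individuals=60, n_flocks=5,
                event_windows=[("2015-11-01", "2015-11-29")], seed=11)
individuals, pedigree, truth = simulate_population(sim)
visits = simulate_visits(individuals, truth, sim)
print(len(visits))                      # 25695 detections

arrivals = detect_arrivals(visits, ArrivalParams())
sri = compute_sri(associate_arrivals(arrivals, ArrivalParams()))
net = build_network(sri, individuals)
bip = build_network(sri, individuals, bipartite=True)
cent = compute_centralities(net, bip)
print(net.number_of_nodes(), net.number_of_edges())   # 60 1592

from flocknet.simulate import simulate_weekly_trait
weekly = simulate_weekly_trait(100, 14, icc=0.30, seed=5)
res = RepeatabilityModel(weekly).fit(
    MCMCConfig(n_iterations=6000, burn_in=1000, thin=5, seed=1))
print(res.summary())
```

```
Repeatability of value
  R (posterior mode) = 0.304  95% CI [0.245, 0.390]  (mean 0.309)
  V_id = 0.3094   V_res = 0.7265
  ...
```

60 birds produced a 60-vertex network with 1592 weighted edges, and a
weekly trait simulated at a true intraclass correlation of 0.30 is
recovered with a posterior mode of 0.30 and a credible interval
comfortably covering the truth — the same machinery that, on real
data, asks whether a bird's sociality is an individual attribute
rather than noise.

The pipeline end to end, from one YAML config:

```sh
flocknet run config.yaml            # simulate -> arrivals -> networks ->
                                    # fitness -> repeatability -> selection
                                    # -> null models, with a run manifest
flocknet simulate out/ --seed 3     # individual stages as subcommands:
flocknet arrivals out/visits.csv out/dyads.csv --delta-t 150 --delta-i 300
```

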