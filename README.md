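# glutcommons

An evolutionary game-theoretic model of glucose-transporter (GLUT1)
production in cancer cells, for researchers in mathematical oncology and
evolutionary game theory who want to study — or treat against — the
tragedy of the commons in tumor nutrient uptake.

## The model

Cancer cells in a shared *depletion zone* (the neighborhood over which a
cell can access and deplete nutrients) compete for glucose by investing in
membrane transporters. A focal cell carrying *v* transporters among *N*
cells with total transporter count *x = v + Σuᵢ* has fitness

    G(v, û, N) = (v/x) · φ(x) − k·v,      φ(x) = R(1 − e^(−a·x)),

its proportional share of the neighborhood's saturating collective uptake,
minus a linear production/maintenance cost. *R* is glucose availability per
zone, *a* the per-transporter encounter rate, *k* the cost per transporter.

Two equilibria are solved:

- **ESS** — the symmetric strategy *u\** no cell can beat by unilateral
  deviation: ∂G/∂v = 0 at v = u\*, ∂²G/∂v² < 0. For N = 1 it has the closed
  form v\* = ln(Ra/k)/a.
- **Team optimum** — the strategy maximizing group payoff N·G, which
  satisfies k = Ra·e^(−a·v) and coincides with the N = 1 ESS.

For N ≥ 2 the ESS overshoots the team optimum (each cell also profits by
*denying* glucose to neighbors), and everyone's payoff drops: a tragedy of
the commons. Two scaling rules relate the microenvironment to N: under
*crowding* R and a are fixed; under the *depletion-zone* rule R(N) = RN and
a(N) = a/N, keeping resources per cell constant.

On top of the game sit a Michaelis–Menten parametrization of GLUT1 counts
([E] = Vmax/Kcat), simulators for GLUT1-inhibitor (lower *a*) and
glucose-starvation (lower *R*) treatments, and the *sucker's gambit*:
letting cells evolve the competitive untreated ESS and then switching the
environment, so the inherited phenotype earns a negative payoff.

## Worked example

```sh
$ glutcommons ess --N 1,5,10,50,100
  N  ess_transporters_per_cell  ess_transporters_total  ess_payoff  team_transporters_per_cell  team_payoff  competitiveness
  1                     645492                  645492        3700                      645492         3700                0
  5                    1430884                 7154418        1558                      645492         3700           785392
 10                    1592629                15926287         827                      645492         3700           947137
 50                    1729743                86487158         172                      645492         3700          1084251
100                    1747277               174727703          86                      645492         3700          1101785
```

At the default parametrization (R = 10000, a = 2e−6, k = 0.0055,
depletion-zone scaling) a lone cell produces 645,492 transporters and nets
3700 resource units per time. With 5 competitors per zone, each cell carries
1,430,884 transporters — 2.2× the team optimum — yet earns only 1558; at
N = 100 the overinvestment reaches 2.7× and the payoff collapses to 86.
The `competitiveness` column is the per-cell transporter excess of the ESS
over the team optimum.

The same machinery drives the other subcommands:

```sh
$ glutcommons therapy --kind glucose-starvation --efficacy medium
$ glutcommons gambit --kind glucose-starvation --hypothesis genetic
$ glutcommons estimate-glut1
mode:                      paper_exact
concentration (nmol/g):    0.2
transporters per cell:     1,204,428
range (+/-50%):            602,214 to 1,806,642
```

The gambit table shows starved cells (R dropped to 5000) stuck with the
transporter load they evolved at R = 10000 earning *negative* payoffs
(−3966 at N = 10): they pay for transporters the environment no longer
rewards. In the library the same results come from `solve_ess`,
`solve_team_optimum`, `gambit_sweep`, and friends:

```python
from glutcommons import BASELINE_PARAMS, solve_ess
solve_ess(BASELINE_PARAMS, 10, "depletion_zone").v_star  # 1592629.3...
```

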