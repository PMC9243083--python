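# Methods

## Model

A focal cancer cell with `v` glucose transporters, embedded among `N`
interacting cells (focal included) whose total transporter count is
`x = v + (N−1)·u`, has per-time fitness

    G(v, u, N) = (v/x) · φ(x) − k·v,     φ(x) = R(1 − e^(−a·x)).

The bounded-exponential gain assumes a well-mixed neighborhood in which
every transporter has the same chance of encountering any glucose molecule,
consistent with Michaelis–Menten uptake kinetics: collective harvest
saturates at `R` with diminishing returns per transporter. A cell's share
of the harvest is its transporter share `v/x`; cost is linear in `v`.
Residents are symmetric — a single resident value `u` stands for all
`N−1` competitors, since every quantity of interest is evaluated at
symmetric or unilaterally-deviating profiles. At `v = x = 0` the payoff is
defined as 0 (the `v/x` limit is taken as full share of zero uptake), which
keeps G continuous and encodes "no investment → no uptake, no cost".

Units are abstract: resource units per time, transporter counts. No
molarity conversion happens inside the game; the kinetics module (below)
provides the bridge to physical transporter numbers.

### Scaling assumptions

How `R` and `a` respond to `N` is a modeling choice with two natural poles:

- **crowding** — the depletion zone is fixed and density varies; `R` and
  `a` are independent of `N`.
- **depletion_zone** — density is fixed and the zone grows with `N`;
  `R(N) = R·N` (more resource in a bigger zone) and `a(N) = a/N` (each
  transporter is less likely to meet any given molecule). Resources per
  cell are then invariant: `N·φ(v) = φ(x)` at symmetric profiles.

The per-transporter cost `k` never scales. Note that `R·a` — and hence the
dimensionless cost ratio `κ = k/(R·a)` — is invariant under both rules.

### Equilibria

The **ESS** is the symmetric strategy no cell can beat by unilateral
deviation: the fitness gradient vanishes at `v = u = v*` with negative
curvature. The gradient and curvature are obtained by differentiating the
G-function directly, with effective parameters:

    ∂G/∂v  = φ(x)(x−v)/x² + (v/x)·R·a·e^(−ax) − k
    ∂²G/∂v² = 2(x−v)/x²·R·a·e^(−ax) − 2φ(x)(x−v)/x³ − (v/x)·R·a²·e^(−ax)

These forms hold at any profile and under either scaling; the familiar
symmetric-point expressions with exponent `e^(−a·v)` are their
specialization to `x = N·v` under depletion-zone scaling (where
`a_eff·x = (a/N)(N·v) = a·v`), and a unit test asserts the two agree there.
We work from the general form because the symmetric specialization is not
valid off the symmetric point or under crowding.

The **team optimum** maximizes the group payoff `N·G` over the total
transporter count, giving `k = R_eff·a_eff·e^(−a_eff·x)`: the total
`x_team = ln(Ra/k)/a_eff` is fixed. Under depletion-zone scaling the
per-cell optimum `ln(Ra/k)/a` is independent of `N`; under crowding the
fixed total is split evenly across cells. Concavity is automatic
(`∂²(NG)/∂x² = −R_eff·a_eff²·e^(−a_eff·x) < 0`). The team optimum equals
the `N = 1` ESS, where the average-benefit term of the gradient vanishes.

For `N ≥ 2` the concavity of the gain function makes the average return
per transporter exceed the marginal return, so the ESS weighs in extra
production and overshoots the team optimum — the tragedy of the commons.
`competitiveness` reports the per-cell excess `v_ess − v_team`.

## Numerical choices

- Root finding operates on the dimensionless variable `w = a·v` (with the
  *original* `a`; under depletion-zone scaling `a_eff·x` collapses to
  `a·v` at symmetric profiles). The ESS condition divided by `R·a` depends
  only on `(κ, N)`, so the solve is scale-free:
  - depletion_zone: `e^(−w)/N + ((N−1)/N)(1−e^(−w))/w = κ`
  - crowding: `e^(−Nw)/N + (N−1)(1−e^(−Nw))/(N²w) = κ`
  The crowding condition is not given in closed form anywhere upstream; it
  is derived from the G-function at the symmetric point with constant R, a.
- Brent's method on the bracket `[1e−12, 50]`, `xtol = 1e−12` on `w`. The
  condition tends to `1 > κ` as `w → 0+` (existence requires `κ < 1`,
  i.e. `k < R·a`, checked up front) and is negative at large `w`; if the
  sign has not changed by `w = 50` (possible for very small κ) the upper
  bracket grows by decades up to `1e8` before reporting a convergence
  error. Uniqueness of the root is not assumed; tests assert a single sign
  change over a wide grid rather than relying on monotonicity.
- Returned diagnostics: the first-order residual in cost units (tests hold
  it below `1e−9·k`) and the curvature at the ESS (always negative in the
  tested parameter ranges).
- `1 − e^(−z)` is computed as `−expm1(−z)` to avoid cancellation at small
  exponents.
- Table rounding is half-away-from-zero to the integer, matching the
  printed precision of the reference tables; raw floats are always
  available (`rounding="raw"`).
- `N` is an integer ≥ 1 in all public interfaces (N counts the focal cell:
  `N = 1` means no competitors). Internal validation accepts real `N` only
  where smooth sweeps are harmless (effective-parameter evaluation).

## GLUT1 parametrization

Transporter counts are backed out of transport kinetics via
`[E] = Vmax/Kcat`. With the measured 3-O-methylglucose kinetics of human
choroid plexus papilloma cells — `Vmax = 14 nmol/10⁶ cells/min`,
`Kcat = 123/s` (converted to 7380/min) — and an assumed `10⁸ cells/g` of
tissue, the concentration is 14/7380 ≈ 0.0019 nmol/10⁶ cells. Two rounding
conventions are kept side by side because they do not commute with the
downstream multiplication by Avogadro's number:

- `paper_exact` (default for table reproduction) rounds the intermediate
  concentration to one significant figure (0.002 nmol/10⁶ cells →
  0.2 nmol/g), giving 1,204,428 transporters/cell and, with the default
  ±50% variance band, 602,214–1,806,642;
- `full_precision` carries 14/7380 through unrounded (≈1,142,406/cell),
  the scientifically preferred value.

Avogadro's constant is fixed at its CODATA exact value 6.02214076e23. The
estimate exceeds the 5–7×10⁵ benchmark for red blood cells, as expected
for glucose-avid tumor cells. The baseline game parameters (R = 10000,
a = 2e−6, k = 0.0055) are chosen so that equilibrium transporter counts
fall inside this kinetics-derived band.

## Therapy simulators

A **GLUT1 inhibitor** blocks transport through channels the cell still
pays for: treated `a < a_baseline`, with efficacy tiers
low/medium/high = 1/800000, 1/1000000, 1/1200000. **Glucose starvation**
lowers the available resource: treated `R` = 7000/5000/3000. Tiers are
registry constants; custom treated values are accepted and marked
`custom`. Scenario validation enforces that each treatment changes only
its own parameter and only downward.

The **sucker's gambit** sequences environments: residents evolve the ESS
of the pre-treatment environment (by default the baseline; an optional
`pre_boost` environment models deliberately raising R first), then the
environment switches. Under the *plastic* hypothesis transporter
production re-adjusts within a lifetime and the endpoint is simply the
treated ESS; under the *genetic* hypothesis the inherited strategy is
scored under the treated parameters (`mismatched_payoff`), which is
negative for every `N ≥ 2` in both reference scenarios. The time course of
re-equilibration between switches is deliberately out of scope: the two
hypotheses select between static endpoints.

## What the tests do and do not show

All results are solved fresh at run time — the model has no data inputs
and no randomness, so the reference tables are reproduced deterministically
to the printed integer (±1 for rounding). Derivatives are cross-checked
against centered finite differences of the payoff at 100 random admissible
parameter draws; solver outputs are cross-checked against brute-force grid
argmax oracles (10⁴–10⁵ points) independent of the root-finding path; the
N = 1 solver is checked against the closed form to relative 1e−10.

The model itself idealizes heavily, and passing tests say nothing beyond
it: neighborhoods are well-mixed with no spatial structure, residents are
monomorphic, uptake is deterministic, glucose is the single limiting
resource, and treatments are static parameter changes with no
pharmacokinetics. Conclusions about real tumors inherit all of those
assumptions.

## Known limitations

- No adaptive-dynamics time integration or invasion analysis of
  polymorphic residents; equilibria only.
- The logistic / power-law shapes of `v*(N)` and payoff(N) are covered by
  monotonicity properties, not curve fits.
- Vector-valued (asymmetric) resident profiles are not exposed.
- Plotting is deliberately minimal: the tables are the product; figures
  can be rebuilt from `rounding="raw"` sweeps with matplotlib.
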