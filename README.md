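# looplaw

Loop-law analysis for stoichiometric metabolic networks:

- **Loop detection** — decide whether a flux distribution contains a
  thermodynamically infeasible internal cycle (a nonzero vector in the null
  space of the internal stoichiometric matrix, sign-consistent with the flux
  directions), by LP and by an exhaustive exact oracle.
- **Certificates of looplessness** — construct metabolite-potential vectors
  *y* whose induced reaction energies *G = S_intᵀ·y* oppose every active flux
  direction. By the theorem of the alternative, such a certificate exists
  exactly when no loop does; `check_dichotomy` machine-verifies that
  exclusivity in exact rational arithmetic.
- **Loopless FBA** — a MILP that maximizes a flux objective while excluding
  all loop-containing solutions (and nothing more), in two provably
  equivalent formulations: `nullspace` (*N_intᵀ·G = 0*) and `image`
  (*G = S_intᵀ·y*). Solutions are re-verified loop-free after every solve.

Exact rational arithmetic (`fractions.Fraction` + sympy) is the primary path
for every sign and feasibility decision; floating-point LP/MILP (scipy/HiGHS)
is the production path, always cross-checked against the exact one.

## Python API

```python
from looplaw import (
    figure2_network, internal_submatrix, FluxDistribution,
    find_loop, find_certificate, flux_admissible,
    build_loopless_milp, solve_loopless_fba,
)

net = figure2_network()                      # 3-metabolite toy cycle + exchange
v = FluxDistribution(net.reaction_ids, (0.0, 1.0, 1.0, 1.0))
find_loop(net, v)                            # LoopVector (0, 1, 1, 1) — a loop
flux_admissible(net, v)                      # False: eliminated by the loop law

v2 = FluxDistribution(net.reaction_ids, (0.0, 1.0, 1.0, 0.0))
find_loop(net, v2)                           # None — loop-free
flux_admissible(net, v2)                     # True, with a verifiable certificate

sol = solve_loopless_fba(build_loopless_milp(net, "x1", formulation="image"))
```

## Command line

All commands read the native TSV network format (or SBML with
`--format sbml` / an `.xml` extension) and print JSON to stdout. Exit codes:
0 = clean, 1 = loop found, 2 = error/infeasible.

```sh
looplaw detect-loops network.tsv flux.tsv      # {"has_loop": ..., "witness": ...}
looplaw certify network.tsv flux.tsv           # certificate JSON or loop witness
looplaw llfba network.tsv OBJECTIVE_ID \
    --formulation image --big-m 1000           # loop-free optimum + plain-FBA comparison
```

### Network TSV format

One file, two sections, tab-separated; coefficients are exact fraction
strings so round-trips are lossless:

```
[reactions]
reaction_id	is_internal	lower_bound	upper_bound
x1	0	0	1000
x2	1	-1000	1000

[stoichiometry]
metabolite_id	reaction_id	coefficient
M1	x1	1
M1	x2	-1
M2	x2	1
```

`is_internal` may be omitted; columns with a single nonzero coefficient are
then classified as exchange reactions.

Flux files are two-column TSV (`reaction_id<TAB>value`, header optional).

## Layout

| module | contents |
| --- | --- |
| `looplaw.model` | `StoichiometricNetwork`, `FluxDistribution`, `SignPattern`, internal/exchange classification |
| `looplaw.exact` | exact null-space bases, row-space membership, orthogonality check |
| `looplaw.loops` | `is_loop`, `find_loop` (LP), brute-force oracles |
| `looplaw.gordan` | matrix reduction, certificate search/verification, `check_dichotomy` |
| `looplaw.milp` | loopless-FBA MILP (both formulations), plain FBA, admissibility |
| `looplaw.synth` | toy cycle, parametric cycles, seeded random networks with planted loops |
| `looplaw.io` / `looplaw.cli` | TSV/SBML readers, TSV writer, `looplaw` CLI |
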