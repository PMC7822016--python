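# mvphi

Cause–effect structures and integrated information (Φ) for discrete
dynamical systems with **multi-valued elements**.

Most numerical work on integrated information theory (IIT) assumes binary
elements. Real models often do not: logical models of gene regulation use
multi-level variables to capture several activation thresholds, and neural
circuits can be read at more than two activity levels. `mvphi` performs
IIT's causal analysis directly on such systems, represented by a
state-by-state transition probability matrix (TPM) over joint states, plus
the number of states of each element. It is written for computational and
systems biologists who work with discrete regulatory or neural network
models and want to quantify how a model's parts constrain the model's own
past and future.

## The analysis in brief

A system of `n` elements with `S_i` states each has `S = ∏ S_i` joint
states and a row-stochastic `S × S` TPM `P`, with `P[h, s] =
Pr(s_t = s | s_{t-1} = h)`. A valid causal model factorizes over elements
(no instantaneous causation):

    Pr(s_t | s_{t-1}) = ∏_i Pr(s_{i,t} | s_{t-1})

For a *mechanism* M in state m and a *purview* Z, the **effect
repertoire** is the distribution over Z's next states given M = m with all
other inputs uniformly perturbed; the **cause repertoire** is the Bayesian
inversion under a uniform prior. Mechanism-level integration φ is the
minimum, over tripartitions of (M, Z), of the **absolute intrinsic
difference** between the intact and the partitioned repertoire,

    AID(p, q) = max_s p(s) · | log2( p(s) / q(s) ) |,

maximized over purviews to give the mechanism's maximally irreducible
cause and effect (MICE). The set of all mechanisms with φ > 0 is the
**cause–effect structure** (CES; at most `2^n − 1` distinctions). System
integration Φ is the total φ lost from the CES under the minimum
unidirectional bipartition cut, assuming cuts cannot create new
distinctions.

Alongside the core analysis the package provides:

- **Binarizations** of deterministic multi-valued evolution functions
  (Van Ham thresholds, Fauré–Kaji, Tonello) and **coarse-graining** of
  networks by grouping elements with a state mapping;
- **Generators**: random deterministic network classes (e.g. `222`, `33`,
  `44(2222)`), random asymptotic evolution functions, the p53–Mdm2
  regulatory model, and a three-neuron circuit in binary/ternary readings;
- **Survey drivers** for class statistics, shared-TPM comparisons and
  binarization-Φ correlations;
- TSV/JSON file formats and a thin `mvphi` command line
  (`validate`, `sia`, `ces`, `binarize`, `survey`, `binarize-corr`).

State indexing is little-endian mixed-radix throughout: element 0 varies
fastest in TPM rows, columns and repertoires.

## Worked example: the p53–Mdm2 network

The p53–Mdm2 model has a ternary node P (active p53) and binary nodes Mc
and Mn (cytoplasmic/nuclear Mdm2): Mn degrades P, P drives Mc, Mc shuttles
into Mn, and P inhibits Mn. Running `python examples/p53_causal_analysis.py`:

```
network: Network(P:3, Mc:2, Mn:2; S=12)
state:   (P, Mc, Mn) = (0, 0, 1)
Phi = 0.2925   minimum cut: [0, 2] -/-> [1]
3 causal distinctions (sum phi = 1.3162):
  mechanism {P}: phi = 0.5850; cause over {Mn} in state (1,), effect over {Mc,Mn} in state (0, 1)
  mechanism {Mc}: phi = 0.2925; cause over {P} in state (0,), effect over {Mn} in state (0,)
  mechanism {Mn}: phi = 0.4387; cause over {Mc} in state (1,), effect over {P} in state (0,)
```

At the attractor state, each element singly specifies a cause and an
effect — e.g. P being off irreducibly points back to Mn having been
active (φ = 0.585) — but no multi-element subset adds anything beyond its
parts, so the CES is entirely first-order. The system as a whole is
irreducible (Φ ≈ 0.29): the cheapest cut, severing inputs from {P, Mn} to
{Mc}, still destroys φ.

The other example scripts cover binarization and coarse-graining
(`binarize_p53.py`), random-class surveys (`class_survey.py`), shared-TPM
pairs (`shared_tpm.py`), and the ternary vs binary neuron circuit
(`neuron_granularity.py`).

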