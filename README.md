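# anblearn

Exact score-based learning of discrete Bayesian-network classifiers.

Given a complete discrete dataset with a designated class variable X0 and
features X1..Xn, `anblearn` finds the *globally optimal* network structure
under the BDeu marginal-likelihood score — either over all DAGs (GBN mode)
or over the augmented-naive-Bayes space (ANB mode: X0 is parentless and a
parent of every feature, with free feature–feature edges). The ANB
constraint keeps the class variable's conditional distribution estimable
when samples are scarce, and an exactly learned ANB asymptotically yields
the same class posterior as the exactly learned unrestricted network
whenever every feature lies in the class's Markov blanket adjacent to the
class. A zero-order Bayes-factor screen removes features that carry no
signal about the class before the exact search runs (the fsANB pipeline).

The package is aimed at people studying discrete classifiers and structure
learning who need exact (not greedy) optima on modest variable counts,
ground-truth simulation, and the standard evaluation toolkit around them.

## The score and the search

With N_ijk the count of X_i = k under the j-th parent configuration,
q = |parent configurations|, r = |states of X_i| and N′ the equivalent
sample size, the local log BDeu score of a parent set Pa_i is

    Score_i(Pa_i) = Σ_j [ lnΓ(N′/q) − lnΓ(N′/q + N_j) ]
                  + Σ_j Σ_k [ lnΓ(N′/(rq) + N_ijk) − lnΓ(N′/(rq)) ]

and the network score is the sum of local scores. The search exploits the
fact that the optimal network over a variable subset Z has a sink whose
parents are its best parents within Z; dynamic programming over the subset
lattice (best-parent tables, then best-sink tables) finds the global
optimum in O(n·2^n) table entries. In ANB mode the lattice runs over
features only — the class is implicitly in every parent set — which makes
the ANB search roughly twice as fast as the GBN search on the same
variables.

Parameters are fitted by the expected-a-posteriori rule
θ̂_ijk = (N′_ijk + N_ijk)/(N′_ij + N_j) with the BDeu-consistent prior
N′_ijk = 1/(r·q), under which Markov-equivalent structures define identical
class posteriors. Classification needs only the Markov blanket of X0.

Feature selection tests each feature against the class with a zero-order
Bayes factor, BF(X0, X_i) = exp(Score(CFT(X0, ∅)) − Score(CFT(X0, {X_i}))),
removing X_i when BF exceeds a threshold δ; N′ ∈ {1, 2, 5} and
δ ∈ {3, 20, 150} are tuned by two-fold cross-validated pipeline accuracy.

## Worked example

Sample a training set from the five-node cancer-screening network bundled
with the package, learn the optimal ANB exactly, and classify:

```python
import importlib.resources as resources
import anblearn as ab

with resources.as_file(resources.files("anblearn") / "networks" / "cancer.bif") as p:
    cancer = ab.read_network(p)
names = [v.name for v in cancer.variables]
ci = names.index("Cancer")

data = ab.forward_sample(cancer, 50_000, seed=7)
data.class_index = ci

result = ab.exact_search(data, "anb")
print("optimal ANB log BDeu score:", round(result.score, 3))
for p_, c_ in result.structure.edges():
    print(f"  {names[p_]} -> {names[c_]}")

model = ab.fit_eap(data, result.structure)
x = [0] * 5
x[names.index("Smoker")] = 1      # Smoker = True
x[names.index("Pollution")] = 2   # Pollution = high
x[names.index("Xray")] = 1        # Xray = positive
x[names.index("Dyspnoea")] = 1    # Dyspnoea = True
print("P(Cancer | x) =", [round(float(v), 4) for v in ab.class_posterior(model, x)])

ref = ab.reference_optimal_anb(cancer, ci)
print("SHD to population-optimal ANB:", ab.shd(result.structure, ref))
```

This prints:

```
optimal ANB log BDeu score: -104804.775
  Cancer -> Pollution
  Pollution -> Smoker
  Cancer -> Smoker
  Cancer -> Xray
  Cancer -> Dyspnoea
P(Cancer | x) = [0.3383, 0.6617]
SHD to population-optimal ANB: 0
```

The learned structure is the fewest-parameter ANB I-map of the generating
distribution: every feature hangs off the class, and the Pollution–Smoker
edge appears because conditioning on their common child Cancer couples the
two causes — an ANB cannot leave them separated. The posterior reads as a
34% cancer probability for a smoker in high pollution with a positive
X-ray and dyspnoea, and the structural Hamming distance of 0 (computed
between equivalence-class patterns) confirms exact recovery at this sample
size.

The same functionality is exposed as a command line tool, e.g.

```sh
anblearn sample --network cancer.bif --n 5000 --seed 7 --out train.csv
anblearn learn --data train.csv --class Cancer --mode anb --edges anb.edges
anblearn fsanb --data train.csv --class Cancer --seed 1 --report report.json
anblearn cv --data train.csv --class Cancer --method fsanb --folds 10 --seed 1
```

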