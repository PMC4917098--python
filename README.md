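# chimic

Chi-square-terminated grid search for the **maximal information coefficient
(MIC)**, together with the classic **ApproxMaxMI** dynamic-programming
baseline, the **MCN** (minimum cell number) complexity statistic, seeded
simulators for the standard benchmark relationships, and permutation-null
statistical-power estimation.

The package is for anyone who screens paired variables for dependence of
unknown form — e.g. ranking thousands of gene-expression features against a
phenotype — and needs a MIC whose null distribution stays close to zero on
small samples.

## The statistic

For a sample *D* of *n* pairs, every grid that partitions the x-axis into
*n<sub>x</sub>* bins and the y-axis into *n<sub>y</sub>* bins induces a
contingency table with mutual information *I(x, y)*. MIC is the best
normalized score over grids:

    MIC(x, y) = max  I(x, y) / log2 min{n_x, n_y}

ApproxMaxMI searches all grid shapes with `n_x * n_y <= B(n) = n^0.6`,
optimizing one axis by dynamic programming given an equipartition of the
other. Exhausting that budget is what inflates MIC on independent data: at
n = 100 the null mean is about 0.24.

**ChiMIC** replaces the budget with a statistical stopping rule. Axis
endpoints are inserted one at a time; each new endpoint EP_m splits a column
in two, and the r×2 contingency table of the two flanking columns is tested
for independence with a chi-square test (Yates-corrected when r = 2,
df = r − 1). If p ≥ 0.01 the endpoint does not separate genuinely different
conditional distributions, so it is rejected and the search for that row
count stops. Noiseless functional relationships still reach MIC = 1, but the
independent-pair null mean at n = 100 drops to about 0.05, and the grid
complexity measure

    MCN(D, eps) = min { log2(n_x n_y) : M[n_x][n_y] >= (1 - eps) MIC(D) }

recovers the intuitive values 2, log2 6 ≈ 2.58 and 3 for noiseless linear,
parabolic and sinusoidal relationships.

## Worked example

MIC of the noiseless sinusoid y = sin(4πx) at n = 1000:

```sh
$ chimic mic --generator sinusoidal --n 1000
{ "algorithm": "chimic", "n": 1000, "mic": 1.0, "best_shape": [4, 2],
  "mcn_eps0": 3.0, ... }
```

The four columns are the half-periods of the sinusoid: a 4×2 grid (8 cells,
MCN = 3) captures the relationship perfectly, so MIC = 1.

The same command on independent uniform pairs shows the two algorithms'
null behaviour (seed 7, n = 400):

```sh
$ chimic mic --generator independent --n 400 --seed 7 --algorithm approxmaxmi
{ ..., "mic": 0.19411370688759244, "best_shape": [18, 2], ... }
$ chimic mic --generator independent --n 400 --seed 7
{ ..., "mic": 0.04670459068793553, "best_shape": [12, 2], ... }
```

ApproxMaxMI pushes to the deepest admissible grid and scores 0.19 on pure
noise; ChiMIC's chi-square rule stops early and scores 0.05. The same
objects are available as a library:

```python
from chimic import chimic_mic, independent_pair, mcn

res = chimic_mic(independent_pair(400, seed=7))
print(res.mic, res.best_shape, mcn(res.matrix, res.mic))
```

Other subcommands: `chimic simulate` (write any generator as TSV),
`chimic mcn`, `chimic power` (permutation-null power over the noise-amplitude
grid), `chimic benchmark` (informational timings). `chimic COMMAND --help`
lists the knobs; all runs are deterministic given `--seed`.

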