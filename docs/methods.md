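# Methods

## The testing problem

Given paired observations $(x_i, y_i) \in \mathbb{R}^p \times \mathbb{R}^q$,
$i = 1, \dots, n$, drawn i.i.d. from a joint distribution $F_{XY}$, we test

$$H_0 : F_{XY} = F_X F_Y \qquad \text{vs.} \qquad H_A : F_{XY} \neq F_X F_Y .$$

Distance-based statistics make this tractable for arbitrary and unequal
dimensions: all information enters through the two $n \times n$ matrices of
pairwise distances $\tilde a_{ij} = \|x_i - x_j\|$, $\tilde b_{ij} =
\|y_i - y_j\|$ (Euclidean by default; squared-Euclidean and city-block are
supported).

## Generalized correlations and centering

After transforming each distance matrix by a centering scheme, a generalized
correlation is the Pearson correlation between the $n^2$ entries of the two
centered matrices $A$ and $B$:

$$c(\mathcal{X}_n, \mathcal{Y}_n) = \frac{1}{z} \sum_{i,j} a_{ij} b_{ij},
\qquad z = n^2 \sigma_a \sigma_b ,$$

with means and standard deviations taken over all $n^2$ positions. The
centering scheme determines the statistic:

| scheme | transform | statistic |
|---|---|---|
| `double` | $\tilde a_{ij} - \bar a_{i\cdot} - \bar a_{\cdot j} + \bar a$, zero diagonal | Dcorr |
| `unbiased` | U-centering with $n-2$, $(n-1)(n-2)$ divisors, zero diagonal | Mcorr |
| `mantel` | subtract off-diagonal grand mean, zero diagonal | Mantel |
| `single` | X centered by column, Y by row, zero diagonals | MGC default base |

All schemes zero the diagonal; the self-distance carries no information.
Because the zero diagonal participates in the means, a constant off-diagonal
matrix double-centers to $c/n$ off-diagonal rather than to zero — a fixed
point of the estimator worth knowing when reasoning about degenerate inputs.

## Local correlations and the MGC-Map

Rank every observation's neighbors: $R(A_{\cdot j}, i) = k$ when $x_i$ is the
$k$-th closest point to $x_j$ (the self-distance ranks first; ties break by
smaller index for cross-platform determinism). The local correlation at scale
$(k, l)$ restricts the Pearson correlation to entries inside the $k$- and
$l$-nearest-neighbor graphs:

$$c_{kl} = \frac{\tilde c_{kl} - e^k_A e^l_B / n^2}
{\sqrt{(v^k_A - (e^k_A)^2/n^2)(v^l_B - (e^l_B)^2/n^2)}},$$

where $\tilde c_{kl}$ sums $a_{ij} b_{ij}$ over pairs with X-rank $\le k$ and
Y-rank $\le l$, and $e$, $v$ are the corresponding restricted first and
second moments (the X-mask applies only to $A$, the Y-mask only to $B$; out-
of-neighborhood entries count as zeros and moments are over all $n^2$
positions). Each $c_{kl}$ is therefore a true correlation in $[-1, 1]$, and
$c_{nn}$ recovers the global statistic exactly.

The full $n \times n$ grid $\{c_{kl}\}$ — the MGC-Map — is computed in
$O(n^2)$ after ranking: each product $a_{ij} b_{ij}$ belongs to every scale
at least as large as its rank pair, so products are scattered onto the grid
at their rank pair and accumulated with two-dimensional prefix sums. The
per-scale masked computation is retained as an independent reference and the
test suite checks the two routes agree to $10^{-10}$ across random instances.

A scale whose restricted variance factor is non-positive returns 0 (the
$(1,1)$ scale, which sees only the zero diagonal, is the canonical case); a
variance factor below $10^{-13}$ of the total sum of squares is treated as
zero to guard against catastrophic cancellation.

## The smoothed maximum

The raw maximum of the map is inflated by sampling noise, so the statistic
is a *smoothed* maximum. Threshold the map at

$$\tau = \max\bigl(3.5 \cdot \max(0.01,\; \overline{c^2 \mid c < 0}),\;
2/n,\; c_{nn}\bigr),$$

where the mean squared negative local correlation estimates the map's noise
level under independence (negative values can only be noise). Take the
largest 8-connected component of $\{(k,l) : c_{kl} > \tau\}$; if it spans at
least $2n$ scales, the statistic $c^*$ is the maximum of the map over that
component and the optimal scales are the argmax set (all reported;
lexicographically smallest as headline). Otherwise $c^*$ defaults to the
global correlation with optimal scale $(n, n)$. Folding $c_{nn}$ into $\tau$
means a local scale must strictly beat the global statistic to be chosen.

For distance-preserving relationships ($Y = sWX + b$ with $W$ orthogonal,
$s \neq 0$), the U-centered matrices of X and Y are proportional, the global
correlation is exactly 1, no scale can exceed the threshold, and the
statistic is 1 at the global scale — the exactness property the test suite
asserts to $10^{-10}$. Conversely a local optimal scale certifies a
nonlinear relationship.

### Why `single` centering is the default

The theory above is cleanest on the U-centered (Mcorr) base, but the
operative default here centers the X matrix by column and the Y matrix by
row, mirroring the column/row rank conventions. The choice is empirical and
substantial: on the 1-D circle at $n = 100$ the single-centered MGC reaches
Monte-Carlo power 0.92 where the U-centered variant reaches 0.27, and the
single-centered variant is the one whose benchmark sample-size ratios behave
as the method's near-dominance property predicts, while the U-centered one
falls short on circular and oscillatory dependences (its global anchor $c_{nn}$ is exactly the
Mcorr statistic, which raises $\tau$ and suppresses genuine local regions on
circular and oscillatory dependences). `unbiased`, `double` and `mantel`
remain one keyword away; the exactness guarantee for affine relationships
holds for `unbiased`, and the tests exercise it there.

## Permutation inference

The p-value permutes the Y sample against X: for each of $r$ uniformly
random permutations $\pi$, the Y distance matrix is re-indexed
$B(\pi, \pi)$ and the *entire* statistic pipeline — centering, ranking, map,
threshold, region — is recomputed. Scanning all scales on every permutation
is what makes the scale search honest: one overall p-value, no per-scale
multiple-testing correction needed.

$$p = \frac{1 + \#\{c^*_0 \ge c^*\}}{r + 1}$$

The add-one correction keeps the test exactly valid (it can never report
$p = 0$); the attainable minimum is $1/(r+1)$. A constant sample on either
side yields statistic 0 and $p = 1$ by convention. A single integer seed
drives the permutation stream, making results bit-reproducible.

## The simulation suite

Twenty joint distributions (five monotone, fourteen non-monotone, one
independent) parameterized by $(n, p, \kappa)$; scalar-output relationships
use the decaying weight vector $w_d = 1/d$ so that higher dimensions dilute
rather than amplify signal. Benchmark conventions: $\kappa = 1$, $p = q = 1$
for the one-dimensional suite; $\kappa = 0$ (noiseless), $n = 100$ for the
increasing-dimension suite. $\kappa$ multiplies every additive noise term,
including those whose magnitude scales with dimension (e.g. the spiral's
$0.4\,p\,\kappa\,\varepsilon$); jitter that is part of X's own construction
(the sines' $0.02\,p$ smear, the squares' $0.05\,p$, the circles' $0.4$)
is always on. Noise is standard normal except the two parabolas' uniform
noise, as each recipe states.

What the generator emulates: exchangeable i.i.d. draws with controlled,
known dependence geometry and closed-form moments for spot checks. What it
does not: heteroscedastic real measurement error, outliers, discrete/mixed
scales, missingness, or dependence between observations — so passing tests
certify correctness of the machinery under clean i.i.d. sampling, not
robustness to messy data.

## Power estimation and sample-size search

Power against a relationship is estimated from $r$ alternative draws and $r$
null draws (X of one draw paired with Y of an independent draw — an exact
sample from the independence coupling of the same marginals). The critical
value is the empirical $1-\alpha$ quantile of the null statistics; power is
the fraction of alternative statistics above it. This null-sampling scheme
(rather than a permutation test per replicate) is orders of magnitude
cheaper and estimates the same rejection probability. Datasets and distance
matrices are shared across methods, removing simulation noise from method
contrasts.

The required-sample-size search scans $n \in \{10, 20, \dots, 200\}$ upward
and reports the first grid value whose power (default $r = 500$ replicates,
reduced from the $10^4$ a full-scale study would use; Monte-Carlo SE at
power 0.85 is $\approx 0.016$) reaches the target, without interpolation.
Ratio tables divide each method's required $n$ by MGC's on the same
datasets. When MGC itself never reaches the target within the grid the
relationship's ratio is undefined and excluded from medians; when only the
comparison method fails, its ratio enters as $+\infty$ (the ">grid"
convention). The grid cap and the reduced replicate count are the
scaled-down study conditions under which the package's benchmark medians
are computed and tested.

Comparison statistics: Dcorr, Mcorr, Mantel (centering variants above),
Hsic (Gaussian kernels with the median-heuristic bandwidth — the field's
standard when no bandwidth is specified — double-centered like Dcorr), and
absolute Pearson correlation (scalar data only; it is the classical baseline
and is blind to symmetric non-monotone dependence by design).

## Numerical and design choices

- **Tie-breaking**: stable ranking by smaller sample index; self-distance
  always rank 1, so $k = n$ includes every pair.
- **Connectivity**: 8-connectivity for the significant region — diagonal
  neighbors on the scale grid are one smoothing step apart; the more
  permissive choice where the convention is not forced.
- **Region-size rule**: the $\ge 2n$ requirement is applied to the largest
  connected component (the region actually maximized over).
- **Quantiles**: `numpy` linear-interpolation empirical quantiles for
  critical values.
- **Degenerate inputs**: zero-variance scales give 0, not NaN, and can never
  be the maximum; constant samples give statistic 0 / p-value 1.
- **Seeds**: every stochastic routine takes one integer seed; nested
  routines derive child seeds via `SeedSequence` so results are independent
  of evaluation order.

## Known limitations

- The permutation test assumes exchangeability: auto-correlated or otherwise
  non-i.i.d. observations invalidate the p-value.
- The statistic pipeline is $O(n^2 \log n)$ time and $O(n^2)$ memory;
  sub-quadratic approximations are out of scope.
- The sample-size grid caps at $n = 200$ by default; relationships harder
  than that report "beyond grid" rather than an extrapolated value.
- Metrics are limited to the three built-ins; kernel-to-distance conversions
  and negative-type metric theory are not implemented.
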