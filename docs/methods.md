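# Methods

## The calibration problem

Pooled DNA genotyping replaces per-individual genotype calls with one
aggregate two-channel measurement per (SNP, pool). If the platform's
responses to the A and B alleles are `H_A` and `H_B`, the raw A-allele
frequency is

    f = H_A / (H_A + H_B).

A measured pool frequency decomposes as `f = p + E_s + E_p + E_m`: sampling
error from the finite pool (`E[E_s^2] = p(1-p)/2N` for N members),
construction error from unequal member contributions
(`E[E_p^2] = tau * p(1-p)/2N`, with `tau` the SD of the contribution
fractions), and measurement error `E_m` from chemistry and detection.
Only `E_m` is addressable by calibration; it splits into a fixed bias `E_B`
and a random part `E_N`, with `MSE = E_B^2 + mean(E_N^2)`. The irreducible
floor of `E_N` is estimated from duplicate measurements: the within-pair
difference `d` carries twice the per-measurement variance, so
`sum(d^2)/2m` over m pairs estimates it.

## Polynomial (anchor-based) calibration

Each SNP's individuals form three clusters (AA, AB, BB). The centre
frequencies `f_AA > f_AB > f_BB` — each computed by applying the frequency
ratio to the *mean* channel responses of a class — anchor all classical
calibrations, which map them onto 1, 1/2, 0. Every method factors into:

1. **Homozygous correction** `f1 = f + d1*f + d0`, with
   `d0 = -f_BB/(f_AA - f_BB)` and `d1 = (1 - (f_AA - f_BB))/(f_AA - f_BB)`,
   pinning the homozygous anchors.
2. **Distortion correction** `f' = f1 + D(f1)`, where D repairs the
   heterozygous anchor subject to `D(0) = D(1) = 0` and `D(f1_AB) = E`
   with `E = 1/2 - f1_AB`.

Implemented distortions:

| method | D(f1) |
|---|---|
| piecewise linear | `(f1/f1_AB) E` for `f1 <= f1_AB`, else `((1-f1)/(1-f1_AB)) E` |
| quadratic (Lagrange / probe-specific correction) | `E f1 (1-f1) / (f1_AB (1-f1_AB))` |
| k-correction | `f1 (1-k)(1-f1) / (f1 (1-k) + k)`, `k = f1_AB/(1-f1_AB)` |
| Hermite variants | `H(f1) - f1` with H a cubic Hermite map (below) |

The branch assignment of the piecewise rule is fixed by the endpoint
conditions themselves (the lower branch must own `D(0) = 0`, the upper
`D(1) = 0`); textbook statements of this rule sometimes print the branches
swapped, which violates `D(1) = 0`, so the implementation derives the
assignment from the conditions rather than copying a printed form.

k-correction is algebraically identical whether applied as the channel
ratio form `f' = H_A/(H_A + k H_B)` (with `k` the ratio of the mean AB
channel responses) or as the distortion above; a test asserts the
equivalence numerically.

**Hermite variants.** Three cubic-Hermite interpolants probe whether a
stiffer interpolating family helps:

- *piecewise*: zero-derivative cubics on `[0, f1_AB]` and `[f1_AB, 1]`
  through the three anchors; outside `[0,1]` the map extends by the nearest
  node value.
- *equal domain*: with half-width `h = min(f1_AB, 1-f1_AB)`, a map on
  `[f1_AB-h, f1_AB+h]` with odd symmetry about `(f1_AB, 1/2)` built from
  the zero-derivative half-domain segment; the symmetric window spans the
  full `[0,1]` output range, so the linear continuation to the anchors
  `(0,0)` and `(1,1)` is flat.
- *equal derivative*: the equal-domain construction with the derivative at
  the centre forced to 1 (edge derivatives remain 0).

The symmetric construction and the continuation rule are design choices of
this package; only the defining one-line properties of each variant are
fixed by the field's usage. Unlike the closed forms, the Hermite maps are
genuine S-curves: they satisfy the three anchor conditions but **not**
`E = 0 => D = 0` — with a perfect heterozygous centre they still reshape
the response. For the same reason the "ideal centres give the identity
map" property holds for the closed forms only. All implemented maps are
monotone on `[0,1]`.

Degenerate inputs: a SNP with an empty genotype class, non-strictly-ordered
centres, or `f_AA = f_BB` is flagged uncalibratable and passed through
unchanged (reported, not dropped). Output clamping to `[0,1]` is on by
default when reporting pool frequencies and off inside error evaluation, so
bias/variance reflect the raw mapping rather than the clip.

## Regression calibration

A regression calibrator learns `f -> f*` per SNP from training pairs:
individuals contribute `f* in {0, 1/2, 1}`; calibration pools contribute
intermediate truths (the mean genotype frequency of their members).
Families and their operating points:

- **LR** — weighted least-squares line (no free parameters).
- **MLP** — 2 hidden layers x 2 sigmoid nodes, linear output, constant
  learning rate 0.1, momentum 0.15, at most 500 epochs. The optimizer uses
  minibatches of 8 with plateau stopping (no loss improvement > 1e-6 for 25
  epochs): the stated learning rate assumes online-style updates, and with
  large batches the network performs so few steps per epoch that it stalls
  at the training mean.
- **SVR** — nu-SVR, `nu = 0.092`, `C = 0.027`, Gaussian kernel with
  bandwidth `gamma = 1/n_features` (= 1 for the single frequency input).
  Epoch counts and kernel bandwidth are not part of the published operating
  point; the values here are this package's documented defaults.

Because pool measurements are scarce relative to individuals, any mixed
("combined") set replicates each pool row `floor(n_ind/n_pool)` or that
plus one times, distributed so total pool weight equals the individual row
count exactly — both sources then contribute equally to the loss and to
the error. Replication is bookkept as an integer `weight` and expanded at
fit time.

**Regimes.** Training and testing each draw from *individuals*, *pools* or
*combined*. Where train and test share a source, the source's sample
identifiers are first partitioned into cross-validation blocks (10 by
default; individuals and pools partitioned independently, seeded), and the
cell is assembled per fold. Partitioning precedes replication, so all
copies of a pool stay on one side of every fold boundary — the no-leakage
property is asserted over (sample, SNP, replicate) triples. Cells whose
train and test sources are disjoint (pools->individuals,
individuals->pools) need no folding and use the full sets.

## Error analysis

- Pooled MSE: weighted mean of squared errors over all test entries (flat
  across SNPs and samples), with the per-fold SD reported across folds.
- Bias/variance split: strata are (SNP, true-frequency class) — the only
  grouping with repeated identical truths, hence only reported for
  individuals-regime tests. Within-stratum mean error is bias, deviation
  around it variance; count-weighted aggregation makes
  `mse = bias_sq + variance` an exact identity.
- Best-method-per-SNP: the minimal-MSE method per SNP, ties broken toward
  the earlier method in the canonical order (`none` first), plus the
  oracle MSE of applying each SNP's winner.
- `Z^2 = (f_a - f_b)^2/(V_a + V_b)` quantifies the power currency of a
  two-pool comparison; calibration raises it by shrinking the variances.

## The simulator

Per SNP: genotypes are Hardy–Weinberg draws at population frequency `p`;
the platform responds `H_A = gain * kappa * c * (1 + eps_A)`,
`H_B = gain * (1-c) * (1 + eps_B)` for true A-fraction `c`, with `kappa`
the differential amplification ratio and `eps ~ N(0, noise_sd^2)`
multiplicative channel noise (factor truncated at 0). An optional
saturating nonlinearity `H <- H/(1 + saturation*H)` compresses strong
signals. Pools average member fractions with symmetric-Dirichlet
contribution weights whose SD matches `tau` (`tau = 0` gives exact equal
weights; `tau` must satisfy `tau^2 < (N-1)/N^2`). Duplicates regenerate
platform noise only.

Multiplicative Gaussian noise was chosen because cluster spread on
intensity platforms scales with signal amplitude; an additive noise floor
is not modelled, which means homozygous measurements have one exactly-zero
channel and therefore zero frequency noise — real platforms show some
spread at the homozygous anchors. Simulated SNPs are independent (no
linkage), and no mass-spectrometry physics is modelled. Passing tests on
this simulator therefore demonstrate correctness of the calibration
machinery under a controlled error model, not performance on any
particular chemistry.

**Default panel** (used by the benchmark): 20 SNPs x 200 individuals x 20
pools of N = 25, `p` evenly spread over [0.15, 0.85], `kappa` log-uniform
in [0.5, 2] (differential amplification up to two-fold in either
direction), `gain = 10`, `noise_sd = 0.08` (≈8% channel CV, giving a
frequency noise floor near 1e-3 in variance), `tau = 0`. The benchmark
saturation strength is 0.2: strong enough that the distortion bias at pool
frequencies (squared bias 5–14e-3) dominates the noise floor, putting the
uncalibrated pool MSE at the ~1e-2 scale characteristic of a platform that
genuinely needs calibration. The saturation is the one distortion in the
model that no anchor-based method can remove: with `kappa = 1` it leaves
all three cluster centres exactly ideal while bending the response between
them, which is precisely the failure mode the regression calibrators
exist to fix.

## Numerical choices

- Anchor conditions are exact algebra; tests assert them at 1e-9 (1e-12
  for the closed forms).
- At `f1 = f1_AB` both piecewise branches agree (value E); ties go to the
  lower branch.
- Fold assignment shuffles sorted sample identifiers with a seeded
  generator; every stochastic component (simulation, folding, MLP
  initialisation) takes an explicit seed, and identical configurations
  rerun byte-identically.
- The headline benchmark comparison evaluates the ML families with 5-fold
  cross-validation (whole pool samples held out per fold) rather than 10,
  halving the number of per-SNP fits; the regime-integrity checks use the
  full 10 folds.

## Known limitations

- The nu-SVR operating point (`C = 0.027`) bounds the fitted function's
  amplitude; on data whose calibration curve spans most of [0,1] it
  underfits, and the MLP is the stronger nonlinear family in the shipped
  benchmark.
- Quality control defines the call rate over signal-passing measurements
  of retained SNPs; this makes the three-stage filter idempotent but means
  a sample's call rate can differ from the naive all-rows fraction.
- Ground truth for real pools requires members to be individually
  genotyped; the simulator instead records the exact pooled frequency, so
  file-based workflows that derive truth from member calls are exercised
  separately in the data-layer tests.
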