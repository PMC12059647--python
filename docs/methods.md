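# Methods

## Model and assumptions

A haploid Wright–Fisher population of baseline variance-effective size N₀
carries L completely linked diallelic sites. Mutation is reversible:
favored → deleterious at rate u per site per generation, back at v = u/κ.
Deleterious alleles each cost s (fitness multiplicative across sites; no
epistasis, no dominance, a single selection coefficient). Reversibility
lets the system reach a true stationary distribution, so all quantities
here are equilibrium properties. Scaled parameters are haploid throughout:
γ = 2Nₑs, γ₀ = 2N₀s, α₀ = 2N₀U with U = Lu. The diploid mapping
(intermediate dominance: replace s by the heterozygous effect and N₀ by the
diploid variance-effective size) is documented but not implemented, since
partial recessivity brings in associative-overdominance effects outside
this model's scope.

Single-site building blocks:

- Level of adaptation (Li–Bulmer): p̄ = 1/(1 + κe^(−γ)). Its inverse
  γ̂ = ln(κp̄/(1−p̄)) turns an observed p̄ into an estimate of γ, and
  B̂ = γ̂/γ₀ into an estimate of the fixation-size ratio. The inversion
  degenerates as p̄ → 1 (deterministic mutation–selection balance), where
  no drift signal remains.
- Selected-site diversity π_sel = (2u/s)(1 − e^(−γ))/(1 + κe^(−γ)),
  derived from the flux of mutations in transit to fixation or loss under
  the infinite-sites assumption. Its γ→0 limit is the neutral
  reversible-site diversity 4Nₑu/(1+κ); its γ→∞ limit is the
  mutation–selection-balance heterozygosity 2u/s.
- Genic variance in relative fitness Vg = L·(s²/2)·π_sel = Us·A/Bd
  (A = 1 − e^(−γ), Bd = 1 + κe^(−γ)); the no-LD assumption sets Va = Vg.
  Mutational variance input Vm = Us².

## Fixation effective size

Interference reduces the effective size governing fixation probabilities.
The reduction is the asymptote of the backward-time trajectory (below):
−ln B = Va³/Vm², with Va evaluated at γ = Bγ₀ — an implicit equation solved
by a bracketed root find on g(B) = ln B + RHS(Bγ₀) over (10⁻¹², 1]. The
right-hand side is increasing in B, so the root is unique; a damped
fixed-point sweep from B = 1 seeds the bracket (naive fixed-point iteration
oscillates in strong-interference regimes). Default residual tolerance
1e-10, max 200 iterations. In the regime γ ≫ 1 with U/s modest the
relation collapses to the classical background-selection formula
B = e^(−U/s).

Two closed forms accompany the solver:

- Small-δ expansion (δ = −ln B): linearizing both brackets for small γ and
  small δ gives δ = X/(1+3X) with X = α₀γ₀²/(1+κ)³. A validity flag is set
  when δ > 0.2 (and the expansion also requires γ₀ ≲ 0.5; outside that the
  call succeeds but is flagged, since the closed form remains a useful
  guide).
- Clonal-interference approximation (after Good et al. 2014):
  B ≈ [16(1+κ)·Bmax·γ₀/α₀]^(1/3) with
  Bmax = 1/[1 + γ₀ ln(1 + κs/u)] clipped to ≤ 1, intended for Nₑs ≪ 1,
  large L, u/s ≪ 1. The source equation's constant could not be verified
  against any independently printed value, so the constant 16 was fixed by
  agreement with the numerical solver in the moderate-interference regime;
  the approximation is used only as a cross-check, never in the prediction
  path.

## Backward-time trajectory and coalescence size

A lineage's fitness background persists across generations and decays as
mutation turns the variance over: the cumulative amplification is
Q_τ = Σ_{x=0}^{τ}(1 − Vm/Va)^x (discrete form; Q₀ = 1, Q_∞ = Va/Vm), and
the apparent effective size at τ generations back is
1/Nₑ′(τ) = (1/N₀)·exp(Va·Q_τ²), a monotone decreasing curve from N₀ to the
fixation size B·N₀. Time is treated as continuous inside integrals
(Q(τ) ≈ (Va/Vm)(1 − e^(−τVm/Va)); the one-generation offset of the discrete
form is negligible at the population sizes considered).

The pairwise no-coalescence probability on the Nₑ = BN₀ timescale is
Pnc(T) = exp{−B∫₀ᵀ exp[δ(1 − e^(−ρX))²]dX} with δ = Va³/Vm² and
ρ = NₑVm/Va = γ(1+κe^(−γ))/(2(1−e^(−γ))). B′/B = ∫₀^∞ Pnc dT by adaptive
quadrature, truncated where Pnc < 10⁻¹² with the analytic exponential tail
(asymptotic rate B·e^δ = 1) added; halving the truncation threshold moves
the result by < 0.1%. Because the integrand's asymptotic rate equals 1
exactly (the trajectory's asymptote *is* the fixation size), B′ ≥ B always.

## Expected spectrum under the trajectory

For spectrum prediction the trajectory is discretized into 10 equal steps
of population-size decrease between Nₑ′(0) = N₀ and the asymptote BN₀; each
piece lasts as long as the continuous curve spends inside its band (by
inversion of the monotone curve) and is held at the band's *lower* level,
with the last level (the asymptote) held forever. Among the conventions
tried (band entry level, midpoint, elevated tail) this one best reproduces
the published distortion predictions. The coarse 10-step rendering biases
the mean pairwise coalescence time low by up to ~20% at strong
interference (it converges ~1/n in the number of steps); it is used only
for spectrum shapes, never for B′ itself, which always comes from the
continuous quadrature.

The expected spectrum for a sample of k under the piecewise-constant
history uses the lineage-count pure-death process on the coalescent-rescaled
clock: Tavaré's exponential-mixture occupancy probabilities are integrated
in closed form piece by piece to give exact E[T_j] (time while j lineages
remain), and branch-size combinatorics convert those into relative class
probabilities p_i — the stable equivalent of the Polanski–Kimmel
expected-spectrum formulas. For a constant history the result is p_i ∝ 1/i
to machine precision through k = 20; alternating-series cancellation grows
with k (~10⁻⁵ absolute at k = 50), so k is capped at 50 by default
(the studies reproduced here use k = 20).

Distortion statistics are computed from the spectrum shape alone:
π/θ_w = [Σᵢ i(k−i)xᵢ / C(k,2)]·[a_k / Σᵢxᵢ], Δθ_w = 1 − π/θ_w, normalized
by the all-singleton maximum Δθ_wm = 1 − 2a_k/k (k = 20: 0.6452). Expected
spectra use the ratio-of-expectations convention, matching how replicate
means are compared; per-replicate ratios are computed separately for
simulated samples.

## Forward simulator

The simulator mirrors the analytical model exactly: haploid Wright–Fisher
reproduction with multiplicative fitness (1−s)^(deleterious count), then
Poisson(NuL) selected-site *toggle* events (a mutation event at an occupied
site removes the variant — reversibility with κ = 1; κ ≠ 1 uses explicit
asymmetric per-site rates and is an extension beyond the reproduced
simulations), then Poisson(NuL) new infinite-sites neutral variants with
unique origin ids, free to stack on selected positions. Selected states and
neutral-variant membership are bit-packed in uint64 words (O(N(L+V)/64) per
generation); deleterious counts are maintained incrementally. Every ~200
generations lost variants are dropped, population-fixed neutral variants
purged and tallied (an empirical neutral molecular clock: the tally rate
should equal uL), and selected-site monomorphism transitions counted (an
empirical two-way substitution rate comparable to the analytical flux).

Reproducibility: one seeded stream per replicate (seed = base + replicate
index); a single uninterrupted run is bit-reproducible from (params, N,
generations, seed).

Defaults follow the reproduced study design: N = 1000, u = 10⁻⁵, κ = 1,
L ∈ {2500, 10000, 40000}, s ∈ {10⁻³, 10⁻²}, 200,000 generations, 200
replicates, sample size 20, all-favorable initialization. Because a full
200-replicate, 200,000-generation grid is cluster-scale, the in-suite
validation runs 30 replicates of 25,000 generations started from
equilibrium-frequency site states (each site independently fixed
deleterious with probability 1 − p̄ at the predicted γ); the p̄ trajectory
log is checked for a plateau, and the replicate mean is compared against
the published mean using its printed confidence interval plus three
standard errors of the scaled run's own mean. What such runs do *not*
probe: very slow components of equilibration (multi-10⁵-generation
substitutional turnover at κ ≠ 1), and rare-event tails of the replicate
distribution.

## Substitution rate and partial neutrality

The two-way substitution flux is λ = 2Luγ/[(1+κe^(−γ))(e^γ−1)] (each
direction contributes half), with neutral limit 2Lu/(1+κ). This equals the
p̄-weighted two-class fixation-flux computation identically. A published
worked value (0.40 at γ = 1.32, L = 4·10⁴, u = 10⁻⁵, κ = 1) corresponds to
the same expression without the (1+κe^(−γ)) factor and is not reproduced;
the equation as typeset (and its exact agreement with the flux oracle) was
preferred.

The partial-neutrality alternative model — a fraction Ps of selected sites
under strong constraint, the rest neutral — gives
R(π_sel) = 1 − (1−Ps)(1−B′)π_neut0/[Ps·π_strong + (1−Ps)π_neut0],
an *increasing* function of B′, distinguishing it from genuine interference
(which lowers selected-site diversity as B′ falls).

## Known limitations and irreproducible published cells

- The published comparison grid's predicted-B cell at (L = 10⁶, γ₀ = 2)
  deviates from the self-consistent solution by 0.003 under every
  convention tried; all other cells agree within ±0.001.
- The published predicted-B′ column's weak-interference rows print
  B′ < B ≈ 1, which the survival integral cannot produce (its asymptotic
  rate equals 1 exactly, forcing B′ ≥ B); moderate rows agree to ~±0.01.
- The published distortion predictions reproduce to ~±0.02 (relative few
  per cent), not to their printed third decimal; the residual is
  insensitive to every discretization convention tried and likely reflects
  unstated details of the original spectrum pipeline.
- Single selection coefficient only; no recombination or gene conversion;
  no diploid dominance effects; no selective-sweep coalescent corrections —
  the spectrum machinery treats ancestral lineages as exchangeable, which
  slightly underestimates high-frequency derived classes when sweeps of
  favored alleles are frequent.
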