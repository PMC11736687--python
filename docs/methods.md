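# Methods

## Model

The package works with a single-excitation Frenkel exciton Hamiltonian

- segment block: `H_S(t) = Σ_n ε_n(t) |n⟩⟨n| + Σ_{n≠m} J_nm |n⟩⟨m|`,
- inter-segment block: static couplings `J_nm` between sites in different
  segments.

Assumptions inherited from the incoherent-transfer framework:

1. bath fluctuations on different segments are uncorrelated;
2. the donor thermalizes within its segment before transfer (the emission
   matrix carries a segment Boltzmann state);
3. inter-segment couplings are constant in time — if a per-frame coupling
   trajectory is supplied, the inter-segment block is frozen to its time
   mean and a `CouplingFluctuationWarning` reports the discarded spread;
4. inter-segment transfer is slower than the decoherence of the rate
   response (checked a posteriori via `Γ` vs `k`).

## Units and constants

Energies/couplings cm⁻¹, time fs, distances nm (Å only in docstrings where
noted), dipoles Debye, rates ps⁻¹. Conversion constants are frozen in
`constants.py`:

- `u = 2πc = 1.8836516×10⁻⁴ rad fs⁻¹ (cm⁻¹)⁻¹` (CODATA c),
- `k_B = 0.6950348 cm⁻¹ K⁻¹`,
- point-dipole constant `C = 5034.12 cm⁻¹ Å³ D⁻²`, i.e.
  `J = screening · C · [μ̂_n·μ̂_m − 3(μ̂_n·r̂)(μ̂_m·r̂)] |μ_n||μ_m| / r³`.
  With 11.4 D dipoles this gives −1526.13 cm⁻¹ for collinear dipoles at
  9.5 Å and 193.85 cm⁻¹ broadside at 15 Å, which pins C to the printed
  precision of those reference couplings.

## Stochastic site energies

Each site's fluctuation is a sum of independent stationary Gaussian
components with exponential autocorrelation `σ² e^{−t/τ}` (overdamped
Brownian oscillator / OU process), sampled with the exact discrete update
`x_{k+1} = x_k e^{−Δt/τ} + σ√(1−e^{−2Δt/τ}) ξ_k`, `x_0 ~ N(0, σ)`. This is
unbiased at any step size, unlike an Euler discretization. Random streams
are spawned per (site, component) from one master seed, so enlarging the
system never perturbs existing streams. "Static" disorder is modeled either
as a slow OU component (e.g. τ = 10 ps) or as frozen per-trajectory offsets
(`static_mode = frozen`), the latter feeding the batch workflow in which one
rate is computed per disorder realization and the rate distribution is
summarized.

## Propagation

The Hamiltonian is taken constant across each step at its value at the
step's left edge (trajectory-sampling convention; the error is O(Δt²) and
controlled by the 3 fs step used throughout). Step propagators
`exp(−i u H Δt)` are evaluated by eigendecomposition; cumulative window
propagators are ordered products. Unitarity is preserved to 10⁻¹⁰ and
tested. Single-site segments use the exact phase-accumulation fast path
(identical algebra, no diagonalization).

## Absorption, emission, rate

- `I(t) = ⟨U(t)⟩`, identity at t = 0.
- `E(t) = ⟨U†(t) ρ_eq⟩`, trace 1 at t = 0. The conjugated evolution gives
  the emission series the opposite phase sense from absorption, so the
  product selects energy-conserving donor→acceptor channels; this
  orientation (rather than `ρ U` or unconjugated variants) is pinned by
  three contracts: trace normalization at t = 0, |E₁₁| = |I₁₁| for a single
  site, and exact agreement with the golden-rule spectral-overlap rate for
  a weakly coupled dimer (tested at 5%).
- `ρ_eq` is built per sampling window from the segment Hamiltonian at the
  window's first frame (`equilibrium = instantaneous`, default) or from the
  trajectory-mean segment Hamiltonian (`equilibrium = average`). The choice
  matters when fast dynamic disorder is comparable to the intra-segment
  couplings: the instantaneous state is more localized than the
  motionally-narrowed emitting ensemble, the average state discards slow
  (quasi-static) localization. Both are exposed; see Limitations.
- `R(t) = Tr[J E_D(t) Jᵀ I_A(t)]` with J the (acceptor × donor) block;
  `k = 2u² Re ∫₀^{t_c} R dt`, reported in ps⁻¹. The prefactor 2u² is fixed
  by the Förster-limit equivalence test, not hard-coded lore.

### Quadrature

The rate integral uses the trapezium sum with a weight of one (not one
half) on the last point, partially compensating the finite-t_c truncation.
The Simpson 1/3 value is always computed alongside; a relative spread above
3% (configurable) raises a `QuadratureWarning` advising a smaller time
step. For strongly dephasing systems the response decays within a few
frames and the warning fires by design — the trapezium value is still the
reported rate.

### Decoherence

`Γ = |R(0)| / ∫₀^{t_c} |R(t)| dt` (same end-point convention), the inverse
persistence time of the rate response: for `R ∝ e^{−t/τ}` it returns 1/τ,
and it is invariant under scaling of R. Ordered pairs are classified
`coherent-flagged` when `k ≥ Γ`, `borderline` when `Γ/k < 3` (a reading of
"on the edge" for pairs only a few times slower than dephasing;
configurable), else `incoherent-ok`.

## Thermal correction

Raw trajectory rates come from a classical bath and need not satisfy
detailed balance. For every pair the corrected rates are the unique
solution of

- `k'_{ji} + k'_{ij} = k_{ji} + k_{ij}` (pairwise equilibration rate kept),
- `k'_{ji}/k'_{ij} = e^{−(Ẽ_j−Ẽ_i)/k_BT}` (Boltzmann ratio),

i.e. `k'_{ji} = (k_{ji}+k_{ij})·b/(1+b)` with `b` the Boltzmann factor; the
diagonal is rebuilt as minus the column sums. A raw pair that itself
violates detailed balance at equal energies is therefore symmetrized — the
two constraints cannot preserve such a pair. Segment energies Ẽ default to
the time average of `Tr[H(t) ρ_eq(H(t))]` (flat eigenvalue average in the
HT limit or with `mode="flat"`). The optional population adjustment
`ΔE_j = k_B T ln(N P_j / D_j)` (off by default) shifts the energies using
the equilibrium populations P of the *uncorrected* rate matrix, so that
thermal effects already contained in the lineshapes are not double-counted;
it vanishes identically in the HT limit where `P_j = D_j/N`.

## Segmentation

Per sampled frame the full-system Hamiltonian is diagonalized and
`Σ_a |c_na||c_ma|` accumulated; the frame average is the ADM. With flat
eigenstate weights the diagonal is exactly 1 (completeness), matching the
diagonal-normalized convention; a Boltzmann-weighted variant is behind
`boltzmann_temperature`. Clustering uses the distance `d_nm = −ln ADM_nm`:
sites with `d < ε_p` (strict inequality) join the same segment, and since
the pairwise criterion is transitively closed, segments are the connected
components of that graph — identical to cutting the single-linkage
dendrogram at ε_p (equivalence is property-tested on random matrices). The
participation-ratio matrix `PR_nm = ⟨Σ_a |c_na|²|c_ma|²⟩` is provided as an
alternative clustering input. Segments are numbered from 1 by ascending
mean exciton energy (per-site energies `Σ_a |c_na|² E_a` averaged over
frames, then averaged over member sites).

## Kinetics

`K[to, from]` with diagonal = −(column sums), so columns sum to zero and
`P(t) = e^{Kt} P0` conserves population (10⁻¹⁰, tested). Propagation uses
the eigendecomposition with a scaling-and-squaring fallback for
(near-)defective K. The eigenvector of the near-zero eigenvalue, normalized
to unit sum, is the equilibrium population; remaining eigenpairs are
relaxation processes with rates −λ. Imaginary parts below
`10⁻⁸·max|Re λ|` are treated as numerical noise; larger ones indicate an
unphysical circular current (possible for ≥3 segments without detailed
balance) and raise a `ComplexEigenvalueWarning` recommending more sampling
while still returning the result with a caution flag. Negative off-diagonal
rates (sampling noise) are flagged, never clipped.

## Sampling and problem sizes

Disorder averaging uses equidistant window starts (`n_samples`,
`interval`). Reference setups in `studies.py`:

- **Chain slip study**: two J-aggregate chains, 0.95 nm spacing, 1.5 nm
  separation, 11.4 D dipoles, σ_dyn = 1500 cm⁻¹ / 6 fs plus a slow static
  component (τ = 10 ps), dt = 3 fs, t_c = 72 fs, 300 K. Full scale is 200
  molecules per chain and 10⁴ windows; the package's reference computation
  (acceptance script and tests) runs 100 molecules per chain and 10³
  windows spread over the same 600 ps trajectory length, which leaves the
  percent rate reduction stable to ~1% while fitting in minutes on one
  core. Both slips share one trajectory; only the inter-chain coupling
  block changes, which is also how the staged workflow is meant to be
  reused.
- **Ring distance scan**: two 18-site rings of 3 nm radius, tangential
  6.3 D dipoles, screening 0.55, σ = 256 cm⁻¹ / 150 fs, mean transition
  energy 11955 cm⁻¹; one trajectory serves all separations.

## What the synthetic generator does and does not emulate

The OU generator reproduces Gaussian spectral diffusion with prescribed
amplitudes and correlation times — the dominant line-broadening mechanism
in the systems above. It does not emulate non-Gaussian baths, correlated
fluctuations between sites, underdamped vibrations, or coupling
fluctuations; passing tests therefore validate the rate machinery under
Gaussian-Markovian noise, not the fidelity of any specific material's bath.
MD-derived trajectories can be supplied through the same
`HamiltonianTrajectory` container and file formats.

## Numerical choices

- Exact OU discretization (unbiased at any dt); per-stream spawned seeds.
- Eigendecomposition per step for propagators (systems here are ≤ a few
  hundred sites; Trotter/Chebyshev schemes are out of scope).
- Strict inequality at the clustering cutoff; ties at exactly ε_p do not
  merge.
- Coupling constant, u, and k_B frozen to the digits listed above so
  reference couplings reproduce to 4–5 significant figures.
- Workflow stages write deterministic artifacts for fixed seeds; per-window
  work is independent and summed in a fixed order, so results do not depend
  on the BLAS thread count.

## Known limitations

- The choice of Hamiltonian behind the emission `ρ_eq` is a genuine
  ambiguity of the time-domain formulation when fast disorder is comparable
  to intra-segment couplings (σ_dyn ≈ |J|). The instantaneous default then
  yields a more localized donor ensemble than the motionally-narrowed
  emitting states; quantities that hinge on delocalization-sensitive
  interference between many coupling pathways (e.g. supertransfer
  enhancements or suppressions of aggregate-to-aggregate rates) can shift
  by tens of percent between defensible conventions. Single-segment line
  shapes, weak-coupling (Förster-limit) rates, distance scaling and all
  post-processing are insensitive to this choice.
- Second-order perturbation theory in the inter-segment coupling: no
  coherent inter-segment dynamics, no higher-order corrections.
- The decoherence diagnostic Γ is a heuristic timescale, not a rigorous
  validity bound.
- Classical bath: detailed balance is imposed a posteriori, not derived.
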