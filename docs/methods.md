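# Methods

This note records the models implemented in `mrellg`, the numerical
choices behind them, and what the synthetic experiments do and do not
demonstrate.

## Amplitude likelihood and LLG

All likelihoods operate on normalized amplitudes E with unit Wilson
variance; ε factors are divided into the normalization beforehand, so the
Wilson baseline is the standard Rayleigh density for acentric reflections
and the half-Gaussian for centric ones. Given a calculated amplitude
E_c and correlation σA, the conditional density of the observed E_o is

- acentric (Rice):
  p(E_o | E_c) = 2E_o/(1−σA²) · exp(−(E_o² + σA²E_c²)/(1−σA²)) · I₀(2σA·E_o·E_c/(1−σA²))
- centric (Woolfson):
  p(E_o | E_c) = √(2/π(1−σA²)) · exp(−(E_o² + σA²E_c²)/(2(1−σA²))) · cosh(σA·E_o·E_c/(1−σA²))

and the per-reflection LLG is log p(E_o|E_c) minus the Wilson log-density
of E_o. At σA = 0 the contribution is identically zero. Numerical
stability: log I₀ is evaluated as log(i0e(x)) + x and log cosh as
|x| + log1p(e^(−2|x|)) − log 2, both exact to machine precision for large
arguments. The measurement-error model is noise-free likelihood — σA
absorbs model imperfection only; experimental-error inflation is a
documented non-goal (the simulator can still add amplitude noise to probe
robustness).

## The σA curve

σA(d) = √fm · (1 − fsol·e^(−Bsol·s²/4)) · e^(−(2π²/3)·rmsd²·s²), s = 1/d.

The exponent constant 2π²/3 is forced by the B = 8π²Δ²/3 error-to-B
relationship together with the Debye–Waller form e^(−B·s²/4): isotropic
Gaussian coordinate errors of 3-D r.m.s. magnitude `rmsd` attenuate the
model's contribution by exactly this factor. The Babinet-style solvent
pair (fsol, Bsol) matters only below roughly 8 Å resolution and defaults
to off (fsol = 0); both parameters are exposed for low-resolution work.

## The eLLG

The per-reflection eLLG is defined here as the exact expectation of the
per-reflection LLG over the joint (E_o, E_c) distribution at the given
σA. This expectation has no elementary closed form (its Bessel/cosh term
resists analytic integration), so it is evaluated by deterministic Gauss
quadrature:

- acentric: E_c² ~ Exp(1) via 64-point Gauss–Laguerre; the two real noise
  components via 40-point Gauss–Hermite. The integrand is smooth because
  I₀ is an even entire function of its argument.
- centric: the log-cosh term behaves like |·| at large argument, which
  stalls Hermite convergence, so the inner integral over the signed
  observed value is split at the E_o = 0 kink with Gauss–Legendre nodes
  centred on the conditional mean (60 × 2 × 48 nodes).

Both schemes are accurate to ~1e-8 up to σA = 0.99. Values are cached in
a monotone PCHIP spline over 211 nodes; beyond σA = 0.99 the curve is
continued with its asymptote −½·log(1−σA²) + C (C fixed by continuity;
the true offset is constant there to ~0.02 log-units). At σA = 1 the
expectation diverges; the policy is to return +inf with a warning rather
than raise, and `total_ellg` propagates it. In the weak-signal limit the
eLLG behaves as σA⁴/2 per reflection for both centricities.

The test suite ties the quadrature to an independent Monte-Carlo
expectation (sampling the joint model and averaging the same LLG) within
3 standard errors across σA ∈ {0.1, …, 0.9} — the central correctness
oracle for the whole likelihood stack.

## Reflection generation and symmetry

d-spacings come from the reciprocal metric tensor (1/d² = hᵀG*h).
Reflection generation enumerates |h_i| ≤ a_i/dmin (a rigorous bound: the
index along axis i is the dot product of the scattering vector with the
direct basis vector) and keeps one Friedel representative by the
convention h > 0, or h = 0 and k > 0, or h = k = 0 and l > 0. Symmetry is
supplied as explicit operator lists — "x,y,z"-style triplets or a named
space group resolved through gemmi's tables — because the likelihood
machinery needs only centricity (some rotation maps h to −h) and ε (the
count of rotations fixing h). Systematic absences beyond ε, anomalous
pairs and unmerged data are out of scope.

## Synthetic diffraction laboratory

Scattering factors are the point-atom approximation f = Z. The theory
operates on normalized amplitudes, where the resolution falloff of the
form factor cancels shell by shell, and constant f keeps the independent
per-atom test oracle exact; a single-Gaussian hook can be added at
`Atom.f` without touching the engine. Random targets place one
carbon "super-atom" per residue uniformly in the cell with a 1.5 Å
minimum-distance rejection — clashes are irrelevant to the statistics
under test, but the guard keeps low-resolution Wilson behaviour clean.
(The hard-core exclusion does depress mean intensity by a few percent in
the highest shells relative to ideal Wilson statistics; tests that check
the Wilson premise itself therefore use unconstrained uniform atoms.)

`simulate_pair` draws Gaussian displacements and rescales them so the
realized r.m.s.d. over the *retained* atom pairs equals the request to
floating-point accuracy (the retained subset is chosen before rescaling);
fm is measured in scattering (Σ(occ·f)² of retained atoms over the
total), which coincides with the atom-count fraction for identical atoms.
Exact-rmsd rescaling rather than expectation-rmsd makes every downstream
example deterministic.

Wilson normalization uses equal-count resolution shells in s². Empirical
mode scales each shell by the observed mean of |F|²/ε, making the
per-shell mean ε-corrected E² exactly 1, idempotent and scale-invariant;
theoretical mode accepts ΣN from the model instead.

## VRMS refinement and error weighting

`refine_vrms` maximizes the total LLG over the single parameter rmsd,
with σA(d) from the curve at fixed fm: a 41-point coarse grid over
[0.01, 5] Å brackets the optimum, then bounded Brent polishes it to
1e-6 Å. The default starting value is 1.2 Å, refined for posed models.
On noise-free simulated pairs with ~2500 reflections the true rmsd is
recovered within a few percent across 0.4–1.2 Å.

`weighting_benefit` compares two ways of using per-residue error
estimates Δ: per-atom B = 8π²Δ²/3 versus the best single uniform B
(scanned over 0–80 Å², 33 points). VRMS is refined for each weighting so
both get their best σA curve; the reported pair is therefore a fair
best-vs-best comparison. On a two-noise-level synthetic model the
weighted LLG exceeds the best uniform LLG by ~100 log-units at ~3000
reflections; with homogeneous errors the two agree to within 1 %, and
deliberately shuffled (wrong) estimates never beat the correct ones.

## Model preparation

Per-residue error estimates are read from the B column (the residue's CA
value, applied to all atoms of the residue — matching the per-residue
convention of predicted-error records; a per-atom alternative would be a
small extension). Trimming removes residues with Δ above a threshold
(0.7, 1.0 and 1.2 Å are the values used on real predicted models);
trimming is idempotent and monotone in the threshold. pLDDT input is
converted by the monotone empirical mapping Δ = 1.5·e^(4(0.7−pLDDT/100)),
clearly flagged as an approximation. Ensemble divergence trimming
superposes all members onto the first over the common residue core, with
a second consensus pass (refit on the better-agreeing half) so a single
displaced residue cannot smear small divergences over the whole chain —
consistent with the observation that meaningful divergence thresholds for
tightly consistent predicted ensembles are exceptionally small (~0.1 Å).
fm estimation divides the model's Σ(occ·f)² by the asymmetric-unit total,
computable from a FASTA sequence via per-residue heavy-atom compositions.

## Scoring

Superposition is Kabsch via SVD with the proper-rotation determinant
correction. GDT uses a seed-and-extend search (seed windows of 3/5/7
residues plus the global fit; iterative refit on inliers per cutoff, best
fraction kept) — a documented simplification of the full LGA program, not
a replication of it; with a user-fixed superposition it reduces to exact
distance counting. Pairing is sequence-dependent (1:1 by index);
sequence-independent alignment is out of scope. LCS scans window lengths
exhaustively (window r.m.s.d. is not monotone under extension, so no
early termination is sound); O(n²) windows is immaterial for chains of a
few hundred residues. The GDT/LCS combination weight defaults to 0.75
toward GDT and is configurable — the exact mix inside LGA_S is not
published, so the default is an approximation and labelled as such.

Helix local axes use the Sugeta–Miyazawa 4-CA construction; the bending
angle compares axes one turn (4 windows) apart. Default classes: kinked
at max bend ≥ 20°, linear below 5°, else curved — chosen so a ~7° maximum
bend falls on the curved side and a ~26° bend on the kinked side, the
sense in which model and target helices differ in practice. Inter-helix
angles come from least-squares line fits through the local-axis origins,
reported unsigned in [0, 180°] by default; a signed convention (triple
product against a caller-supplied reference normal) is exposed because
published helix-packing angles use varying sign conventions.

## Survey

Free-text method strings are lower-cased, punctuation-stripped and
matched as tokens, collapsed abbreviations ("S.A.D." → "sad") and known
phrases; when several categories are named the most senior wins
(MIRAS > MIR > MAD > SIRAS > SIR > SAD > MR > Fourier synthesis).
Ab-initio/direct-methods strings are excluded (historically they mostly
denote fragment-based MR or substructure determination); unknown strings
map to NULL with a logged sample. The shipped alias dictionary is
best-effort — the historical field was free-format — and extensible via a
YAML mapping. Windows are half-open five-year calendar intervals starting
at 2000 (earlier entries are too sparse); a record is counted only when
deposition *and* release fall in the same window, entity ID is '1', and
the category is neither NULL nor EXCLUDED. Revision dates are ignored:
they are dominated by archive-wide renamings. The fixture generator
emulates the spelling variety, window composition, null entries and
straddling records, and round-trips exactly through the pipeline when
straddle-free.

## Problem sizes and determinism

The synthetic experiments use 250-residue models in ~30 Å cells at
2.8–3.2 Å resolution (2500–6000 reflections) and 2000-draw Monte-Carlo
oracles — sizes at which every statistical check is comfortably resolved
while the full suite and the acceptance script each run in tens of
seconds. All randomness flows through seeded `numpy` generators;
`scripts/acceptance.py` derives every stream from its `--seed`.

## Limitations

The laboratory is deliberately idealized: point atoms, no bulk solvent,
no anisotropy, no twinning or translational NCS, noise-free likelihoods.
Passing tests demonstrate the internal consistency of the σA/eLLG/LLG
machinery and the exactness of the preparation and scoring arithmetic —
not performance on real diffraction data, where measurement error,
solvent and data pathologies (e.g. the amplitude modulations of coiled
coils) intervene. Running molecular replacement itself — rotation and
translation searches, packing, map correlation — is out of scope.
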