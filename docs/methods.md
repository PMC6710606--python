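# Methods

## Model and assumptions

The package treats a drug-sized molecule as a set of `x` fragments, one per
binding pocket, and estimates the whole molecule's ligand efficiency from
its parts. The underlying additivity assumption is strong and stated
plainly: each fragment is assumed to bind its pocket with the same free
energy alone and in the assembled molecule (same pose, no hot spots, no
super-additivity or cooperativity), so that ΔG_T ≈ Σ ΔG_i and every
departure — linker strain, rigid-body entropy loss, linker binding, and any
residual non-additivity — is an explicit correction term, not part of the
averaging model.

Two averaging modes are provided:

- **arithmetic** — `LE_T_app = mean(LE_i)`. Exactly equal to ΔG_T/N_T when
  all fragments have the same heavy-atom count and all corrections are
  zero; an approximation otherwise.
- **wrms** — `LE_T_app = sqrt(Σ LE_i² w_i / Σ w_i)`. The weight policy is
  `w_i = N_i` by default (options: `sqrt_n`, `unit`). The weighted RMS
  always dominates the arithmetic mean (equality iff all LE_i coincide), so
  wrms is the more optimistic estimator on heterogeneous slates.

The subtractive average LE_δ answers "what must the not-yet-chosen
fragments deliver?". Its weighted-RMS closed form is derived here as the
unique expression consistent with the WRMS averaging formula — inserting
`x − a` copies of `(LE_δ, W_δ)` next to the known fragments reproduces the
target apparent LE to relative 1e-10, which the test suite asserts together
with the two anchor identities (`a = 0` ⇒ LE_δ = target; `x − a = 1` ⇒
LE_δ = the held-out fragment's LE, exactly, not only in the limit). A
negative discriminant means no real LE_δ solves the equality because the
known fragments already exceed the target's squared-efficiency budget; this
is surfaced as a first-class `DeltaInfeasibleError`, and the screening
layer maps it to a requirement of 0 ("already funded") since its acceptance
criterion is an inequality, not an equality.

## Conventions and units

- Free energies in kcal/mol, signed: ΔG = RT·ln K_d, negative for binders.
  Some of the literature writes the opposite sign; the signed-internal /
  magnitude-by-default split removes that ambiguity: all efficiency metrics
  are reported as magnitudes (positive, ~0.3 kcal·mol⁻¹·HA⁻¹ scale) unless
  `convention="signed"` is requested.
- Temperature defaults to 298.15 K with R = 1.987e-3 kcal·mol⁻¹·K⁻¹; both
  overridable through `ThermoParams`.
- K_d accepted in M, µM, or nM at parse time; internally always molar.
- Non-binders (ΔG ≥ 0) are flagged, excluded from screening by default, and
  contribute an effective LE of 0 when explicitly allowed.

## Screening

The screen is an exact depth-first branch-and-bound over pockets. A partial
choice is abandoned only when even the best per-fragment acceptance margins
in the unfilled pockets cannot reach the cutoff; margins are `LE_i − c`
(arithmetic) or `w_i(LE_i² − c²)` (wrms), whose sums are sign-equivalent to
the acceptance inequality. Pruning carries a 1e-9 safety slack and every
surviving leaf is re-evaluated with the same averaging functions an
exhaustive enumeration would use, so the accepted set matches brute force
bit-for-bit even for combinations exactly at the cutoff (verified over 400
random libraries in the test suite). Accepted combinations are sorted by
apparent LE descending, then lexicographically by fragment key — the output
order is a package choice, made for determinism.

The acceptance inequality is exact (`LE_T_app ≥ cutoff`); a `tolerance`
knob relaxes it to `cutoff − tolerance` but defaults to 0. Combinations
must fill every pocket. Fragments are keyed `pocket_id:fragment_id`, so the
same identifier in two pockets denotes two distinct entities. A classical
per-fragment screen (`classic_classification`, CLI `--classic`) is provided
for comparison with partner-blind triage.

`required_le_for_remaining` returns the mode-appropriate LE_δ for a partial
choice, clamped to ≥ 0, with `math.inf` signalling that even the best
fragments in the unfilled pockets cannot reach the cutoff. In wrms mode the
ideal weight W_δ defaults to the mean weight of the candidate fragments in
the unfilled pockets.

## Synthetic data

The generator emulates a fragment-linking campaign, not any particular
published dataset. Defaults (chosen once, as the package's study
conditions): 2 pockets (two-fragment linking), 8 fragments per pocket,
fragment LE drawn from a normal truncated at 0 with mean 0.35 and sd 0.10
kcal·mol⁻¹·HA⁻¹ — the scale of typical fragment hits — and N uniform on
[8, 16] (rule-of-three-sized fragments). ΔG is back-computed as −LE·N.
Linked molecules obey `N_T = Σ N_i + linker_atoms` and `ΔG_T = Σ ΔG_i +
ΔG_rigid + ΔG_binding + ΔG_strain + ε`, with ε Gaussian whole-molecule
noise (`noise_sd`) — non-additivity is modelled at the molecule level, not
per fragment. `linking_study` pools two-fragment comparisons across 10
synthetic targets by default, mirroring the shape of a small literature
linking survey without claiming its numbers.

Randomness is split into three `SeedSequence` child streams (library,
noise, per-molecule choices). Because the standard-normal noise deviates
are drawn before scaling by `noise_sd`, a seed-fixed ladder over noise
levels reuses identical deviates, making the mean absolute deviation
exactly proportional to `noise_sd` in the equal-size, zero-correction
regime — the monotone noise response is an identity of the design, not a
statistical observation.

What passing simulation tests show — and do not show: they confirm the
internal consistency of the averaging algebra and the direction of the
noise response; they say nothing about real protein targets, where pose
changes, hot spots and cooperativity violate the additivity assumption in
ways no whole-molecule Gaussian captures.

## Numerical choices

- Identity and round-trip assertions at relative 1e-10; the closed-form
  WRMS LE_δ agrees with a bracketing root finder to 1e-8 in tests.
- The equal-size additivity identity is algebraically exact; floating-point
  summation order leaves ≤ a few ulps (~1e-16 observed), so tests assert
  ≤ 1e-12 on a ~0.4 scale.
- Tiny negative WRMS discriminants (within 1e-10 relative of 0) are clamped
  to 0 rather than raised, since they arise from cancellation when the
  target is exactly attained.
- Truncated-normal sampling is by rejection; with sd = 0 the distribution
  collapses to the mean deterministically.

## Known limitations

- Affinities are inputs; no docking, ΔG prediction, or 3-D structure
  handling.
- No lipophilicity-aware metrics (LLE, LELP), no hot-spot or
  super-additivity modelling, no growing/merging elaboration strategies —
  linking only.
- The exhaustive-oracle cross-check is a test-time device for small
  libraries; for very large `∏|pocket|` the pruned search still runs but
  grows with the accepted set size.
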