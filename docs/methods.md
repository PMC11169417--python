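# Methods

This note records the models, conventions and numerical choices behind
`scaffscreen`, what the synthetic generators do and do not emulate, and the
known limitations.

## Library enumeration

Reaction templates are SMARTS/SMIRKS transforms with ordered role names, one
per reactant slot (validated at parse time). Substrate-scope rules restrict
which building blocks may occupy each role: `required_substructure` and
`forbidden_substructure` take SMARTS queries, `property_bound` takes a named
2D property (MW, logP, TPSA, HBD, HBA, RB, rings, heavy atoms) with a closed
interval. A block fails iff a forbidden pattern matches, a required pattern
is absent, or a bound is violated; the decisive rule ids are returned for
audit.

Multi-component reactions may declare mechanism `steps`, each a single-step
transform consuming original roles and/or intermediates produced by earlier
steps. The step chain is validated (undefined intermediates rejected; the
steps must jointly consume exactly the declared roles), and enumeration
through the steps reproduces the one-pot transform's product set — a
property the test suite asserts on a worked double-alkylation example.

Conventions, chosen where a library builder has genuine freedom:

- **Dedup key** is the canonical isomeric SMILES. Stereocenters a transform
  leaves unspecified stay undefined; constitutions, not stereoisomers, are
  enumerated (stereo-enumeration would multiply counts without adding
  screening information).
- **Ordering** is lexicographic in (template id, block-id tuple), so
  enumeration is reproducible without seeds.
- **Tuple failure policy**: a reactant tuple on which the transform fails is
  skipped and logged. One incompatible block must not abort a large library
  build.

## Bemis–Murcko scaffolds

The scaffold is the molecular framework left after iteratively pruning
terminal side-chain atoms: ring systems plus the acyclic linkers connecting
them. Atoms double-bonded to the framework (the oxindole carbonyl oxygen
being the motivating case) are retained, matching common practice; a
`strip_exocyclic` switch removes them. The scaffold **key** is the canonical
SMILES of the framework with charges neutralized (protons adjusted) and
isotopes stripped; an all-carbon generic-framework key is available as a
non-default option, since published scaffold counts rarely state which
abstraction level they used. Acyclic molecules index under the reserved key
`ACYCLIC`.

`decompose_units` labels every atom as ring system (maximal fused/spiro
components, extended by exocyclic multiply-bonded atoms), linker (remaining
framework atoms) or side chain — a partition the tests assert exactly, and
cross-check against an independent iterative-pruning oracle.

Monosubstituted expansion attaches one substituent at one site; allowed
sites default to any H-bearing aromatic or sp³ ring atom, overridable by an
explicit site list. Acyclic substituents preserve the scaffold key (asserted
per product); ring-containing substituents change it and are therefore
flagged and excluded from a scaffold's sub-library by default.

## Hierarchical screening

Round 1 scores the bare scaffold structure per key (a methyl-capped
representative is an option — published campaigns rarely state which was
docked). Selection is an explicit `top_k` with a deterministic
(score, key) tie-break; a vague "energy advantage" threshold is not a usable
contract. Round 2 scores the members of the selected scaffolds, keeps the
best (minimum) of `n_poses` pose scores per ligand, applies the
residue-interaction filter, and ranks by (score, record id).

The filter passes a pose iff it contacts at least `min_matches` of the
required residues. Default: the four voltage-sensor hot spots Tyr1537,
Trp1538, Arg1602, Arg1608 with `min_matches = 2` — "prioritized during
visual inspection" is not quantifiable, so the default is documented and
configurable rather than baked in.

The scorer contract is: deterministic given (canonical structure, seed),
lower is better, per-pose scores plus residue contacts. External docking
adapters are out of the tested core; the JSON pose-report schema
(record_id, pose_id, score, contacts[]) is the integration point. The
built-in `SyntheticScorer` scores −(weighted substructure-match count) with
optional seeded per-pose Gaussian jitter and emits contacts for the motifs
it matches, which exercises every branch of the funnel.

The audit log reconciles the funnel: round-2 candidates scored = Σ members
of selected scaffolds; passed + rejections = scored. Funnel sizes
(scaffolds in, scaffolds selected, hits out) are always outputs, never
constants.

## Chemical space

The inertia tensor is mass-weighted with hydrogens included when present
(`mass_weighted=False` switches to unit masses; published shape analyses
frequently omit which convention they used, and the choice shifts NPR
values). Eigenvalues are sorted ascending; npr1 = I₁/I₃ and npr2 = I₂/I₃
obey npr1 ≤ npr2 ≤ 1 and npr1 + npr2 ≥ 1 for any rigid body.

Conformers come one per molecule from ETKDGv3 with a fixed seed followed by
an MMFF relax; embedding failures are flagged `EMBED_FAIL`, never silently
dropped. Descriptors are 2D: FRB is defined as rotatable bonds divided by
heavy-heavy bonds (0 when none); chiral centers count assigned plus
unassigned; ring count is the SSSR count.

PCA z-scores each descriptor (unit variance — descriptor units are
incommensurate), drops zero-variance columns with a warning, and keeps the
full explained-variance spectrum even when fewer score components are
requested, so the variance fractions always sum to 1.

## Bioassay analytics

**Imaging.** Background is subtracted first; F₀ is the baseline-epoch mean;
ΔF/F₀ = (max agonist-epoch F − F₀)/F₀. Responder iff ΔF/F₀ ≥ 0.10; a trace
is viable iff its KCl epoch meets the same criterion, and only viable traces
enter group means. Inhibition is reported both as percent-of-control and its
complement, with a 50 % hit threshold and full exclusion accounting
(in = responders + non-responders + non-viable + rejected).

**Patch clamp.** Peaks are signed extrema (inward = negative) within the
commanded step epoch after a 1-ms capacitive-artifact blank (configurable);
densities are peak/capacitance (pA/pF). Step duration comes from the
protocol object, never a constant, because acquisition protocols differ
between experiments (150 vs 200 ms pulses both occur in practice). The
reversal potential for the chord-conductance transform
G(V) = I/(V − V_rev) is estimated per cell by linear extrapolation of the
three most-depolarized I–V points, with an override; the V = V_rev point is
dropped. Gating curves are fit per cell and parameters averaged — not
pooled — matching how mean ± SEM gating shifts are reported.

**Fits.** Boltzmann: y = 1/(1+exp((V½ − V)/k)) (activation) or the
sign-mirrored form (inactivation), k > 0, initialized from the interpolated
half-maximum, trust-region least squares with tight tolerances
(xtol = ftol = gtol = 1e-14) so noiseless synthetic curves are recovered to
better than 1e-6. Hill: y = bottom + (top − bottom)/(1+(IC50/c)^h); by
default top is fixed at 1 (complete block) with bottom free in [0, 0.5];
`fix_top=None` frees the top for data that plateau below complete block, and
`fix_bottom` pins the bottom. **Known behavior:** with the true bottom at 0,
the free-bottom fit's boundary truncation inflates the mean IC50 by ~3–5 %
under noise; Monte-Carlo recovery studies therefore fit the generating model
(bottom pinned), where the engine's relative bias is < 0.2 % at σ = 0.03.
Non-convergence returns a flagged fit with parameters withheld; data
non-monotone beyond a tolerance are flagged, not rejected.

**Behavior and statistics.** AUC is the trapezoidal integral of PWT over the
measurement window (time points sorted first), aggregated as group
mean ± SEM. Group comparisons: unpaired two-tailed t test, one-way ANOVA
with Šidák-adjusted pairwise tests against the control group
(p_adj = 1 − (1 − p)^m), and type-II two-way ANOVA via statsmodels for
treatment × time designs.

## Synthetic data: what it emulates and what it does not

The planted library is an amide coupling of ring-system carboxylic-acid
cores (benzene, naphthalene, thiophene, benzofuran, biphenyl,
benzothiophene as inactives; pyridine, quinoline, pyrimidine as actives)
with systematically generated acyclic primary amines. This gives an exactly
known scaffold partition (each core one scaffold), a planted pharmacophore
(aromatic nitrogen, SMARTS `[n]`) that survives Murcko reduction so round-1
scaffold scoring can see it, and closed-form expected counts
(n_scaffolds × n_per_scaffold). Default 9 × 12; the per-scaffold size is
configurable into the hundreds, the realistic band for screened
sub-libraries. It does **not** emulate reaction failures, regiochemical
ambiguity, tautomers, or the scale (10⁷ molecules) of production libraries —
passing tests demonstrate correctness of the funnel logic, not retrieval
performance against a real docking landscape.

Ephys cells follow I(V) = g·m(V)·(V − V_rev) with Boltzmann m(V), an
(1−e^{−t/τ})³·e^{−t/τ_h} rise/inactivation envelope, per-cell capacitance
~N(15, 2²) pF, and Gaussian current noise — enough structure for peak
detection, the conductance transform and gating fits, but no series
resistance, space clamp or leak artifacts. Imaging traces are square
epoch responses plus noise (no indicator kinetics, bleaching or drift);
behavior series are a triangular reversal transient over an allodynic
floor. Dose tables come directly from the Hill model. Every generator emits
a ground-truth file, and all randomness flows through one explicit
`numpy.random.Generator`.

Problem sizes in the test suite and acceptance script (1008-molecule index
check, 100-seed recall study, 500-rep Monte-Carlo fits, 500 random
geometries) were chosen to make each estimate stable to well within its
assertion margin while keeping the whole suite in seconds on one CPU.

## Limitations

- No docking physics, protein preparation, pose geometry or MD rescoring;
  the scorer contract is deliberately the boundary of the package.
- Scaffold keys follow one convention (isomeric, charge-neutralized,
  exocyclic doubles kept); libraries indexed under another convention will
  partition differently — the options exist but interoperability is the
  user's responsibility.
- The 11-descriptor PCA characterizes a library on its own; comparisons
  against commercial collections require those collections.
- Hill IC50 confidence is summarized by RMSE and convergence flags, not
  profile-likelihood intervals.
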