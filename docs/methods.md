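# Methods

## Glycan representation and canonical form

Glycans are rooted trees: each residue is a glucosyl (or, at the root
only, a glucitol), each bond runs from a child's C1 to its parent's O3
or O6, and each acceptor position holds at most one substituent. The
root is the reducing end; anomeric configuration is uniformly β and is
never branched on. No 3D geometry, no other monosaccharides, no
anomeric mixtures.

Serialization writes residues from the non-reducing end toward the
root, with branches bracketed immediately before their parent
(`Glc(b1-3)[Glc(b1-6)]Glc`) and `-ol` marking a reduced root. The
canonical form places the O3 subtree inline and the O6 subtree in
brackets at every residue, which makes equality a string comparison and
avoids graph-isomorphism machinery; round-tripping
(`parse ∘ serialize = id`) is property-tested over 1000+ random trees
built by an independent slot-attachment constructor.

Masses are additive: DP × anhydrohexose + water (+2.016/+2.0157 for an
alditol root), with average 162.141 / monoisotopic 162.0528 for the
anhydrohexose. The `integer` flavor rounds the average mass to whole
g/mol — the convention of tabulated µg→nmol accounting (180, 342, 504,
1315 for DP 1, 2, 3, 8). Ions are [M+Na]+ monoisotopic centroids only
(Na = 22.9898); no isotope envelopes, adduct series or charge states.
The constants are cross-checked in the tests against molecular-formula
masses (C6nH(10n+2)O(5n+1)) computed with pyteomics.

## Exo-1,3-β-glucanase engine

Removability of a terminal residue requires: leaf status, glucosyl
kind, a β1→3 bond to its parent, and a rootward run of ≥
`min_run_length` (default 3) consecutive β1→3-linked glucosyl residues.
The run terminates at a glucitol or at a β1→6 bond but **passes
through** backbone residues that merely bear a β1→6 branch; residues
carrying a branch are themselves never removable because they are not
leaves. This run rule is the discrete form of "the main chain must
retain two consecutive 1,3-linkages ahead of the scissile bond", and it
is the choice that makes the engine release exactly three glucose units
from a 5+3 hybrid octamer branched at the third backbone position — the
stoichiometry the accounting layer reports. The alternative reading
(terminating the run at branch-bearing residues) yields one glucose per
octamer and was rejected for that reason.

Digestion removes the lexicographically smallest removable terminus per
step until none remains. The final multiset is order-invariant (local
confluence: removing one leaf never disables another), verified by an
exhaustive-order oracle on all structures of DP ≤ 8 used in the tests.
Residue count and water-corrected mass (substrate + n×H2O = products)
are conserved exactly. Step count is the only notion of time — no
kinetics, pH or temperature dependence is modelled; the activity
arithmetic in the quantification module (U/mg, relative activity) is
implemented for data reduction, not simulated.

`scheme_mode` exists because the inferred product table of the hybrid
octamer (3 Glc + LAM2 + branched trimer X) requires one internal
hydrolysis that a strict exo enzyme cannot perform on a connected
substrate: rule derivation leaves a single branched DP-5 residual
(LAM2 core + trimer branch, covalently joined) instead. Both modes are
first-class; the experiment layer always surfaces which convention
produced its numbers. In scheme mode the cleavage count is 4 (five
fragments from one octamer), which closes the mass balance exactly.

## Transglucanase engine

Donors must be linear, all-β1→3, non-reduced, DP ≥ `min_donor_dp`
(default 5 — tetramers and shorter are untouched). The donor is split
after the second glucosyl from the reducing end, releasing LAM2; the
DP−2 fragment attaches via one new β1→6 bond to a backbone O6 of the
acceptor. Hybrids accept but never donate (transfer only ever
lengthens branched products), so exhaustive batches with the
largest-acceptor policy generate the +DP3 ladder: all product DPs lie
in {start + 3k} ∪ {2}.

Attachment models: `near_terminal` restricts the acceptor position to
the three backbone O6 nearest the non-reducing end — the three-isomer
model of the hybrid octamer — with the **innermost** of the three as
the deterministic default, because that geometry reproduces the
observed three-Glc-per-octamer digestion; `all_o6` allows every free
backbone O6. Which hydroxyls are chemically accessible in vivo is
unresolved, so both models are exposed rather than adjudicated.

Batch semantics: one transfer per round. Exhaustive mode picks the
smallest eligible donor and the largest hybrid (else a second donor
molecule) deterministically; stochastic mode samples donor, acceptor
and position abundance-weighted from `numpy.random.default_rng(seed)`
and is bit-reproducible per seed.

## Quantification conventions

µg and nmol are reported at one decimal, percentages as integers; all
internal arithmetic is unrounded. µg→nmol uses integer molar masses by
default (switchable to exact averages). The difference formulas
(hybrid = start − LAM2; X = start − LAM2 − Glc) deliberately neglect
the water incorporated by hydrolysis, as the accounting convention they
reproduce does; the parameter-recovery test therefore targets the
zero-noise inference of the same formulas rather than the molecular
mass of the trimer (which is ~0.4 µg heavier at the tested scale).
Closure — Σ nmol × DP conserved through digestion and transfer — holds
exactly before rounding and is tested.

## Peak prediction and series detection

One peak per distinct (DP, reduction state), intensity proportional to
abundance (base peak 100); isobaric topologies merge into one annotated
peak, as they would in a spectrum. +DP3 series detection is an
exhaustive search for maximal arithmetic runs spaced 486.158 ± tol Da
(default tol 0.5 Da, the external-calibration scale of MALDI-TOF, and
consistent with a printed 1337.5 vs theoretical 1337.42). Runs need ≥ 3
members: two peaks a coincidental three-hexose apart are not evidence
of iterative transfer. Detection ignores intensities and input order.

## Synthetic data

The generator emulates three measurement layers with no downloads:

* **Substrate pools** — nominal LAM5 with a multinomial LAM6
  contaminant fraction (default 0.05; the true contaminant fraction of
  commercial pentamer is unknown, this is a configuration choice).
* **Laminarin ensembles** — chain DP ~ Poisson(25) truncated at ≥ 5,
  each internal residue independently carrying a single-glucose β1→6
  stub with probability 0.07 (switchable to longer branches). This is
  a deliberately minimal parametric model; real laminarin fine
  structure (mannitol caps, intrachain 1,6 segments, branch placement)
  is not represented.
* **Quant tables** — true µg from counts × mole scale × exact average
  mass; measured values are means of three gaussian replicates
  (sd 0.1 µg, truncated at 0, homoscedastic — replicate scatter in the
  data this emulates is small and roughly constant), rounded to one
  decimal with replicate sd alongside. **Peak lists** add gaussian m/z
  jitter (sd 0.05 Da).

All draws flow through one `numpy.random.default_rng(seed)`; fixed
seeds give byte-identical fixture files.

## Numerical and degenerate-input choices

Tie-breaks are canonical-string orderings throughout (removable
termini, donor/acceptor selection), so every deterministic path is
reproducible. Degenerate inputs: DP-1 substrates digest to themselves
with zero cleavages; pools without LAM2 raise on ratio queries rather
than returning infinity; negative difference-formula results raise
accounting errors; empty pools yield empty tables and peak lists.
Problem sizes are desk-scale by construction (pools of hundreds,
oligomers of DP ≤ ~30); the exhaustive-order digestion oracle in the
tests is limited to DP ≤ 12, where full order enumeration is cheap.

## Known limitations

* The scheme/rules tension for the hybrid octamer is intrinsic: no exo
  rule set can emit the inferred LAM2 + branched trimer as separate
  molecules from a connected octamer. The package reports both
  conventions instead of pretending one mechanism covers both.
* In the laminarin ensemble a single 1,6 stub blocks the entire
  rootward backbone, so branched chains leave one large residual each.
  Digesting the default ensemble gives a Glc : branched-residual ratio
  of ≈ 14 (≈ 4.8× the hybrid octamer's 3.0) — the corresponding
  acceptance property asserts ≥ 5× and documents this as a genuine
  shortfall of the single-stub generator, not of the engines. Passing
  tests on this generator show rule behaviour, not fidelity to real
  laminarin fine structure.
* Isomer abundances, enzyme kinetics, subsite energetics and any
  intensity model beyond pool abundance are out of scope.
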