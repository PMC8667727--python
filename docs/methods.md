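# Methods

## Assignment model

The package treats a protein chain as the polygonal curve through its Cα
atoms. Assuming a near-constant virtual bond length (~3.8 Å), the local
shape of the curve is fully described by two discrete order parameters:
the pseudo-bond angle θ_n ∈ (0°, 180°], the angle at Cα_n subtended by its
sequence neighbours (discrete curvature), and the pseudo-torsion
γ_n ∈ (−180°, 180°], the signed dihedral of Cα_{n−1}…Cα_{n+2} (discrete
torsion). γ follows the right-handed sign convention — a canonical
right-handed α-helix sits near γ ≈ +50°, its mirror image near −50° — and
this choice is load-bearing: the helix detection window on γ is one-sided
positive, which is what makes the assignment chirality-aware. The
convention is cross-checked in the tests against MDAnalysis'
`calc_dihedrals`.

A residue is assigned H when it belongs to at least one accepted
4-residue helix window (θ at all four residues in [80°, 105°], the two
inner γ in [30°, 80°]); windows slide with stride 1 and are unioned, so
every H run has ≥ 4 residues. A residue is assigned E when it belongs to
at least one accepted duplet pair: two 2-residue duplets ≥ 4 positions
apart, with θ of all four residues in [100°, 155°], |γ| > 80° at both
duplet starts, and inter-strand distances < 5.5 Å (in-register pairs) and
< 6.8 Å (one diagonal) in either the parallel or the mirrored
antiparallel registration. Everything else is C.

Numerical and tie-break choices:

- Interval bounds are inclusive (θ = 80.0° passes [80, 105]); the γ
  magnitude test and the distance tests are strict, matching their
  "smaller/larger than" phrasing. Inclusive interval bounds are the
  measure-zero-safe reading of "between".
- Helix wins any helix/sheet conflict: sheet detection runs with helix
  residues excluded. The two θ windows overlap only in [100°, 105°], where
  the γ criteria are already disjoint, so exclusion mainly prevents duplet
  ends from straddling helix termini.
- A duplet pair whose geometry satisfies both registrations (possible only
  in contrived inputs) is labelled with the orientation whose two
  in-register distances sum smaller; the rule is isolated in one predicate.
- Degenerate geometry (coincident or collinear points) makes an angle
  undefined, never silently zero; undefined angles fail every window.
- Chain breaks — consecutive Cα–Cα distance outside [2.8, 4.2] Å or an
  author-numbering gap — make every angle whose atom span crosses the
  break undefined, so no window or duplet is ever evaluated across a break.
  Inter-residue *distances* remain available across breaks, which is what
  lets a two-chain parallel strand pair be analysed as one concatenated
  trace with an explicit break at the junction.
- Residues 1 and N can never be H or E (their angles do not exist), and a
  helix can only be observed from residue 2 of a geometric helix onward;
  segment termini are therefore structurally undetectable, which the
  recovery metrics below account for.

The minimal sizes (helix ≥ 4, strand ≥ 2, sheet ≥ 4 residues) are
structural consequences of the window/duplet mechanism rather than
post-filters; 3₁₀-helix fragments shorter than the window and isolated
β-bridges are deliberately not assigned.

## Parameters

All detection parameters live in `CutabiParams` (angles in degrees,
distances in Å): helix θ window [80, 105], helix γ window [30, 80], sheet
θ window [100, 155], sheet |γ| floor 80, in-register distance cap 5.5,
diagonal cap 6.8, minimal helix length 4, minimal strand length 2, minimal
sequence separation between duplet starts 4. The separation of 4 is the
smallest value that prevents a hairpin turn from pairing with itself.
Every field can be overridden per call or via a JSON/TOML file on the CLI.

The Flory coil reference Rg = 0.367·b·N^ν defaults to b = 7.6 Å (twice
the Cα–Cα distance, the conventional statistical segment for proteins)
and ν = 3/5 (the good-solvent exponent); ν is a parameter, not a
constant. The inter-region contact counter defaults to an 8 Å Cα–Cα
cutoff, a common coarse-grained contact definition; it is likewise a
parameter. The monomer filter for two-chain frames retains a frame only
when no cross-chain Cα pair is closer than 20 Å.

## Ensemble analytics

Each frame is reduced to (α, β) — H and E counts inside an analysis
region, default positions 1–95 (the N-terminal plus NAC regions of
α-synuclein, the region where sequence variants differ; always
overridable) — plus the full-chain radius of gyration. Frames with α = 0
form the B state, all others the HB state. P(α, β) is a plain normalised
count map on the integer grid (1-residue cells, no smoothing). The
free-energy cutoff is ΔF = ln(P_max_B / P) in kT units with P_max_B the
maximum of the α = 0 column; the printed form of this quantity is
sometimes typeset with the fraction inverted, but the positive-axis
convention used here is the standard free-energy difference from the
B-state mode. An HB cell more probable than the B-state mode gets ΔF < 0
and is included from its (negative) cutoff onward, with the default grid
extended below zero when needed. Temperature never enters; everything is
in kT.

## What the synthetic generators emulate

Generators produce Cα geometry with ground-truth labels, standing in for
MD trajectory frames:

- `build_helix`: right-handed circular helix, rise 1.5 Å, radius 2.3 Å,
  twist 100°/residue — canonical α-helix Cα geometry (θ ≈ 90.4°,
  γ ≈ +50°, bond ≈ 3.83 Å), comfortably inside the detection windows and
  parameterised so boundary tests can push θ/γ to the window edges.
- `build_hairpin`: two pleated strands (bond 3.8 Å, pleat amplitude set
  for θ ≈ 125°, γ = ±180°) in register at 4.8 Å separation; antiparallel
  as one chain with a 2-residue turn, parallel as a two-chain pair.
- `build_coil`: fixed-bond self-avoiding random walk grown by per-step
  rejection (non-adjacent clash floor 4 Å). Kinetic growth does not
  sample the equilibrium self-avoiding ensemble: at n = 140 its mean Rg
  is ≈ 29 Å, a factor ≈ 1.9 below the good-solvent Flory reference of
  54 Å, and the tests freeze that measured ratio rather than the
  asymptotic SAW amplitude. Real denatured-protein ensembles are more
  expanded than this walk; conclusions about absolute coil dimensions
  should not be read off the fixture.
- `build_chimera` / `build_ensemble`: segments placed rigidly end-to-end
  with clash-free random linkage, optional isotropic per-coordinate
  Gaussian noise (no bond renormalisation afterwards), labels
  concatenated; ensembles draw plans from a weighted mixture, all frames
  equal length.

What passing tests on these fixtures show — and do not show: the fixtures
exercise the geometric rules exactly (ideal and noisy windows, registration,
chirality, breaks), but they contain no physics, no realistic
Ramachandran statistics, no bent sheets or kinked helices, and no
correlated thermal motion. Agreement numbers on fixtures are therefore
upper bounds on what to expect for experimental structures or MD frames.

## Noise robustness: a quantified limitation

Per-coordinate Gaussian noise of σ propagates to the pseudo-bond angle
with sd ≈ 2σ/b rad (b = 3.8 Å): 3° at σ = 0.1 Å but 8.9° at σ = 0.3 Å.
The helix θ window leaves only ~10.4° of margin below the ideal 90.4°, so
at σ = 0.3 Å about 18% of individual θ values leave the window, an
all-or-nothing 4-angle window then fails more than half the time, and
helix-class interior recovery drops to ≈ 66% (overall interior recovery
≈ 78% on the mixed fixture; strand and coil classes stay above 90%).
Recovery is ≈ 100% noise-free and ≥ 95% at σ = 0.1 Å. The corresponding
acceptance test asserts an 85% target at σ = 0.3 Å and fails; it is left
failing deliberately, as the measured behaviour of the window rule under
that noise model. Interior residues are defined as those ≥ 2 positions
from any ground-truth segment boundary, since segment ends are
structurally undetectable (see above).

## Benchmarking conventions

DSSP's alphabet is collapsed to three classes — helix {H, G, I}, sheet
{E}, other (including B, the isolated bridge, which this method does not
emit). Per-class discrepancy between two assignments is normalised by the
full sequence length, so "5% sheet difference" means 5% of all residues.
Reference labels for the synthetic benchmark are derived from generator
ground truth by trimming one residue from each end of every helix run,
mirroring the n→n+4 hydrogen-bond pattern that leaves helix termini
unassigned in hydrogen-bond-based methods. Structure-vs-DSSP comparison
aligns residues by (chain, author number, insertion code), never
positionally. The default discrepancy histogram edges are
{0, 5, 15, 35, 100}%.

## Problem sizes

The shipped tests and the reproduction script use: a 24-structure
benchmark fleet (2–3 structured blocks per chain, helices 10–24 residues,
strands 5–8, coils 6–15), 200 random traces of ≤ 30 residues for the
brute-force equivalence check, 1,000 random rigid motions for invariance,
500 random chimeras for the minimal-size guarantees, a 10⁴-frame
mixture ensemble (32-residue frames, 70% zero-helix plans) for the
B-state recovery, and 50 chimeras per noise level for label recovery.
These sizes give binomial standard errors well below the asserted margins
while keeping a full run in the tens of seconds.

## Known limitations

- Helix subtypes (3₁₀, π), turns, bends and β-bridges are out of scope by
  design; comparisons against eight-state references must collapse classes.
- Sheet merging is union-based; bifurcated sheets are represented only
  through the pair list, and a strand segment reports a single partner
  (the first pair touching it).
- The assignment is exactly rigid-motion invariant but, by construction,
  not mirror invariant for helices (chirality is a feature, not a bug).
- Author residue numbering is metadata only; all windows are positional.
- The two-chain parallel fixture relies on distances being defined across
  chain breaks in a concatenated trace; multi-chain complexes beyond two
  chains are not modelled.
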