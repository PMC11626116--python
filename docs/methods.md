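# Methods

## Model

The Gaussian Network Model treats a protein as an elastic network of Cα
nodes: residues *i*, *j* are linked by a spring of uniform constant γ
whenever their Cα–Cα distance is at most a cutoff *r*<sub>c</sub>. The
Kirchhoff matrix Γ (off-diagonal −γ for contacts, diagonal the contact
count, rows summing to zero) is the graph Laplacian of the contact
network. Residue fluctuations decompose over its nonzero eigenmodes with
amplitudes ∝ 1/λ; the lowest-λ ("slow", "global") modes are the most
cooperative motions. A mode *profile* is the per-residue signed component
of a unit-norm eigenvector.

Assumptions inherited from the GNM: isotropic Gaussian fluctuations,
uniform springs (γ = 1 — only relative mode shapes matter here), no
directionality (for directions one would need an anisotropic model, which
is out of scope), first model only for multi-model files, and one network
over all chains of an assembly so that inter-chain contacts shape the
modes of dimers.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `gnm.cutoff` | 10.0 | Å (Cα–Cα) | standard GNM contact radius |
| `gnm.sigma_min` | 1/3 | — | minimum cumulative variance of the kept modes |
| `gnm.k_max` | 3 | modes | hinge analysis is a slow-mode concept; beyond mode 3 profiles fragment |
| `hinge.terminal_exclusion` | max(5, 4% of chain) | residues | terminal crossovers dissipate locally; scale-aware default |
| `hinge.rigid_block_min_len` | 20 | residues | a "long" low-mobility stretch, ≈ half a small subdomain |
| `hinge.delta_scale` | 0.5 | × RMS of profile | low-amplitude threshold δ; scale-free because profiles are unit-norm |
| `hinge.extension_span` | 2 | residues/side | hinge sites span short runs of consecutive residues |
| `binding.cutoff` | 4.5 | Å heavy-atom | common non-covalent contact criterion |
| `binding.min_frequency` | 0.10 | fraction | "consistent" coordination across drug-bound members without admitting one-off poses |
| ensemble small profile | identity > 85%, z > 10, RMSD < 2 Å | | for references with N ≤ 550 |
| ensemble large profile | identity > 25%, RMSD unbounded, z > 10 | | see "Open design points" |

The hinge-filter defaults are this repository's calibration, chosen once
from the physical arguments above; they are not published values.

## Procedure

**Mode selection.** k is the smallest mode count whose cumulative variance
reaches `sigma_min`, capped at `k_max` (cap binding is logged). Degenerate
eigenvalues are kept in ascending order as returned by the symmetric
eigensolver; each eigenvector's sign is fixed so its largest-magnitude
component is positive, making single-structure output deterministic.

**Crossover rule.** For every consecutive same-chain residue pair with
strictly opposite profile signs, both residues are candidates; exact zeros
whose nearest nonzero neighbours disagree in sign are candidates as well.
Chain boundaries never produce crossovers.

**Filters**, in order: (a) candidates within the terminal margin of their
chain are dropped; (b) maximal same-chain runs of ≥ `rigid_block_min_len`
residues with |value| < δ are rigid blocks — candidates strictly interior
are dropped, block-boundary residues are kept, and a crossover partner
immediately *outside* a block collapses onto the boundary residue (the
boundary is the flex point; the outside partner belongs to the moving
lobe); (c) residues contiguous with a surviving crossover and with
|value| < δ are annexed, up to `extension_span` per side. Filters only
remove or locally extend: no hinge is created farther than
`extension_span` residues from a crossover.

**Mode matching.** For an ensemble, each member's 2k slowest modes are
compared to the k reference modes by the normalized inner product over
mapped positions; assignment is one-to-one, greedy by descending |overlap|
with ties broken toward the lower member mode index, and the member
eigenvector is sign-flipped to make the product positive. Members mapping
< 50% of the reference are skipped with a warning. The signature profile
is the position-wise mean and population SD of the matched, sign-aligned,
mapped components; hinges are called on the mean profile (per-member
hinge calls remain available as a diagnostic).

**Residue mapping.** An external alignment can be supplied; otherwise a
global sequence alignment (match 1, mismatch −1, gap open −10, extend
−0.5) maps member residues to reference numbering. This is a sequence
stand-in for the structural alignments typically used to assemble such
ensembles; it is reliable at the high identities the small-protein filter
enforces and should be replaced by a supplied structural alignment for
diverse ensembles.

**Statistics.** The hypergeometric tail is evaluated through the library
survival function (log-space internally), accurate to 3 significant
figures down to ~1e-12. Enrichment conventions: e = 0 when s = 0, +∞ when
s = h; undefined (an error) when h = 0 or b = 0. Per-family P values are
reported raw — no multiple-testing correction, since families are
interpreted individually. Aggregation over families is a plain arithmetic
mean with sample SD and an optional exclusion list (leave-one-out style);
a geometric-mean alternative exists but is off by default.

## Synthetic fixtures

`synthetic.make_dumbbell` builds two compact domains (serpentine cubic
lattice, 3.8 Å spacing, so every bead has well over 3 contact neighbours
at the 10 Å cutoff) joined by a straight extended linker. The slowest mode
of this geometry is the anticorrelated rigid-body motion of the two
domains with its single sign crossover inside the linker — the planted
hinge. A decoy drug is planted by placing one ligand atom 3.8 Å from each
pocket residue's Cα (pocket defaults to the interior linker residues),
which by construction is 3.5–4.0 Å from its own residue and > 4.5 Å from
every other residue, so contact detection at the default cutoff recovers
the pocket exactly at zero jitter. Ensembles are independent per-atom
Gaussian jitters of the base geometry (member i uses seed + i) with the
drug present in a chosen fraction of members.

What the fixtures do *not* emulate: real side-chain packing and chemistry,
sequence variation across homologs (members are identical in sequence),
insertions/deletions, crystallographic disorder, and multi-chain
assemblies. Passing the planted-recovery tests therefore demonstrates the
pipeline's mechanics — mode computation, crossover logic, consolidation,
bookkeeping — not predictive performance on real proteins.

## Numerical choices

* Zero-mode tolerance: eigenvalues ≤ 1e-8 × the largest are zero; more
  than one ⇒ disconnected contact graph, reported with its components.
* Kabsch superposition restricted to proper rotations; the residual is
  recomputed explicitly after rotation because the solver's reported
  residual loses precision near zero.
* Altloc resolution: per atom name, highest occupancy, ties to file order.
* Population (ddof = 0) SD in signature profiles — the ensemble is the
  whole population of interest, and a two-member ensemble with aligned
  values ±a then reports SD = a.
* Contact test uses ≤ (cutoff-inclusive) semantics.
* Problem sizes in tests and the acceptance script (86-residue dumbbells,
  ensembles of 10–20 members, 40 recovery seeds, 100,000 permutation
  draws) were chosen to exercise every code path at desk scale.

## Open design points

* The published membership criteria for large proteins state "RMSD > 1 Å"
  while the accompanying results describe *relaxing* the RMSD bound
  (ensembles averaging up to ~9.8 Å RMSD); the criterion as printed is
  most likely a typo. Both lower and upper bounds on identity and RMSD
  are therefore exposed in config, and the large-protein default is
  permissive (identity > 25%, RMSD unbounded).
* Whether a hinge "site" is the crossover pair only, or a short band of
  near-zero residues, is resolved here as: the pair, plus up to
  `extension_span` annexed low-amplitude neighbours per side.
* The minimum structure size for GNM analysis is set at 10 residues;
  below that the contact graph is too small for a meaningful slow mode.

## Limitations

GNM hinges are sequence-agnostic: the model sees only Cα topology, so
residue chemistry at a predicted hinge is not assessed. Drug status of a
ligand is an input flag (an allow-list of het codes), not a database
lookup. Structure-database searches, biological-assembly reconstruction
and binding-affinity estimation are out of scope.
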