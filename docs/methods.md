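# Methods

## Scope and model

The package decomposes a two-chain protein–protein interface into
per-residue-pair interaction energies with the molecular fractionation with
conjugated caps (MFCC) scheme, detects the geometric contacts that mediate
the interface, selects representative conformations from an ensemble, and
derives mimetic peptides from the energetically dominant regions.  It was
built around antibody::epitope interfaces — the shipped defaults name the
aducanumab CDRs (HCDR2: heavy chain 50–60, HCDR3: 101–109, LCDR3: light
chain 90–96) and the Aβ2–7 epitope — but every threshold and region is
configurable.

## Coordinate model

Structures are ordered residue lists keyed by chain ID, author sequence
number, insertion code and residue name.  Author numbering is the only
coordinate system: results in this field are reported against
crystallographic numbers (VAL50, SER91, …), so renumbering would only
obscure.  Altloc ensembles collapse to the highest-occupancy conformer;
hydrogens are used when present and never generated (protonation is treated
as an upstream preparation step).  Multi-model PDB files stand in for MD
trajectories; no binary trajectory formats are supported in v1.

## Contact criteria

Hydrogen bonds follow the distance-only LigPlot+/HBPLUS convention:
H···acceptor ≤ 2.70 Å **and** donor···acceptor ≤ 3.35 Å, with donors and
acceptors drawn from fixed chemistry tables (N/O/S donors bearing a
hydrogen within 1.3 Å; N/O acceptors; His is both).  No angular criterion
is applied — the convention these cutoffs come from is distance-driven, and
adding angles would change counts silently.  A `heavy_only` mode applies
the donor–acceptor criterion alone for proton-free structures.  Hydrophobic
contacts are apolar-carbon pairs (carbons not bonded to N/O, from a
per-residue table) within [2.90, 3.90] Å.  Salt bridges — for which no
standard criterion exists — default to 4.0 Å between Asp/Glu carboxylate
oxygens and Lys/Arg/His basic nitrogens, configurable.  Comparisons carry a
1e-9 Å guard so that a distance exactly at a criterion qualifies regardless
of floating-point representation.  One record is emitted per qualifying
atom pair; `collapse_residues` reduces to one per residue pair.

## The MFCC scheme

For a cross-chain pair (Ri, Rj), four capped systems are built: caps are
the single covalently adjacent residues (C<sub>i±1</sub>), kept with full
side chains; every cut backbone bond receives a fill hydrogen at 1.09 Å
along the former bond vector.  A residue at a chain terminus keeps its one
existing cap.  The pair energy is E(S1) − E(S2) − E(S3) + E(S4).  Pairs are
enumerated by minimum heavy-atom distance with an 8.0 Å default cutoff.
Explicit waters within a shell (2.5 Å default when enabled) attach to the
nearer core residue (ties to Ri) and travel with it, i.e. they appear in
the subsystems that contain that core.

Backends:

* **classical** — Coulomb with a distance-independent dielectric (default
  ε = 40, representing the screened electrostatics of a solvated
  protein–protein interface) plus 12-6 Lennard-Jones with per-element
  parameters; partial charges from a coarse per-residue table (formal
  charges on titratable groups, small backbone dipoles), overridable per
  atom.  The total energy of a system is the sum over all unordered atom
  pairs with no bonded exclusions — strictly pairwise additive by
  construction.  Fill hydrogens are inert (zero charge, zero LJ depth);
  this is what makes the four-term combination *exactly* equal to the
  direct Ri::Rj cross-term, because the inner fill hydrogens of caps-only
  subsystems have no counterpart in S1 and would otherwise leave a
  residual.  The backend is a desk-scale stand-in that preserves every
  structural aspect of the scheme; it makes no claim to force-field
  accuracy.
* **table** — ingests a CSV of per-subsystem energies (pair_id, subsystem,
  energy_kcal_mol) computed by an external engine and combines them.
* **export** — writes the four capped systems per pair as PDB or XYZ for an
  external quantum engine.  It produces files, not numbers, so it is not
  accepted by `pair_energy` (an interaction record requires a finite
  energy); use `export_subsystems`/`interface_export`.

## Hot-spot aggregation

Per-residue totals are sums of a residue's pair energies; region totals sum
member residues, with everything else under "other".  Fractions use the
grand total including repulsive contributions as denominator (configurable
by passing a different total).  The cumulative profile sums pair energies
with pair distance ≤ r over a 0–8 Å grid (0.25 Å steps); its endpoint
equals the interface total by construction.  Rankings sort ascending in
energy (most attractive first) with ties broken by chain and residue
number.

## Ensemble descriptors and representatives

Superposition is the Kabsch SVD fit with reflection rejection (det +1
enforced).  RMSF superposes all frames to the ensemble mean (two passes:
fit to frame 0, average, refit) and reports per-residue root-mean-square
fluctuation over the selected atoms.  Featurization emits backbone φ/ψ as
sin/cos pairs (interior residues only) plus Cα–Cα distances for all
selected residue pairs, in a documented, stable column order.

Representative selection fits Gaussian mixtures (full covariance, 10
restarts, fixed seed) for each k in a range (default 2–10), scores each
labelling with the mean silhouette, and picks the argmax with ties to the
smaller k.  The representative of a cluster is the frame nearest its
mixture mean in the clustering space — the cluster "hub".  Dimensionality
reduction (UMAP, seeded) is available behind a flag but off by default:
clustering raw features is reproducible across library versions, whereas
the embedding's geometry is seed- and implementation-sensitive.  An
all-identical-frames input returns a single cluster with a warning.

## Peptide panel conventions

The panel deliberately matches the conventions of the standard web
calculators so values are comparable with published tables:

* **Molecular weight**: ExPASy average residue masses plus one water;
  cyclic (disulfide-closed) peptides are reported on the linear chain
  without the −2H correction, matching common practice of computing the
  panel on the sequence.
* **pI**: bisection root of the Henderson–Hasselbalch net charge with the
  Bjellqvist pKa set, including residue-specific N-terminal (A 7.59, M 7.0,
  S 6.93, P 8.36, T 6.82, V 7.44, E 7.7; default 7.5) and C-terminal
  (D 4.55, E 4.75; default 3.55) values; side chains K 10.0, R 12.0,
  H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0.  Bisection on [0, 14] to 5e-4 pH.
* **Net charge**: the integer (#K + #R) − (#D + #E), His and termini
  excluded — the antimicrobial-peptide-database convention for a charge at
  neutral pH.
* **Cleavage sites**: PeptideCutter position-specific rules.  Trypsin
  (after K/R, not before P, with the WKP/MRP pro-cleavage and
  CKD/DKD/CKH/CKY/CRK/RRH/RRR blocking exceptions), chymotrypsin high
  (F/Y/W) and low (F/L/Y/W/M/H) specificity with their P1′ exceptions, and
  the pepsin pH 1.3 / pH > 2 two-clause window matrices over P3..P2′.
  Boundary convention: a window position outside the sequence satisfies
  negative ("not in") constraints and fails positive ("in") ones, and the
  bond after the terminal residue counts as a site (`terminal_counting`,
  default on).  This convention reproduces published susceptibility counts
  for short peptides; it can be disabled for protein-interior semantics.

## Synthetic data

The generators define the study conditions for everything not derivable
from a public structure:

* **Toy complexes**: two chains of ideal extended backbone (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å; φ = ψ = ω = 180°; natural-extension internal
  coordinates), default 10 Å apart.  A planted contact places the two
  defining side-chain atoms (ASP OD1 ↔ SER OG + HG for hydrogen bonds,
  ALA CB pairs for hydrophobic, GLU OE1 ↔ LYS NZ for salt bridges) on the
  Cα–Cα axis, centred midway between the backbones, at exactly the target
  distance; each residue may host at most one planted contact.  Non-contact
  residues are glycine so nothing else crosses the criteria.  The ground
  truth carries the planted contact list and the direct classical pair
  energy of every cross-chain residue pair.
* **Conformer ensembles**: frames = base + per-mode displacement of the
  trailing half of the first chain + iid Gaussian coordinate noise
  (default σ = 0.1 Å, 3 modes, 15–20 frames per mode).  Default mode
  vectors slide the displaced block along the chain axis in steps of
  max(1 Å, 6σ), so modes differ in internal distances to first order and
  the > 5σ separation guarantee is meaningful in feature space.  True mode
  labels are returned for recovery scoring.
* **Point mutants**: side chains are replaced by idealized "stick"
  templates along the Cβ direction — approximate geometry, exact sequence;
  backbone atoms never move.

What the generators do **not** emulate: real rotamer packing, backbone
relaxation around mutations, solvent structure, or the thermodynamics of
conformer populations.  Passing tests therefore demonstrate the
correctness of the algorithms (detection, decomposition, selection,
design) under controlled truth, not the accuracy of the classical backend
on real interfaces — quantitative energetics on real systems require the
table backend fed by a quantum engine.

## Problem sizes and numerics

The shipped analyses and tests run on 8-residue chains (≈70 atoms),
45-frame ensembles and 100 randomized 3–5-residue toys; these sizes give
sub-second to few-second stages while exercising every code path,
including a 4-point brute-force rotation-grid oracle for the Kabsch fit.
The MFCC additivity identity holds to ~1e-10 kcal/mol (float64 subtraction
of near-cancelling subsystem totals); tests assert 1e-9.  Degenerate
inputs are defined: empty interfaces give empty lists and zero totals,
zero enumeration cutoff gives no pairs, single-frame RMSF is zero with a
warning, zero-total fractions raise.

## Known limitations

* No angular hydrogen-bond term; no π-stacking, cation–π or water-mediated
  bridges.
* The classical backend's charges/LJ are coarse by design; sign and rough
  magnitude only.
* Cap width is fixed at one residue (the conjugated-cap notation of the
  scheme); wider caps are not implemented.
* mmCIF and binary trajectory formats are unsupported; PDB only.
* The pepsin matrices pin the published rule tables, but terminal-window
  edge cases beyond the calibrated short-peptide set are convention, not
  ground truth.
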