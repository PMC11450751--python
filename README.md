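# epitope-decomp

Residue-level energy decomposition of an antibody::epitope interface, and
design of mimetic peptides from its energetic hot spots.

The package targets the kind of question raised by aducanumab binding the
amyloid-β N-terminus (Aβ residues 2–7): *which antibody residues actually
hold the epitope, and can short peptides mimic them?*  It implements the
full desk-side workflow around that question:

1. **Structures** — PDB reading/writing, residue selection by author
   numbering, minimum-distance geometry.
2. **Contacts** — hydrogen bonds (H···A ≤ 2.70 Å and donor···acceptor
   ≤ 3.35 Å), hydrophobic apolar-carbon contacts (2.90–3.90 Å) and salt
   bridges (≤ 4.0 Å), plus conservation counting across conformations.
3. **MFCC energy decomposition** — the molecular fractionation with
   conjugated caps scheme.  For residues Ri, Rj on different chains,

   E(Ri::Rj) = E(C<sub>i−1</sub>R<sub>i</sub>C<sub>i+1</sub> + C<sub>j−1</sub>R<sub>j</sub>C<sub>j+1</sub>)
   − E(C<sub>i−1</sub>R<sub>i</sub>C<sub>i+1</sub> + C<sub>j−1</sub>C<sub>j+1</sub>)
   − E(C<sub>i−1</sub>C<sub>i+1</sub> + C<sub>j−1</sub>R<sub>j</sub>C<sub>j+1</sub>)
   + E(C<sub>i−1</sub>C<sub>i+1</sub> + C<sub>j−1</sub>C<sub>j+1</sub>),

   where C<sub>i±1</sub> are single-residue conjugated caps and every cut
   bond is saturated with a fill hydrogen.  Energy backends are pluggable:
   a classical Coulomb (screened, ε = 40 by default) + Lennard-Jones
   backend, a table backend for externally computed (e.g. DFT) subsystem
   energies, and a subsystem exporter (PDB/XYZ) feeding external engines.
4. **Hot-spot profiles** — per-residue and per-CDR energy sums, fractional
   contributions, cumulative energy–distance profiles, rankings.
5. **Ensembles** — Kabsch superposition, RMSD/RMSF, dihedral + distance
   featurization, Gaussian-mixture clustering with silhouette model
   selection, hub (representative-frame) extraction.
6. **Peptide design** — CDR segment extraction, point mutation, disulfide
   cyclization, and a sequence-based panel: average molecular weight,
   isoelectric point (Bjellqvist/ProtParam bisection), integer net charge,
   and protease cleavage-site counts (PeptideCutter rules for trypsin,
   chymotrypsin high/low specificity, pepsin at pH 1.3 and pH > 2).
7. **Synthetic fixtures** — toy complexes with planted contact geometries
   and an exactly pairwise-additive energy truth table, planted-mode
   conformer ensembles, idealized point mutants.  Everything is testable
   without downloads.

## Worked example

```python
from epitope_decomp import (
    PlantedContact, ToyComplexSpec, make_toy_complex,
    interface_energies, total_energy, detect_hbonds,
    PeptideRecord, cyclize, design_report,
)

spec = ToyComplexSpec(
    n_res_per_chain=8,
    planted_contacts=(PlantedContact("hbond", 2, 2, 2.90),),
)
structure, truth = make_toy_complex(spec)
print(detect_hbonds(structure, (["A"], ["B"]))[0])
# hbond: B:SER2(OG)::A:ASP2(OD1) d=2.90

records = interface_energies(structure, ["A"], ["B"], truth.backend, cutoff=8.0)
print(f"{len(records)} pairs, total {total_energy(records):+.4f} kcal/mol")
# 22 pairs, total +0.6499 kcal/mol   (classical backend, eps=40)

pep = PeptideRecord("Pep-L3-L1", "QSYSTPL")        # light-chain CDR3 segment
print(design_report([pep, cyclize(pep, "Pep-L3-C1")])
      [["name", "sequence", "mw", "pi", "net_charge"]].to_string(index=False))
#      name  sequence      mw   pi  net_charge
# Pep-L3-L1   QSYSTPL  794.86 5.52           0
# Pep-L3-C1 CQSYSTPLC 1001.14 5.51           0
```

The MW/pI values match the ProtParam convention; the net charge is the
simple K/R vs D/E count at neutral pH.

## Analysis scripts

`analysis/01_simulate_complex.py` … `06_design_peptides.py` run the whole
workflow on the synthetic study system and write tables under `results/`:
planted-contact recovery, the additivity check of the four-term
decomposition (max deviation ~1e-10 kcal/mol), silhouette selection of the
planted k = 3 conformer modes (adjusted Rand index 1.0 versus truth),
hot-spot rankings/CDR sums, and the eight-peptide design panel.

A CLI mirrors the stages: `epitope-decomp simulate|select|contacts|mfcc|
hotspots|ensemble|peptides|run` (see `--help`).

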