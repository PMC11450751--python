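"""Design the mimetic peptides and compute their physicochemical panel.

The linear peptides are the CDR hot-spot segments (H2: heavy chain 50-60,
H3: heavy chain 101-109, L3: light chain 90-96, and the S91Y mutant of L3);
cyclic variants add terminal cysteines for a disulfide.  The script derives
the sequences from a CDR-carrying synthetic chain, confirms they match the
published segments, and reports molecular weight, pI, net charge and
protease cleavage-site counts per peptide.

Writes: results/peptide_report.csv
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import MIMETIC_PEPTIDES, RESULTS  # noqa: E402

from epitope_decomp import (  # noqa: E402
    PeptideRecord,
    RegionDef,
    cyclize,
    design_report,
    extract_segment,
    mutate,
)
from epitope_decomp.chemistry import ONE_TO_THREE  # noqa: E402
from epitope_decomp.structures import Structure  # noqa: E402
from epitope_decomp.synthetic import build_ideal_chain  # noqa: E402


def _cdr_chains() -> Structure:
    """Synthetic chains carrying the antibody CDR sequences at the
    crystallographic author numbers."""
    h = ["GLY"] * 120
    for i, letter in enumerate("VIWFDGTKKYY"):
        h[49 + i] = ONE_TO_THREE[letter]
    for i, letter in enumerate("GIGARRGPY"):
        h[100 + i] = ONE_TO_THREE[letter]
    l = ["GLY"] * 100
    for i, letter in enumerate("QSYSTPL"):
        l[89 + i] = ONE_TO_THREE[letter]
    return Structure(build_ideal_chain("H", h)
                     + build_ideal_chain("L", l, origin=(0.0, 30.0, 0.0)))


def main() -> None:
    structure = _cdr_chains()
    h2 = extract_segment(structure, RegionDef("H2", "H", ((50, 60),)),
                         name="Pep-H2-L")
    h3 = extract_segment(structure, RegionDef("H3", "H", ((101, 109),)),
                         name="Pep-H3-L")
    l3 = extract_segment(structure, RegionDef("L3", "L", ((90, 96),)),
                         name="Pep-L3-L1")
    l3_mut = mutate(l3, 91, "Y")
    peptides = [
        h2, cyclize(h2, "Pep-H2-C"),
        h3, cyclize(h3, "Pep-H3-C"),
        l3, cyclize(l3, "Pep-L3-C1"),
        PeptideRecord("Pep-L3-L2", l3_mut.sequence, mutations=l3_mut.mutations),
        cyclize(l3_mut, "Pep-L3-C2"),
    ]
    order = ["Pep-H2-L", "Pep-H2-C", "Pep-H3-L", "Pep-H3-C",
             "Pep-L3-L1", "Pep-L3-C1", "Pep-L3-L2", "Pep-L3-C2"]
    peptides.sort(key=lambda p: order.index(p.name))
    for pep in peptides:
        assert pep.sequence == MIMETIC_PEPTIDES[pep.name], pep.name

    frame = design_report(peptides)
    frame.to_csv(RESULTS / "peptide_report.csv", index=False)
    with_cols = frame[["name", "sequence", "mw", "pi", "net_charge",
                       "sites_trypsin", "sites_chymotrypsin_high",
                       "sites_pepsin_1.3"]]
    print(with_cols.to_string(index=False))


if __name__ == "__main__":
    main()
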