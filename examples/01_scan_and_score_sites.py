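"""Scan a 3'UTR for relaxed-seed target sites and score their energies.

A candidate site is any perfect Watson-Crick 4-mer match to the miRNA
seed region (positions 2-8) — no 6/7/8-mer seed requirement.  Each site
gets three energies: dG_H (hybridization of the duplex), dG_open
(cost of opening the local mRNA structure, always <= 0) and their
difference ddG = dG_H - dG_open.  Lower ddG = energetically better
target.  Overlapping 4-mer nuclei collapse to the best-ddG site.
"""

from mirthermo import MiRNA, UtrRecord, score_sites
from mirthermo.thermo import ThermoEngineConfig, ViennaEngine

mirna = MiRNA(id="mir-ex", sequence="UGGAAUGUAAAGAAGUAUGUAU")
# one perfect 8mer target (ACAUUCCA) placed in an accessible AU-rich stretch
utr = UtrRecord(
    id="gene-1",
    sequence="GCUAGCUAGCAUGCAUGGCAUA" + "A" * 20 + "ACAUUCCA" + "U" * 20 + "GCGCAUGGC",
)

engine = ViennaEngine()  # swap in ToyEngine() for a folding-free dry run
config = ThermoEngineConfig()  # W=80, L=40, u=20, 37 degC

sites = score_sites(mirna, utr, engine, config)
print(f"{len(sites)} site(s) after overlap resolution\n")
print(f"{'utr_start':>9} {'seed_type':>9} {'dG_H':>8} {'dG_open':>8} {'ddG':>8}")
for s in sites:
    print(
        f"{s.match.utr_start:>9} {s.seed_type.label:>9} "
        f"{s.dG_H:>8.2f} {s.dG_open:>8.2f} {s.ddG:>8.2f}"
    )
print(
    "\nddG is the overall favorability of stepwise duplex formation "
    "(kcal/mol); the 8mer in open context should dominate."
)
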