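"""Site accessibility: the same seed match costs more inside a hairpin.

The stepwise duplex-formation model says a target site must first open
its local secondary structure (dG_open = RT ln P_unpaired over sliding
20-nt windows in 80-nt local folds).  Planting an identical 8mer match
in an unstructured context versus inside a designed hairpin stem
isolates that term: hybridization is the same, accessibility is not.
"""

from mirthermo import MiRNA, UtrRecord, score_sites
from mirthermo.seq_io import reverse_complement
from mirthermo.thermo import ThermoEngineConfig, ViennaEngine

mirna = MiRNA(id="mir-ex", sequence="UGGAAUGUAAAGAAGUAUGUAU")
target = reverse_complement(mirna.sequence[:8])  # the 8mer site: ACAUUCCA

open_utr = UtrRecord(id="open", sequence="A" * 40 + target + "A" * 40)
stem = reverse_complement(target)  # pairs with the site -> hairpin stem
hairpin_utr = UtrRecord(id="stem", sequence="A" * 34 + stem + "AAAAAA" + target + "A" * 40)

engine = ViennaEngine()
config = ThermoEngineConfig()

for utr in (open_utr, hairpin_utr):
    best = min(score_sites(mirna, utr, engine, config), key=lambda s: s.ddG)
    print(
        f"{utr.id:>5} context: dG_H {best.dG_H:7.2f}  dG_open {best.dG_open:7.2f}  "
        f"ddG {best.ddG:7.2f} kcal/mol"
    )
print(
    "\nSame duplex, but the hairpin buries the site: dG_open is far more "
    "negative, so ddG (= dG_H - dG_open) is worse. Accessible sites win."
)
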