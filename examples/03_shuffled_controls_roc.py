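"""Shuffled-miRNA controls and the site-level ROC.

Real negatives are scarce, so the null is built from dinucleotide-
shuffled miRNAs (composition-preserving first-order Markov walk, 85%
first-order rule, seed-collision filter) scanned against randomly
assigned UTRs, one randomly chosen control site per pair.  ddG at
strong-seed sites is then compared to control-site ddG by ROC/AUC and
a Wilcoxon rank-sum test.
"""

import numpy as np

from mirthermo import rank_sum_test, roc_auc, sample_control_site, score_sites
from mirthermo.controls import ShuffleConfig, generate_control_pairs
from mirthermo.fixtures import SyntheticSpec, synthetic_cohort
from mirthermo.site_scan import FILTER_LEVELS
from mirthermo.thermo import ThermoEngineConfig, ToyEngine

engine = ToyEngine(unpaired_mode="au")
config = ThermoEngineConfig()
cohort = synthetic_cohort(SyntheticSpec(n_genes=300, rng_seed=42), engine, config)
mirna = cohort["mirna"]

positives = []
for sites in cohort["sites"].values():
    strong = [s for s in sites if s.seed_type.label in FILTER_LEVELS["6in8"]]
    if strong:
        positives.append(min(strong, key=lambda s: s.ddG))

rng = np.random.default_rng(42)
cfg = ShuffleConfig(forbidden_seeds=frozenset({mirna.seed}))
controls = []
for shuffled, utr in generate_control_pairs([mirna], cohort["utrs"], cfg, rng):
    pick = sample_control_site(score_sites(shuffled, utr, engine, config), rng)
    if pick is not None:
        controls.append(pick)

pos = [s.ddG for s in positives]
neg = [s.ddG for s in controls]
auc = roc_auc(pos, neg, lower_is_positive=True).auc
_, p = rank_sum_test(pos, neg)
print(f"{len(pos)} strong-seed sites vs {len(neg)} shuffled-control sites")
print(f"ddG AUC = {auc:.3f}   rank-sum p = {p:.2e}")
print(
    "\nAUC > 0.5: strong-seed sites form more favorable duplexes than "
    "matches of composition-matched shuffled miRNAs."
)
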