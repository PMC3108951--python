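"""Per-UTR energy features for the expression-change model.

All sites of one miRNA-UTR pair collapse into 14 features: the top two
values of each energy type, the dG_H/dG_open read off at the two best-ddG
sites, the per-type sums over all sites, and the 3'UTR length (longer
UTRs carry more chance matches, so length enters the model directly).
"Best" is the minimum for ddG and dG_H (most favorable) but the maximum
for dG_open (closest to zero = most accessible, the direction observed
at true sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .site_scan import TargetSite

FEATURE_NAMES = [
    "best_ddG",
    "second_best_ddG",
    "best_dG_H",
    "second_best_dG_H",
    "best_dG_open",
    "second_best_dG_open",
    "dG_H_at_best_ddG",
    "dG_H_at_second_ddG",
    "dG_open_at_best_ddG",
    "dG_open_at_second_ddG",
    "sum_ddG",
    "sum_dG_H",
    "sum_dG_open",
    "utr_length",
]


@dataclass(frozen=True)
class FeatureVector:
    """The 14 per-UTR features, kcal/mol except ``utr_length`` (nt)."""

    best_ddG: float
    second_best_ddG: float
    best_dG_H: float
    second_best_dG_H: float
    best_dG_open: float
    second_best_dG_open: float
    dG_H_at_best_ddG: float
    dG_H_at_second_ddG: float
    dG_open_at_best_ddG: float
    dG_open_at_second_ddG: float
    sum_ddG: float
    sum_dG_H: float
    sum_dG_open: float
    utr_length: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def utr_features(sites: Sequence[TargetSite], utr_length: int) -> FeatureVector:
    """Collapse one pair's (overlap-resolved) sites into a FeatureVector.

    Genes with fewer than two sites get zero for the affected energy
    features so every gene stays scorable; ``utr_length`` is always
    populated.
    """
    if utr_length < 0:
        raise ValueError("utr_length must be non-negative")
    by_ddG = sorted(sites, key=lambda s: s.ddG)
    ddGs = sorted(s.ddG for s in sites)
    dGHs = sorted(s.dG_H for s in sites)
    dGopens = sorted((s.dG_open for s in sites), reverse=True)  # max = most accessible

    def nth(vals, i):
        return vals[i] if len(vals) > i else 0.0

    return FeatureVector(
        best_ddG=nth(ddGs, 0),
        second_best_ddG=nth(ddGs, 1),
        best_dG_H=nth(dGHs, 0),
        second_best_dG_H=nth(dGHs, 1),
        best_dG_open=nth(dGopens, 0),
        second_best_dG_open=nth(dGopens, 1),
        dG_H_at_best_ddG=by_ddG[0].dG_H if len(by_ddG) > 0 else 0.0,
        dG_H_at_second_ddG=by_ddG[1].dG_H if len(by_ddG) > 1 else 0.0,
        dG_open_at_best_ddG=by_ddG[0].dG_open if len(by_ddG) > 0 else 0.0,
        dG_open_at_second_ddG=by_ddG[1].dG_open if len(by_ddG) > 1 else 0.0,
        sum_ddG=math.fsum(s.ddG for s in sites),  # fsum: order-independent
        sum_dG_H=math.fsum(s.dG_H for s in sites),
        sum_dG_open=math.fsum(s.dG_open for s in sites),
        utr_length=utr_length,
    )


def feature_table(
    pairs: Iterable[tuple[str, str, Sequence[TargetSite], int]]
) -> pd.DataFrame:
    """One feature row per (mirna_id, gene_id) pair.

    ``pairs`` yields (mirna_id, gene_id, sites, utr_length).  Duplicate
    keys are an error; row order is deterministic (sorted by key).
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for mirna_id, gene_id, sites, utr_length in pairs:
        key = (mirna_id, gene_id)
        if key in seen:
            raise ValueError(f"duplicate feature key {key}")
        seen.add(key)
        row = {"mirna_id": mirna_id, "gene_id": gene_id}
        row.update(utr_features(sites, utr_length).as_dict())
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["mirna_id", "gene_id"] + FEATURE_NAMES)
    return frame.sort_values(["mirna_id", "gene_id"], ignore_index=True)


def write_feature_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
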