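"""FASTA input and tabular output for miRNA / 3'UTR records.

All sequences are held internally in the RNA alphabet (A, C, G, U),
5'->3'.  DNA input (T, lowercase) is normalized on read; ambiguity codes
are rejected outright because duplex energies on ambiguous bases are
undefined.  UTR coordinates are 0-based half-open throughout the package,
while miRNA positions are quoted 1-based from the 5' end so that
"positions 2-8" means the canonical seed region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: Column order of the site table written by :func:`write_site_table`.
SITE_TABLE_COLUMNS = [
    "utr_id",
    "mirna_id",
    "utr_start",
    "utr_end",
    "mirna_nucleus_start",
    "seed_type",
    "dG_H",
    "dG_open",
    "ddG",
]


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be parsed or validated."""


def normalize_rna(raw: str, *, record_id: str = "?") -> str:
    """Uppercase ``raw`` and convert T->U; reject anything outside ACGU.

    Idempotent: normalizing an already-normalized sequence is a no-op.
    """
    seq = raw.strip().upper().replace("T", "U")
    for pos, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise FastaParseError(
                f"record {record_id!r}: illegal character {base!r} at position {pos}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement on the RNA alphabet."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MiRNA:
    """A mature microRNA, 5'->3'.

    Positions 1-8 form the seed region; at least one base must remain
    3' of it, hence the minimum length of 9 nt.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, record_id=self.id))
        if len(self.sequence) < 9:
            raise ValueError(
                f"miRNA {self.id!r}: length {len(self.sequence)} < 9 "
                "(need positions 1-8 plus at least one 3' base)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def seed(self) -> str:
        """Positions 2-8 (the canonical seed heptamer)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UtrRecord:
    """A 3'UTR, optionally with the tail of the upstream CDS attached.

    ``upstream_context`` immediately precedes the UTR 5' end; duplex
    context extraction may reach into it when a site sits close to the
    stop codon.
    """

    id: str
    sequence: str
    upstream_context: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, record_id=self.id))
        object.__setattr__(
            self,
            "upstream_context",
            normalize_rna(self.upstream_context, record_id=f"{self.id} (context)"),
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _iter_fasta(path: str | Path) -> Iterable[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq)


def read_mirna_fasta(path: str | Path) -> list[MiRNA]:
    """Read miRNAs from FASTA; duplicate ids are an error."""
    out: list[MiRNA] = []
    seen: set[str] = set()
    for rid, seq in _iter_fasta(path):
        if rid in seen:
            raise FastaParseError(f"duplicate miRNA id {rid!r} in {path}")
        seen.add(rid)
        out.append(MiRNA(id=rid, sequence=seq))
    return out


def read_utr_fasta(path: str | Path, context_path: str | Path | None = None) -> list[UtrRecord]:
    """Read UTRs, attaching upstream CDS context records when provided.

    Context ids must match UTR ids; a context record with no matching
    UTR is skipped with a warning.
    """
    contexts: dict[str, str] = {}
    utr_pairs = list(_iter_fasta(path))
    utr_ids = {rid for rid, _ in utr_pairs}
    if context_path is not None:
        for rid, seq in _iter_fasta(context_path):
            if rid not in utr_ids:
                warnings.warn(f"context record {rid!r} has no matching UTR; skipped")
                continue
            contexts[rid] = seq
    out: list[UtrRecord] = []
    seen: set[str] = set()
    for rid, seq in utr_pairs:
        if rid in seen:
            raise FastaParseError(f"duplicate UTR id {rid!r} in {path}")
        seen.add(rid)
        out.append(UtrRecord(id=rid, sequence=seq, upstream_context=contexts.get(rid, "")))
    return out


def write_fasta(records: Sequence[MiRNA] | Sequence[UtrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def sites_to_frame(sites: Sequence["TargetSite"]) -> pd.DataFrame:  # noqa: F821
    """Flatten TargetSite records into the canonical site table."""
    rows = []
    for s in sites:
        m = s.match
        rows.append(
            {
                "utr_id": m.utr_id,
                "mirna_id": m.mirna_id,
                "utr_start": m.utr_start,
                "utr_end": m.utr_start + 4,
                "mirna_nucleus_start": m.mirna_pos,
                "seed_type": s.seed_type.label,
                "dG_H": s.dG_H,
                "dG_open": s.dG_open,
                "ddG": s.ddG,
            }
        )
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def write_site_table(sites: Sequence["TargetSite"], path: str | Path) -> None:  # noqa: F821
    """Write sites as TSV; energies at 2 decimals, '.' for missing values."""
    frame = sites_to_frame(sites)
    for col in ("dG_H", "dG_open", "ddG"):
        frame[col] = frame[col].map(lambda v: "." if pd.isna(v) else f"{v:.2f}")
    frame.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a site table back into a DataFrame (energies as floats)."""
    frame = pd.read_csv(path, sep="\t", na_values=".")
    return frame
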