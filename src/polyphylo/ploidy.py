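"""Ploidy classification from karyotypes and homeolog copy counts.

Two independent lines of evidence are combined:

* somatic chromosome counts (2n) together with flow-cytometry genome
  sizes (2C, picograms, converted at 1 pg = 978 Mb to Mb/1C);
* the number of distinct copies recovered per low-copy nuclear gene —
  diploids yield a single sequence per gene, allopolyploids a pair of
  homeologs for (almost) every gene.

Chromosome counts are mapped to ploidy by the observed-count lookup
(20 -> 2x; 28, 38, 40 -> 4x; 60 -> 6x; 56, 76 -> 8x): dysploid counts
such as 28 and 38 belong to documented 4x lineages, so rounding 2n/20
would misclassify them, and any count outside the observed set is
reported as unknown rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

#: Conversion factor between DNA mass and length: 1 pg = 978 Mb.
PG_TO_MB = 978.0

#: Observed 2n -> ploidy lookup; dysploid counts mapped per documented lineage.
PLOIDY_BY_2N = {20: "2x", 28: "4x", 38: "4x", 40: "4x", 56: "8x", 60: "6x", 76: "8x"}

DIPLOID_LIKE = "diploid-like"
POLYPLOID_LIKE = "polyploid-like"
CONFLICTED = "conflicted"

#: Ploidy call consistent with each copy-count consensus.
_CALL_OF_PLOIDY = {"2x": DIPLOID_LIKE, "4x": POLYPLOID_LIKE,
                   "6x": POLYPLOID_LIKE, "8x": POLYPLOID_LIKE}


def pg2c_to_mb1c(c2_pg: float) -> float:
    """Convert a 2C DNA amount (pg) to a 1C genome size (Mb)."""
    if not c2_pg > 0:
        raise ValueError(f"2C value must be positive, got {c2_pg}")
    return c2_pg / 2.0 * PG_TO_MB


def classify_ploidy(two_n: int) -> str:
    """Ploidy call for a somatic chromosome count; unobserved counts -> unknown."""
    if not two_n > 0:
        raise ValueError(f"chromosome count must be positive, got {two_n}")
    return PLOIDY_BY_2N.get(int(two_n), "unknown")


@dataclass
class KaryotypeRecord:
    """One taxon's karyotype and genome-size evidence."""

    taxon: str
    two_n: Optional[int] = None
    c2_pg: Optional[float] = None
    mb_1c: Optional[float] = field(default=None, init=False)
    ploidy_call: str = field(default="unknown", init=False)

    def __post_init__(self) -> None:
        if self.two_n is not None:
            self.ploidy_call = classify_ploidy(self.two_n)
        if self.c2_pg is not None:
            self.mb_1c = pg2c_to_mb1c(self.c2_pg)


@dataclass
class CopyCountRecord:
    """Distinct-copy counts per low-copy nuclear gene for one taxon."""

    taxon: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"no gene copy counts for {self.taxon!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("copy counts must be >= 1")


def infer_from_copies(record: CopyCountRecord, threshold: float = 0.5) -> str:
    """Consensus call from per-gene copy counts.

    All genes single-copy -> diploid-like; fraction of two-copy genes at
    least ``threshold`` -> polyploid-like; anything in between ->
    conflicted. The 0.5 default encodes that polyploids carry homeolog
    pairs for most, if not all, genes.
    """
    counts = list(record.counts.values())
    if all(c == 1 for c in counts):
        return DIPLOID_LIKE
    frac_two = sum(1 for c in counts if c >= 2) / len(counts)
    return POLYPLOID_LIKE if frac_two >= threshold else CONFLICTED


@dataclass
class ConsensusCall:
    taxon: str
    ploidy_call: str
    conflict: bool
    karyotype_call: str = "unknown"
    copy_call: str = "unknown"


def consensus_ploidy(
    karyo: Optional[KaryotypeRecord],
    copies: Optional[CopyCountRecord],
    threshold: float = 0.5,
) -> ConsensusCall:
    """Joint ploidy call; the karyotype wins on disagreement, flagged."""
    if karyo is None and copies is None:
        raise ValueError("at least one evidence source is required")
    taxon = karyo.taxon if karyo is not None else copies.taxon
    k_call = karyo.ploidy_call if karyo is not None else "unknown"
    c_call = infer_from_copies(copies, threshold) if copies is not None else "unknown"
    if karyo is None or k_call == "unknown":
        return ConsensusCall(taxon, c_call, False, k_call, c_call)
    if copies is None:
        return ConsensusCall(taxon, k_call, False, k_call, c_call)
    expected = _CALL_OF_PLOIDY.get(k_call)
    conflict = expected is not None and c_call != "unknown" and c_call != expected
    return ConsensusCall(taxon, k_call, conflict, k_call, c_call)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_karyotype_table(path) -> list[KaryotypeRecord]:
    """Read a karyotype CSV with columns taxon, 2n[, 2C_pg]."""
    df = pd.read_csv(path)
    cols = {c.lower().lstrip("﻿"): c for c in df.columns}
    taxon_col = cols.get("taxon") or df.columns[0]
    twon_col = cols.get("2n")
    pg_col = cols.get("2c_pg")
    records = []
    for _, row in df.iterrows():
        two_n = row[twon_col] if twon_col and pd.notna(row[twon_col]) else None
        c2 = row[pg_col] if pg_col and pd.notna(row[pg_col]) else None
        records.append(KaryotypeRecord(str(row[taxon_col]),
                                       int(two_n) if two_n is not None else None,
                                       float(c2) if c2 is not None else None))
    return records


def read_copy_count_table(path) -> list[CopyCountRecord]:
    """Read a copy-count CSV: column taxon plus one integer column per gene."""
    df = pd.read_csv(path)
    taxon_col = df.columns[0]
    gene_cols = [c for c in df.columns if c != taxon_col]
    records = []
    for _, row in df.iterrows():
        counts = {g: int(row[g]) for g in gene_cols if pd.notna(row[g])}
        records.append(CopyCountRecord(str(row[taxon_col]), counts))
    return records


def ploidy_report(
    karyotypes: list[KaryotypeRecord],
    copy_counts: Optional[list[CopyCountRecord]] = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Annotated table: genome sizes, per-source calls, consensus, conflicts."""
    copies_by_taxon = {r.taxon: r for r in (copy_counts or [])}
    taxa = [k.taxon for k in karyotypes]
    karyo_by_taxon = {k.taxon: k for k in karyotypes}
    for t in copies_by_taxon:
        if t not in karyo_by_taxon:
            taxa.append(t)
    rows = []
    for taxon in taxa:
        karyo = karyo_by_taxon.get(taxon)
        copies = copies_by_taxon.get(taxon)
        call = consensus_ploidy(karyo, copies, threshold)
        rows.append(
            {
                "taxon": taxon,
                "2n": karyo.two_n if karyo else None,
                "2C_pg": karyo.c2_pg if karyo else None,
                "Mb_1C": karyo.mb_1c if karyo else None,
                "karyotype_call": call.karyotype_call,
                "copy_call": call.copy_call,
                "ploidy": call.ploidy_call,
                "conflict": call.conflict,
            }
        )
    return pd.DataFrame(rows)
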