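"""Deletion context classification and indel length comparisons.

Each deletion is classified into exactly one of three categories:

* ``repeat`` — the deleted sequence is an exact copy of the reference
  immediately 3' or 5' of the deletion (loss of one unit of a tandem
  duplication);
* ``microhomology`` — not a repeat, but 1–5 terminal bases of the deleted
  sequence recur at the matching end of a flank (partial repetition at the
  breakpoint, the footprint of end-joining repair);
* ``other`` — no terminal overlap at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genome as gn
from .stats import fisher_exact, ks_two_sample

MICROHOMOLOGY_CAP = 5
DEFAULT_LENGTH_BINS = ((1, 1), (2, 5), (6, 10), (11, None))


@dataclass
class DeletionRecord:
    chrom: str
    start: int  # 1-based position of the first deleted base
    deleted_sequence: str
    flank5: str  # reference upstream of the deletion
    flank3: str  # reference downstream of the deletion
    sample_id: str = ""

    def __post_init__(self) -> None:
        L = len(self.deleted_sequence)
        if not 1 <= L <= 50:
            raise ValueError("deletion length must lie in 1..50")
        need = max(5, L)
        if len(self.flank5) < need or len(self.flank3) < need:
            raise ValueError(
                f"flanks must be >= max(5, deletion length) = {need} bp"
            )


@dataclass
class DeletionClassification:
    record: DeletionRecord
    category: str  # repeat | microhomology | other
    microhomology_length: int  # 0..5
    evidence: str


def _prefix_match(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_deletion(rec: DeletionRecord) -> DeletionClassification:
    """Assign the context category of one deletion.

    Overlap is measured on both sides (deleted prefix vs the start of the
    3' flank and deleted suffix vs the end of the 5' flank) and the larger
    value is reported, capped at 5 with a note when longer.
    """
    d = rec.deleted_sequence
    L = len(d)
    if rec.flank3[:L] == d or rec.flank5[-L:] == d:
        side = "3'" if rec.flank3[:L] == d else "5'"
        return DeletionClassification(
            rec, "repeat", 0, f"full adjacent copy on the {side} side"
        )
    k3 = _prefix_match(d, rec.flank3)
    k5 = _prefix_match(d[::-1], rec.flank5[::-1])
    k = max(k3, k5)
    if k == 0:
        return DeletionClassification(rec, "other", 0, "no terminal overlap")
    note = ""
    if k > MICROHOMOLOGY_CAP:
        note = f" (raw overlap {k} capped at {MICROHOMOLOGY_CAP})"
        k = MICROHOMOLOGY_CAP
    return DeletionClassification(
        rec, "microhomology", k,
        f"prefix/3' overlap {k3}, suffix/5' overlap {k5}{note}",
    )


def deletions_from_calls(
    calls: pd.DataFrame, reference: dict[str, str], flank: int = 60
) -> list[DeletionRecord]:
    """Build deletion records from a calls table, re-reading flanks from
    the reference. Call positions are 1-based anchors (base before the
    deletion)."""
    out = []
    dels = calls[calls["type"] == "DEL"]
    for row in dels.itertuples():
        deleted = row.ref[len(row.alt):]
        seq = reference[row.chrom]
        p0 = int(row.pos)  # 0-based index of the first deleted base
        if seq[p0 : p0 + len(deleted)] != deleted:
            raise ValueError(
                f"deleted sequence mismatch at {row.chrom}:{row.pos}"
            )
        out.append(
            DeletionRecord(
                chrom=row.chrom,
                start=p0 + 1,
                deleted_sequence=deleted,
                flank5=seq[max(0, p0 - flank) : p0],
                flank3=seq[p0 + len(deleted) : p0 + len(deleted) + flank],
                sample_id=row.sample,
            )
        )
    return out


def classification_table(
    classifications: list[DeletionClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.record.sample_id,
                "chrom": c.record.chrom,
                "start": c.record.start,
                "deleted": c.record.deleted_sequence,
                "length": len(c.record.deleted_sequence),
                "category": c.category,
                "microhomology_k": c.microhomology_length,
                "evidence": c.evidence,
            }
            for c in classifications
        ]
    )


def length_distribution(
    lengths_by_group: dict[str, list[int]],
    bins: tuple[tuple[int, int | None], ...] = DEFAULT_LENGTH_BINS,
) -> pd.DataFrame:
    """Histogram of indel lengths per group over inclusive bins."""
    labels = [
        (f"{lo}" if lo == (hi or lo) else f"{lo}-{hi}" if hi else f">{lo - 1}")
        for lo, hi in bins
    ]
    rows = {}
    for group, lengths in lengths_by_group.items():
        arr = np.asarray(list(lengths), dtype=int)
        if arr.size and (arr.min() < 1 or arr.max() > 50):
            raise ValueError("lengths must lie in 1..50")
        counts = []
        for lo, hi in bins:
            hi_eff = hi if hi is not None else 50
            counts.append(int(((arr >= lo) & (arr <= hi_eff)).sum()))
        rows[group] = counts
    return pd.DataFrame(rows, index=labels).T


def compare_length_distributions(x: list[int], y: list[int]):
    """Two-sample KS test on raw deletion lengths."""
    return ks_two_sample(list(x), list(y))


def compare_category_tables(table) -> float:
    """Exact test of independence on a category x genotype count table."""
    res = fisher_exact(np.asarray(table, dtype=int))
    return res.p_value
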