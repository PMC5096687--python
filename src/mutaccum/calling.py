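"""Unique-mutation calling across many isogenic samples.

All samples are compared simultaneously at each genomic position. A call
is emitted for a sample only when that sample alone shows the variant
(alternate-allele fraction and coverage thresholds), every other sample is
clean (reference-allele fraction threshold), and an exact-test quality
score against the noisiest other sample clears a cutoff. Base-quality
filtering is assumed to have been applied upstream of the count tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CALL_COLUMNS

logger = logging.getLogger("mutaccum.calling")


@dataclass
class CallerConfig:
    min_alt_allele_fraction: float = 0.2
    min_mutated_coverage: int = 5
    min_other_ref_fraction: float = 0.93
    min_quality_score: float = 2.0
    max_indel_length: int = 50
    base_quality_cutoff: int = 30  # documentation only; applied upstream

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_alt_allele_fraction <= 1.0:
            raise ValueError("min_alt_allele_fraction must lie in [0, 1]")
        if not 0.0 <= self.min_other_ref_fraction <= 1.0:
            raise ValueError("min_other_ref_fraction must lie in [0, 1]")
        if self.min_mutated_coverage < 1:
            raise ValueError("min_mutated_coverage must be >= 1")
        if self.max_indel_length < 1:
            raise ValueError("max_indel_length must be >= 1")


@dataclass
class PositionCounts:
    """Per-sample, per-position filtered observation counts.

    ``base_counts`` holds reads whose base call at this position supports
    that base and no indel; reads supporting an insertion or deletion
    anchored here are counted in ``insertion_counts`` / ``deletion_counts``
    and in ``depth`` only.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref_base: str
    base_counts: dict[str, int]
    insertion_counts: dict[str, int] = field(default_factory=dict)
    deletion_counts: dict[str, int] = field(default_factory=dict)  # "len:seq" keys
    depth: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_counts.values()):
            raise ValueError("negative base count")
        if self.depth < 0:
            raise ValueError("negative depth")

    @property
    def ref_count(self) -> int:
        return self.base_counts.get(self.ref_base, 0)

    @property
    def ref_fraction(self) -> float:
        return self.ref_count / self.depth if self.depth > 0 else 0.0


@dataclass
class MutationCall:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mutation_type: str  # SNV | INS | DEL
    alt_fraction: float
    depth: int
    quality_score: float
    comparison_sample_id: str


@dataclass
class _Candidate:
    counts: PositionCounts
    events: list[tuple[str, str, int]]  # (type, payload, count)
    comparison: PositionCounts


def quality_score(
    candidate_counts: tuple[int, int], comparison_counts: tuple[int, int]
) -> float:
    """-log10 of Fisher's two-sided exact p on the 2x2 (ref, alt) table."""
    table = np.array([candidate_counts, comparison_counts])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table: quality undefined")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(-np.log10(max(p, 5e-324)))


def _candidate_events(pc: PositionCounts, cfg: CallerConfig) -> list[tuple[str, str, int]]:
    """Variant alleles in one sample meeting the AF and coverage thresholds."""
    if pc.depth < cfg.min_mutated_coverage:
        return []
    thresh = cfg.min_alt_allele_fraction * pc.depth
    events = []
    for base, n in pc.base_counts.items():
        if base != pc.ref_base and n > 0 and n >= thresh:
            events.append(("SNV", base, n))
    for seq, n in pc.insertion_counts.items():
        if n > 0 and n >= thresh:
            events.append(("INS", seq, n))
    for key, n in pc.deletion_counts.items():
        if n > 0 and n >= thresh:
            events.append(("DEL", key, n))
    return events


def screen_position(
    counts_all_samples: list[PositionCounts], cfg: CallerConfig
) -> _Candidate | None:
    """Apply the unique-mutation filter cascade at one position.

    Returns a candidate only when exactly one sample carries a variant
    allele at sufficient fraction and coverage while every other sample is
    covered and sufficiently pure reference.
    """
    if len(counts_all_samples) < 2:
        raise ValueError("need at least two samples")
    first = counts_all_samples[0]
    for pc in counts_all_samples[1:]:
        if (pc.chrom, pc.pos) != (first.chrom, first.pos):
            raise ValueError("samples disagree on position")
        if pc.ref_base != first.ref_base:
            raise ValueError(
                f"inconsistent ref_base at {first.chrom}:{first.pos}"
            )
    flagged = [
        (pc, _candidate_events(pc, cfg)) for pc in counts_all_samples
    ]
    with_events = [(pc, ev) for pc, ev in flagged if ev]
    if len(with_events) != 1:
        return None
    cand, events = with_events[0]
    comparison = None
    for pc in counts_all_samples:
        if pc.sample_id == cand.sample_id:
            continue
        if pc.depth == 0:
            return None  # cannot certify cleanliness in a coverage hole
        if pc.ref_fraction < cfg.min_other_ref_fraction:
            return None
        if comparison is None or pc.ref_fraction < comparison.ref_fraction:
            comparison = pc
    return _Candidate(counts=cand, events=events, comparison=comparison)


def _parse_tokens(text: str) -> dict[str, int]:
    """Parse ``key:count`` tokens (keys may themselves contain colons)."""
    out: dict[str, int] = {}
    if not text:
        return out
    for tok in text.split(";"):
        key, _, n = tok.rpartition(":")
        out[key] = out.get(key, 0) + int(n)
    return out


def counts_from_rows(rows: pd.DataFrame) -> list[PositionCounts]:
    """Convert count-table rows at one position into PositionCounts objects."""
    out = []
    for r in rows.to_dict("records"):
        out.append(
            PositionCounts(
                sample_id=r["sample"],
                chrom=r["chrom"],
                pos=int(r["pos"]),
                ref_base=r["ref_base"],
                base_counts={b: int(r[b]) for b in "ACGT"},
                insertion_counts=_parse_tokens(r["ins"]),
                deletion_counts=_parse_tokens(r["del"]),
                depth=int(r["depth"]),
            )
        )
    return out


def _event_to_alleles(
    event: tuple[str, str, int], ref_base: str
) -> tuple[str, str, str]:
    kind, payload, _n = event
    if kind == "SNV":
        return ref_base, payload, "SNV"
    if kind == "INS":
        return ref_base, ref_base + payload, "INS"
    _len, _, seq = payload.partition(":")
    return ref_base + seq, ref_base, "DEL"


def _event_count(pc: PositionCounts, event: tuple[str, str, int]) -> int:
    kind, payload, _ = event
    if kind == "SNV":
        return pc.base_counts.get(payload, 0)
    if kind == "INS":
        return pc.insertion_counts.get(payload, 0)
    return pc.deletion_counts.get(payload, 0)


def call_at_position(
    counts_all_samples: list[PositionCounts], cfg: CallerConfig
) -> list[MutationCall]:
    """Full cascade at one position: screen, then exact-test quality."""
    cand = screen_position(counts_all_samples, cfg)
    if cand is None:
        return []
    calls = []
    for event in cand.events:
        kind, payload, n = event
        if kind != "SNV":
            length = len(payload.partition(":")[2]) if kind == "DEL" else len(payload)
            if length > cfg.max_indel_length or length == 0:
                continue
        score = quality_score(
            (cand.counts.ref_count, n),
            (cand.comparison.ref_count, _event_count(cand.comparison, event)),
        )
        if score < cfg.min_quality_score:
            continue
        ref, alt, mtype = _event_to_alleles(event, cand.counts.ref_base)
        calls.append(
            MutationCall(
                sample_id=cand.counts.sample_id,
                chrom=cand.counts.chrom,
                pos=cand.counts.pos,
                ref=ref,
                alt=alt,
                mutation_type=mtype,
                alt_fraction=n / cand.counts.depth,
                depth=cand.counts.depth,
                quality_score=score,
                comparison_sample_id=cand.comparison.sample_id,
            )
        )
    return calls


def call_unique_mutations(
    counts: pd.DataFrame,
    cfg: CallerConfig | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Run the filter cascade over a whole count table.

    ``counts`` follows the count-table layout (one row per sample per
    position with non-reference evidence anywhere in the cohort). Positions
    missing one or more samples are skipped with a warning. The output is
    sorted by (chrom, pos, sample) and is independent of any chunking of
    the input by genomic region.
    """
    cfg = cfg or CallerConfig()
    if sample_ids is None:
        sample_ids = sorted(counts["sample"].unique())
    n_samples = len(sample_ids)
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if counts.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)

    df = counts
    chrom_vals = df["chrom"].to_numpy()
    pos_vals = df["pos"].to_numpy()
    order_ok = True
    if len(df) > 1:
        same = chrom_vals[:-1] == chrom_vals[1:]
        if (pos_vals[1:][same] < pos_vals[:-1][same]).any():
            order_ok = False
    if not order_ok:
        raise ValueError("count table must be sorted by (chrom, pos)")

    # vectorized per-row candidate pre-filter (exact for SNVs; indel rows
    # are rare and re-checked in full)
    bases = df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    ref_idx = pd.Categorical(
        df["ref_base"], categories=list("ACGT")
    ).codes.astype(np.int64)
    depth = df["depth"].to_numpy(dtype=np.int64)
    nonref = bases.copy()
    nonref[np.arange(len(df)), ref_idx] = -1
    max_alt = nonref.max(axis=1)
    flag = (depth >= cfg.min_mutated_coverage) & (
        max_alt >= cfg.min_alt_allele_fraction * depth
    ) & (max_alt > 0)
    has_indel = (df["ins"].to_numpy() != "") | (df["del"].to_numpy() != "")
    for i in np.nonzero(has_indel & ~flag)[0]:
        row = df.iloc[i]
        if depth[i] < cfg.min_mutated_coverage:
            continue
        toks = _parse_tokens(row["ins"]) | _parse_tokens(row["del"])
        if any(
            n >= cfg.min_alt_allele_fraction * depth[i] and n > 0
            for n in toks.values()
        ):
            flag[i] = True

    # group rows by position, visit only groups containing a flagged row
    keys = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
    codes, _uniq = pd.factorize(keys, sort=False)
    flagged_groups = np.unique(codes[flag])
    calls: list[MutationCall] = []
    n_skipped = 0
    for g in flagged_groups:
        # input is position-sorted, so group codes form contiguous runs
        lo = int(np.searchsorted(codes, g, side="left"))
        hi = int(np.searchsorted(codes, g, side="right"))
        rows = df.iloc[lo:hi]
        if rows["sample"].nunique() != n_samples:
            n_skipped += 1
            continue
        pcs = counts_from_rows(rows)
        calls.extend(call_at_position(pcs, cfg))
    if n_skipped:
        logger.warning("skipped %d positions missing one or more samples",
                       n_skipped)

    out = pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.mutation_type,
             c.alt_fraction, c.depth, c.quality_score, c.comparison_sample_id)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    return out.sort_values(["chrom", "pos", "sample"], kind="mergesort").reset_index(
        drop=True
    )
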