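"""Triplet mutation spectra and intermutation-distance statistics.

The 96 classes are ordered substitution-type major (C>A, C>G, C>T, T>A,
T>C, T>G), then 5' flank, then 3' flank, both alphabetical — the layout of
published signature catalogues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genome as gn

logger = logging.getLogger("mutaccum.spectra")

MODES = ("counts", "rates", "normalized")


@dataclass
class TripletSpectrum96:
    values: np.ndarray
    mode: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (96,):
            raise ValueError("spectrum must have exactly 96 values")
        if (self.values < 0).any():
            raise ValueError("spectrum values must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "normalized" and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1")

    def normalized(self) -> "TripletSpectrum96":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return TripletSpectrum96(self.values / total, mode="normalized")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=gn.CLASS_LABELS, name=self.mode)


def classify_snv(ref_triplet: str, alt_base: str) -> int:
    """Class index (0..95) of a substitution given its reference triplet.

    Purine-centred substitutions are reverse-complemented into the
    pyrimidine representation first, so the map is two-to-one over strands
    and bijective over pyrimidine-centred (triplet, alt) pairs.
    """
    if len(ref_triplet) != 3:
        raise ValueError("ref_triplet must be a 3-mer")
    for b in ref_triplet + alt_base:
        if b not in gn.BASE_INDEX:
            raise ValueError(f"ambiguous base {b!r}")
    if ref_triplet[1] == alt_base:
        raise ValueError("alt base equals the reference base")
    if ref_triplet[1] in "AG":
        ref_triplet = gn.revcomp(ref_triplet)
        alt_base = gn.COMPLEMENT[alt_base]
    sub = gn.SUBSTITUTION_TYPES.index((ref_triplet[1], alt_base))
    f5 = gn.BASE_INDEX[ref_triplet[0]]
    f3 = gn.BASE_INDEX[ref_triplet[2]]
    return sub * 16 + f5 * 4 + f3


def build_spectrum(
    calls: pd.DataFrame, reference: dict[str, str]
) -> TripletSpectrum96:
    """Count spectrum over the SNV calls in a calls table; indels ignored.

    Calls at a chromosome edge (no flanking base) are excluded with a
    warning, so the spectrum total equals the number of usable SNVs.
    """
    values = np.zeros(96)
    excluded = 0
    snvs = calls[calls["type"] == "SNV"] if "type" in calls.columns else calls
    for row in snvs.itertuples():
        seq = reference[row.chrom]
        p = int(row.pos) - 1
        if p < 1 or p >= len(seq) - 1:
            excluded += 1
            continue
        triplet = seq[p - 1 : p + 2]
        if seq[p] != row.ref:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{row.pos}: "
                f"{seq[p]} != {row.ref}"
            )
        values[classify_snv(triplet, row.alt)] += 1
    if excluded:
        logger.warning("excluded %d SNVs at chromosome edges", excluded)
    return TripletSpectrum96(values, mode="counts")


def normalize_by_genome(
    spectrum: TripletSpectrum96, freqs: gn.GenomeTripletFrequencies
) -> TripletSpectrum96:
    """Per-class mutation rates: counts divided by triplet occurrences."""
    if spectrum.mode != "counts":
        raise ValueError("normalize_by_genome expects a counts spectrum")
    per_class = freqs.per_class()
    bad = (per_class == 0) & (spectrum.values > 0)
    if bad.any():
        name = gn.triplet_of_class(int(np.nonzero(bad)[0][0]))
        raise ValueError(f"zero genome frequency for triplet {name}")
    rates = np.divide(
        spectrum.values, per_class,
        out=np.zeros(96), where=per_class > 0,
    )
    return TripletSpectrum96(rates, mode="rates")


def intermutation_distances(calls: pd.DataFrame) -> pd.DataFrame:
    """Distance of each SNV to the previous SNV on the same chromosome.

    Expects one sample's calls. The first SNV on each chromosome has no
    previous mutation and is omitted. Output columns: chrom, pos, distance,
    class label.
    """
    snvs = calls[calls["type"] == "SNV"] if "type" in calls.columns else calls
    if "sample" in snvs.columns and snvs["sample"].nunique() > 1:
        raise ValueError("intermutation distances are per sample; got several")
    rows = []
    for chrom, grp in snvs.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        if pos.size < 2:
            continue
        dist = np.diff(pos)
        has_alleles = {"ref", "alt"}.issubset(grp.columns)
        for i, (p, d) in enumerate(zip(pos[1:], dist)):
            label = ""
            if has_alleles:
                ref = str(grp["ref"].iloc[i + 1])
                alt = str(grp["alt"].iloc[i + 1])
                if ref in "AG":
                    ref, alt = gn.COMPLEMENT[ref], gn.COMPLEMENT[alt]
                label = f"{ref}>{alt}"
            rows.append((chrom, int(p), int(d), label))
    return pd.DataFrame(rows, columns=["chrom", "pos", "distance", "class"])


def clustered_fraction(distances, window: int = 100) -> float:
    """Fraction of SNVs within ``window`` bp of the previous SNV."""
    if isinstance(distances, pd.DataFrame):
        distances = distances["distance"].to_numpy()
    arr = np.asarray(distances)
    if arr.size == 0:
        raise ValueError("no intermutation distances: fraction undefined")
    if (arr < 1).any():
        raise ValueError("distances must be >= 1")
    return float((arr <= window).mean())
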