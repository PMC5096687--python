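"""Sequence utilities: complements, triplet coding and genome triplet counting.

All spectra in this package use the pyrimidine-centred convention: a
substitution observed at an A or G is reverse-complemented before
classification, so the 96 classes are the 6 substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 flanking-base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: substitution classes in catalogue order
SUBSTITUTION_TYPES = [
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
]

_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G on 0..3 codes

# byte-level encoding table: ACGT -> 0..3, everything else -> 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence to int codes A=0, C=1, G=2, T=3; non-ACGT -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def class_label(index: int) -> str:
    """Human-readable label, e.g. ``A[C>T]G``, for a 0..95 class index."""
    sub, rem = divmod(index, 16)
    f5, f3 = divmod(rem, 4)
    ref, alt = SUBSTITUTION_TYPES[sub]
    return f"{BASES[f5]}[{ref}>{alt}]{BASES[f3]}"


CLASS_LABELS = [class_label(i) for i in range(96)]

#: the 32 pyrimidine-centred triplets, in (5' flank, centre, 3' flank) order
PYRIMIDINE_TRIPLETS = [
    f"{f5}{c}{f3}" for c in "CT" for f5 in BASES for f3 in BASES
]
PYRIMIDINE_TRIPLETS.sort()
TRIPLET_INDEX = {t: i for i, t in enumerate(PYRIMIDINE_TRIPLETS)}


def collapse_triplet(triplet: str) -> str:
    """Map a 3-mer to its pyrimidine-centred representative."""
    if len(triplet) != 3 or any(b not in BASE_INDEX for b in triplet):
        raise ValueError(f"not an unambiguous 3-mer: {triplet!r}")
    return triplet if triplet[1] in "CT" else revcomp(triplet)


def triplet_of_class(index: int) -> str:
    """Pyrimidine-centred reference triplet of a 0..95 class index."""
    sub, rem = divmod(index, 16)
    f5, f3 = divmod(rem, 4)
    return BASES[f5] + SUBSTITUTION_TYPES[sub][0] + BASES[f3]


@dataclass
class GenomeTripletFrequencies:
    """Occurrence counts of the 32 pyrimidine-centred triplets in a genome.

    Purine-centred windows are reverse-complemented into the pyrimidine
    bins, so each count covers both strands. Windows containing non-ACGT
    characters are skipped.
    """

    counts: dict[str, int]
    label: str = ""

    def __post_init__(self) -> None:
        missing = set(PYRIMIDINE_TRIPLETS) - set(self.counts)
        if missing:
            raise ValueError(f"missing triplets: {sorted(missing)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative triplet count")

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[t] for t in PYRIMIDINE_TRIPLETS], dtype=float)

    def per_class(self) -> np.ndarray:
        """Length-96 vector giving each class its triplet's occurrence count."""
        return np.array(
            [self.counts[triplet_of_class(i)] for i in range(96)], dtype=float
        )


def count_genome_triplets(
    chromosomes: dict[str, str], label: str = ""
) -> GenomeTripletFrequencies:
    """Count overlapping triplets over all chromosomes, strand-collapsed."""
    totals = np.zeros(64, dtype=np.int64)
    for seq in chromosomes.values():
        codes = encode_sequence(seq)
        if codes.size < 3:
            continue
        a, b, c = codes[:-2], codes[1:-1], codes[2:]
        valid = (a < 4) & (b < 4) & (c < 4)
        trip = (
            a[valid].astype(np.int64) * 16
            + b[valid].astype(np.int64) * 4
            + c[valid].astype(np.int64)
        )
        totals += np.bincount(trip, minlength=64)
    counts = {}
    for t in range(64):
        f5, cen, f3 = t // 16, (t // 4) % 4, t % 4
        trip_str = BASES[f5] + BASES[cen] + BASES[f3]
        key = collapse_triplet(trip_str)
        counts[key] = counts.get(key, 0) + int(totals[t])
    return GenomeTripletFrequencies(counts=counts, label=label)
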