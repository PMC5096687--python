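"""Signature-catalogue comparison of triplet spectra.

Observed spectra are reweighted by the ratio of triplet occurrences in a
target genome versus the source genome (so a spectrum measured in one
species can be compared against a catalogue derived from another), then
correlated signature-by-signature with Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome as gn
from .spectra import TripletSpectrum96


@dataclass
class SignatureCatalog:
    """Named signatures as rows of 96 class probabilities."""

    names: list[str]
    matrix: np.ndarray  # (n_signatures, 96)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError("catalog matrix must be (n, 96)")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("names/matrix size mismatch")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("each signature must sum to 1")

    def __len__(self) -> int:
        return len(self.names)


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a catalogue TSV (Substitution Type, Trinucleotide, one column
    per signature), reordering rows into the package's class order."""
    df = pd.read_csv(path, sep="\t")
    sub_col, tri_col = df.columns[0], df.columns[1]
    labels = [
        f"{t[0]}[{s}]{t[2]}" for s, t in zip(df[sub_col], df[tri_col])
    ]
    df = df.set_axis(labels, axis=0)
    value_cols = df.columns[2:]
    matrix = df.loc[gn.CLASS_LABELS, value_cols].to_numpy(dtype=float).T
    return SignatureCatalog(names=list(value_cols), matrix=matrix)


def load_demo_catalog() -> SignatureCatalog:
    """Bundled 30-signature fixture (synthetic, for tests and demos)."""
    with resources.as_file(
        resources.files("mutaccum.data").joinpath("signature_catalog_demo.tsv")
    ) as p:
        return read_catalog(p)


@dataclass
class AdjustedSpectrum:
    spectrum: TripletSpectrum96
    source_label: str = ""
    target_label: str = ""

    def __post_init__(self) -> None:
        if self.spectrum.mode != "normalized":
            raise ValueError("adjusted spectrum must be normalized")


def cross_genome_adjust(
    spectrum: TripletSpectrum96,
    source_freqs: gn.GenomeTripletFrequencies,
    target_freqs: gn.GenomeTripletFrequencies,
) -> AdjustedSpectrum:
    """Reweight class values by target/source triplet-occurrence ratios.

    Applied to counts before normalization; the result is renormalized to
    sum to 1.
    """
    src = source_freqs.per_class()
    tgt = target_freqs.per_class()
    if (src == 0).any():
        bad = gn.triplet_of_class(int(np.nonzero(src == 0)[0][0]))
        raise ValueError(f"zero source frequency for triplet {bad}")
    adjusted = spectrum.values * (tgt / src)
    total = adjusted.sum()
    if total <= 0:
        raise ValueError("adjusted spectrum is all zero")
    return AdjustedSpectrum(
        TripletSpectrum96(adjusted / total, mode="normalized"),
        source_label=source_freqs.label,
        target_label=target_freqs.label,
    )


def correlate_with_catalog(
    adjusted: AdjustedSpectrum | TripletSpectrum96, catalog: SignatureCatalog
) -> pd.Series:
    """Pearson correlation of the spectrum with each catalogue signature."""
    spec = adjusted.spectrum if isinstance(adjusted, AdjustedSpectrum) else adjusted
    x = spec.values
    if np.std(x) == 0:
        raise ValueError("zero-variance spectrum: correlation undefined")
    xc = x - x.mean()
    out = {}
    for name, row in zip(catalog.names, catalog.matrix):
        if np.std(row) == 0:
            out[name] = np.nan
            continue
        rc = row - row.mean()
        out[name] = float(
            (xc @ rc) / np.sqrt((xc @ xc) * (rc @ rc))
        )
    return pd.Series(out, name="pearson_r")


def subtract_baseline(
    spectrum: TripletSpectrum96, baseline: TripletSpectrum96
) -> tuple[TripletSpectrum96, int]:
    """Component-wise subtraction with clipping at zero, then renormalize.

    Returns the renormalized difference spectrum and the number of clipped
    (negative) components.
    """
    if spectrum.mode != baseline.mode:
        raise ValueError("spectrum and baseline must share a mode")
    diff = spectrum.values - baseline.values
    clipped = int((diff < 0).sum())
    diff = np.clip(diff, 0.0, None)
    total = diff.sum()
    if total <= 0:
        raise ValueError("all components <= 0 after subtraction")
    return TripletSpectrum96(diff / total, mode="normalized"), clipped


#: class indices of the four NCG>NTG categories (C>T with a 3' G)
NCG_NTG_INDICES = [2 * 16 + f5 * 4 + gn.BASE_INDEX["G"] for f5 in range(4)]


def cg_tg_overrepresentation(rates: TripletSpectrum96) -> float:
    """Mean NCG>NTG class rate divided by the mean rate over all classes."""
    if rates.mode != "rates":
        raise ValueError("overrepresentation is defined on rate spectra")
    overall = rates.values.mean()
    if overall == 0:
        raise ValueError("zero mean rate: fold undefined")
    return float(rates.values[NCG_NTG_INDICES].mean() / overall)
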