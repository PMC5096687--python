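"""Plain-text I/O: FASTA, count tables, truth sets, VCF and spectrum tables.

All on-disk coordinates are 1-based; in-memory bulk tables keep the same
1-based ``pos`` column so files round-trip without shifting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

COUNT_COLUMNS = [
    "sample", "chrom", "pos", "ref_base",
    "A", "C", "G", "T", "ins", "del", "depth",
]

TRUTH_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "class",
    "del_category", "microhomology_k",
]

CALL_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "type",
    "af", "depth", "score", "comparison_sample",
]


def write_fasta(chromosomes: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    chromosomes: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                chromosomes[name] = []
            elif line and name is not None:
                chromosomes[name].append(line.upper())
    return {k: "".join(v) for k, v in chromosomes.items()}


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"sample": str, "chrom": str, "ins": str, "del": str},
        keep_default_na=False,
    )
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_truth_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"sample": str, "chrom": str}, keep_default_na=False
    )


def write_calls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})


def write_vcf(
    calls: pd.DataFrame,
    sample: str,
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write one sample's calls as a minimal VCF v4.2 file."""
    sub = calls[calls["sample"] == sample].sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mutaccum\n##sample={sample}\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="Mutation type">\n'
        )
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sub.itertuples():
            info = f"TYPE={row.type};AF={row.af:.4f};DP={row.depth}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                f"\t{row.score:.4f}\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF back into a calls-like frame (one sample)."""
    sample = ""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sample="):
                sample = line.strip().split("=", 1)[1]
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, qual, _filt, info = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in info.split(";"))
            rows.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    "type": fields["TYPE"],
                    "af": float(fields["AF"]),
                    "depth": int(fields["DP"]),
                    "score": float(qual),
                }
            )
    return pd.DataFrame(rows)


def write_spectrum_tsv(values: Iterable[float], path: str | Path) -> None:
    from .genome import CLASS_LABELS

    vals = list(values)
    if len(vals) != 96:
        raise ValueError("spectrum must have 96 values")
    with open(path, "w") as fh:
        fh.write("class\tvalue\n")
        for label, v in zip(CLASS_LABELS, vals):
            fh.write(f"{label}\t{v:.10g}\n")


def read_spectrum_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("class")["value"]


def write_triplet_frequencies(freqs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genome={freqs.label}\ntriplet\tcount\n")
        for t in sorted(freqs.counts):
            fh.write(f"{t}\t{freqs.counts[t]}\n")


def read_triplet_frequencies(path: str | Path, label: str = ""):
    from .genome import GenomeTripletFrequencies

    counts = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("triplet"):
                continue
            t, c = line.split()
            counts[t] = int(c)
    return GenomeTripletFrequencies(counts=counts, label=label)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
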