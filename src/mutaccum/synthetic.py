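"""Synthetic mutation-accumulation cohorts.

Generates a multi-chromosome reference, implants sample-private SNVs and
indels (with controllable triplet spectrum and deletion contexts) plus
shared germline heterozygous sites, and simulates noisy per-position
allele-count tables that are valid input for the unique-mutation caller.

Counts are emitted as if base-quality filtering had already been applied
upstream; the noise model therefore only covers coverage variation and a
small per-base substitution error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import genome as gn
from .io import COUNT_COLUMNS, TRUTH_COLUMNS


class CapacityError(RuntimeError):
    """Requested burden cannot be placed without violating spacing rules."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class SyntheticGenomeSpec:
    chromosome_lengths: Sequence[int]
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) == 0:
            raise ValueError("need at least one chromosome")
        if any(int(l) < 1000 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be >= 1000 bp")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


@dataclass
class NoiseModel:
    mean_coverage: float = 25.0
    coverage_dispersion: float = 0.0
    per_base_error: float = 0.002

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.coverage_dispersion < 0:
            raise ValueError("coverage_dispersion must be >= 0")
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must lie in [0, 1]")

    def draw_coverage(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Negative-binomial depth (Poisson when dispersion is zero)."""
        m, d = self.mean_coverage, self.coverage_dispersion
        if d == 0:
            return rng.poisson(m, size=size).astype(np.int32)
        r = 1.0 / d
        p = r / (r + m)
        return rng.negative_binomial(r, p, size=size).astype(np.int32)


DEFAULT_DELETION_LENGTHS = {1: 0.35, 2: 0.2, 3: 0.15, 4: 0.1, 5: 0.08,
                            6: 0.05, 8: 0.04, 10: 0.02, 15: 0.01}
DEFAULT_INSERTION_LENGTHS = {1: 0.6, 2: 0.2, 3: 0.1, 4: 0.05, 5: 0.05}


@dataclass
class CohortSpec:
    """Cohort layout and per-sample mutation burdens.

    ``samples`` is a list of ``(sample_id, genotype_label)`` pairs. Burdens
    apply to every sample unless ``per_sample_burdens`` overrides the SNV
    burden for specific samples.
    """

    samples: Sequence[tuple[str, str]]
    snv_burden: int = 0
    insertion_burden: int = 0
    deletion_burden: int = 0
    snv_spectrum: np.ndarray | None = None  # 96 sampling weights; None = uniform
    deletion_mix: tuple[float, float, float] = (0.2, 0.4, 0.4)  # repeat, mh, other
    deletion_lengths: dict[int, float] | None = None
    microhomology_k: int | None = None  # None: uniform over feasible 1..5
    insertion_lengths: dict[int, float] | None = None
    germline_het_density: float = 0.0
    min_spacing: int = 100
    per_sample_burdens: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")
        if min(self.snv_burden, self.insertion_burden, self.deletion_burden) < 0:
            raise ValueError("burdens must be non-negative")
        if self.snv_spectrum is not None:
            spec = np.asarray(self.snv_spectrum, dtype=float)
            if spec.shape != (96,) or (spec < 0).any() or spec.sum() <= 0:
                raise ValueError("snv_spectrum must be 96 non-negative weights")
            self.snv_spectrum = spec / spec.sum()
        mix = np.asarray(self.deletion_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any():
            raise ValueError("deletion_mix must be 3 non-negative fractions")
        if self.deletion_burden > 0 and not np.isclose(mix.sum(), 1.0):
            raise ValueError("deletion_mix must sum to 1")
        if self.microhomology_k is not None and not 1 <= self.microhomology_k <= 5:
            raise ValueError("microhomology_k must lie in 1..5")
        if self.germline_het_density < 0:
            raise ValueError("germline_het_density must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]


@dataclass
class TruthRecord:
    sample: str
    chrom: str
    pos: int  # 1-based; for indels the anchor base before the event
    ref: str
    alt: str
    mclass: str  # SNV | INS | DEL
    del_category: str = ""  # repeat | microhomology | other for DELs
    microhomology_k: int = 0


@dataclass
class CohortTruthSet:
    records: list[TruthRecord]
    germline: list[tuple[str, int, str, str]]  # chrom, pos (1-based), ref, alt
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.sample, r.chrom, r.pos, r.ref, r.alt, r.mclass,
             r.del_category, r.microhomology_k)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(spec: SyntheticGenomeSpec) -> dict[str, str]:
    """Random reference with the requested GC content; chr1, chr2, ..."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    chromosomes = {}
    for i, length in enumerate(spec.chromosome_lengths, start=1):
        codes = rng.choice(4, size=int(length), p=probs)
        chromosomes[f"chr{i}"] = "".join(gn.BASES[c] for c in codes)
    return chromosomes


# ---------------------------------------------------------------------------
# mutation implantation


def _prefix_match(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _draw_from_dist(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    w = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=w / w.sum()))


class _Placer:
    """Tracks blocked regions so implants keep a minimum pairwise spacing."""

    def __init__(self, chromosomes: dict[str, str], spacing: int) -> None:
        self.chromosomes = chromosomes
        self.names = list(chromosomes)
        self.lengths = np.array([len(chromosomes[c]) for c in self.names])
        self.blocked = {c: np.zeros(len(chromosomes[c]), dtype=bool)
                        for c in self.names}
        self.spacing = spacing

    def random_chrom(self, rng: np.random.Generator) -> str:
        p = self.lengths / self.lengths.sum()
        return self.names[rng.choice(len(self.names), p=p)]

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > len(self.chromosomes[chrom]):
            return False
        return not self.blocked[chrom][start:end].any()

    def block(self, chrom: str, start: int, end: int) -> None:
        lo = max(0, start - self.spacing)
        hi = min(len(self.chromosomes[chrom]), end + self.spacing)
        self.blocked[chrom][lo:hi] = True


def _build_triplet_position_index(
    chromosomes: dict[str, str],
) -> dict[str, list[tuple[str, np.ndarray]]]:
    """For each of the 32 collapsed triplets: centre positions per chromosome."""
    index: dict[str, list[tuple[str, np.ndarray]]] = {
        t: [] for t in gn.PYRIMIDINE_TRIPLETS
    }
    for chrom, seq in chromosomes.items():
        codes = gn.encode_sequence(seq).astype(np.int64)
        if codes.size < 3:
            continue
        a, b, c = codes[:-2], codes[1:-1], codes[2:]
        trip = a * 16 + b * 4 + c
        valid = (a < 4) & (b < 4) & (c < 4)
        # fold purine-centred codes onto pyrimidine-centred ones
        comp = gn._COMP_CODE
        rc = comp[c.clip(max=3)] * 16 + comp[b.clip(max=3)] * 4 + comp[a.clip(max=3)]
        purine = (b == 0) | (b == 2)
        folded = np.where(purine, rc, trip)
        for t_str in gn.PYRIMIDINE_TRIPLETS:
            f5, cen, f3 = (gn.BASE_INDEX[x] for x in t_str)
            code = f5 * 16 + cen * 4 + f3
            pos = np.nonzero(valid & (folded == code))[0] + 1  # centre, 0-based
            if pos.size:
                index[t_str].append((chrom, pos))
    return index


def _place_snvs(
    rng: np.random.Generator,
    placer: _Placer,
    trip_index,
    spectrum: np.ndarray | None,
    n: int,
    sample: str,
) -> list[TruthRecord]:
    if n == 0:
        return []
    if spectrum is None:
        weights = np.ones(96) / 96.0
    else:
        weights = spectrum.copy()
    # restrict to classes whose triplet context exists in the reference
    avail = np.array(
        [bool(trip_index[gn.triplet_of_class(i)]) for i in range(96)]
    )
    weights = np.where(avail, weights, 0.0)
    if weights.sum() == 0:
        raise CapacityError("no requested triplet context present in reference")
    weights = weights / weights.sum()

    flat_index = {
        t: (entries, np.array([p.size for _, p in entries]))
        for t, entries in trip_index.items() if entries
    }
    records = []
    classes = rng.choice(96, size=n, p=weights)
    max_tries = 200
    for cls in classes:
        trip = gn.triplet_of_class(int(cls))
        ref_pyr, alt_pyr = gn.SUBSTITUTION_TYPES[int(cls) // 16]
        entries, sizes = flat_index[trip]
        placed = False
        for _ in range(max_tries):
            ci = rng.choice(len(entries), p=sizes / sizes.sum())
            chrom, positions = entries[ci]
            p = int(positions[rng.integers(positions.size)])  # 0-based centre
            if not placer.is_free(chrom, p - 1, p + 2):
                continue
            ref_base = placer.chromosomes[chrom][p]
            alt = alt_pyr if ref_base == ref_pyr else gn.COMPLEMENT[alt_pyr]
            placer.block(chrom, p, p + 1)
            records.append(
                TruthRecord(sample, chrom, p + 1, ref_base, alt, "SNV")
            )
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place SNV in context {trip} after {max_tries} tries"
            )
    return records


def _place_insertions(
    rng, placer: _Placer, lengths: dict[int, float], n: int, sample: str
) -> list[TruthRecord]:
    records = []
    for _ in range(n):
        L = _draw_from_dist(rng, lengths)
        for attempt in range(2000):
            chrom = placer.random_chrom(rng)
            seq = placer.chromosomes[chrom]
            a = int(rng.integers(10, len(seq) - 10))  # 0-based anchor base
            if not placer.is_free(chrom, a, a + 2):
                continue
            ins = "".join(gn.BASES[c] for c in rng.integers(0, 4, size=L))
            placer.block(chrom, a, a + 1)
            records.append(
                TruthRecord(sample, chrom, a + 1, seq[a], seq[a] + ins, "INS")
            )
            break
        else:
            raise CapacityError("could not place insertion")
    return records


def _deletion_context(seq: str, p0: int, L: int) -> tuple[bool, int, int]:
    """Repeat flag and 3'/5' partial-overlap lengths for deleting seq[p0:p0+L]."""
    deleted = seq[p0 : p0 + L]
    right = seq[p0 + L : p0 + 2 * L]
    left = seq[max(0, p0 - L) : p0]
    is_rep = deleted == right or (len(left) == L and deleted == left)
    k3 = _prefix_match(deleted, seq[p0 + L : p0 + L + len(deleted)])
    k5 = _prefix_match(deleted[::-1], seq[:p0][::-1])
    return is_rep, k3, k5


def _repeat_positions(seq: str, L: int) -> np.ndarray:
    """0-based starts p where seq[p:p+L] == seq[p+L:p+2L] (tandem unit)."""
    codes = gn.encode_sequence(seq)
    if codes.size < 2 * L + 22:
        return np.array([], dtype=np.int64)
    eq = (codes[:-L] == codes[L:]).astype(np.int64)
    window = np.convolve(eq, np.ones(L, dtype=np.int64), mode="valid")
    starts = np.nonzero(window == L)[0]
    starts = starts[(starts >= L + 11) & (starts + 2 * L + 11 <= len(seq))]
    return starts


def _place_deletions(
    rng,
    placer: _Placer,
    mix: tuple[float, float, float],
    lengths: dict[int, float],
    mh_k: int | None,
    n: int,
    sample: str,
) -> list[TruthRecord]:
    records = []
    categories = rng.choice(3, size=n, p=np.asarray(mix, dtype=float))
    names = ["repeat", "microhomology", "other"]
    repeat_sites: dict[tuple[str, int], np.ndarray] = {}
    repeat_lengths = dict(lengths)  # lengths with no tandem site get dropped

    def accept(chrom: str, p0: int, L: int, cat: str, k: int) -> None:
        seq = placer.chromosomes[chrom]
        placer.block(chrom, p0 - 1, p0 + L)
        records.append(
            TruthRecord(
                sample, chrom, p0, seq[p0 - 1 : p0 + L], seq[p0 - 1], "DEL",
                del_category=cat,
                microhomology_k=k if cat == "microhomology" else 0,
            )
        )

    for cat_i in categories:
        cat = names[int(cat_i)]
        placed = False
        if cat == "repeat":
            # tandem-unit sites are rare at larger lengths: enumerate them
            # once per (chromosome, length) and sample directly
            while repeat_lengths and not placed:
                L = _draw_from_dist(rng, repeat_lengths)
                pools = []
                for chrom in placer.names:
                    key = (chrom, L)
                    if key not in repeat_sites:
                        repeat_sites[key] = _repeat_positions(
                            placer.chromosomes[chrom], L
                        )
                    if repeat_sites[key].size:
                        pools.append((chrom, repeat_sites[key]))
                if not pools:
                    repeat_lengths.pop(L)
                    continue
                for _ in range(200):
                    chrom, sites = pools[int(rng.integers(len(pools)))]
                    p0 = int(sites[rng.integers(sites.size)])
                    if placer.is_free(chrom, p0 - 1, p0 + L + 1):
                        accept(chrom, p0, L, cat, 0)
                        placed = True
                        break
                else:
                    repeat_lengths.pop(L)
            if not placed:
                raise CapacityError("no tandem-repeat deletion site available")
            continue

        L = _draw_from_dist(rng, lengths)
        if cat == "microhomology":
            while L < 2:  # k >= 1 with k < L needs at least 2 deleted bases
                L = _draw_from_dist(rng, lengths)
            k = mh_k if mh_k is not None else int(rng.integers(1, min(5, L - 1) + 1))
            k = min(k, L - 1)
        else:
            k = 0
        for _ in range(100_000):
            chrom = placer.random_chrom(rng)
            seq = placer.chromosomes[chrom]
            if len(seq) < 2 * L + 30:
                continue
            p0 = int(rng.integers(L + 11, len(seq) - 2 * L - 11))
            if not placer.is_free(chrom, p0 - 1, p0 + L + 1):
                continue
            is_rep, k3, k5 = _deletion_context(seq, p0, L)
            if cat == "microhomology":
                ok = (not is_rep) and k3 == k and k5 <= k
            else:
                ok = (not is_rep) and k3 == 0 and k5 == 0
            if not ok:
                continue
            accept(chrom, p0, L, cat, k)
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place a {cat} deletion of length {L}"
            )
    return records


def implant_mutations(
    reference: dict[str, str], cohort: CohortSpec
) -> CohortTruthSet:
    """Implant germline het sites plus sample-private SNVs and indels.

    All implants (across samples) keep at least ``cohort.min_spacing`` bp
    between each other, which makes truth/call matching unambiguous and the
    unclustered null hold by construction.
    """
    ss = np.random.SeedSequence(cohort.seed)
    streams = ss.spawn(1 + len(cohort.samples))
    placer = _Placer(reference, cohort.min_spacing)
    trip_index = _build_triplet_position_index(reference)

    # shared germline heterozygous sites
    germ_rng = np.random.default_rng(streams[0])
    genome_len = int(placer.lengths.sum())
    n_germ = int(round(cohort.germline_het_density * genome_len))
    germline: list[tuple[str, int, str, str]] = []
    for _ in range(n_germ):
        for _attempt in range(2000):
            chrom = placer.random_chrom(germ_rng)
            seq = placer.chromosomes[chrom]
            p = int(germ_rng.integers(1, len(seq) - 1))
            if not placer.is_free(chrom, p, p + 1):
                continue
            ref_base = seq[p]
            alt = germ_rng.choice([b for b in gn.BASES if b != ref_base])
            placer.block(chrom, p, p + 1)
            germline.append((chrom, p + 1, ref_base, str(alt)))
            break
        else:
            raise CapacityError("could not place germline site")

    del_lengths = cohort.deletion_lengths or DEFAULT_DELETION_LENGTHS
    ins_lengths = cohort.insertion_lengths or DEFAULT_INSERTION_LENGTHS
    records: list[TruthRecord] = []
    for (sample, _genotype), stream in zip(cohort.samples, streams[1:]):
        rng = np.random.default_rng(stream)
        n_snv = cohort.per_sample_burdens.get(sample, cohort.snv_burden)
        records += _place_snvs(
            rng, placer, trip_index, cohort.snv_spectrum, n_snv, sample
        )
        records += _place_insertions(
            rng, placer, ins_lengths, cohort.insertion_burden, sample
        )
        records += _place_deletions(
            rng, placer, cohort.deletion_mix, del_lengths,
            cohort.microhomology_k, cohort.deletion_burden, sample,
        )
    return CohortTruthSet(
        records=records, germline=germline, sample_ids=cohort.sample_ids
    )


# ---------------------------------------------------------------------------
# pileup-count simulation


def _format_tokens(tokens: dict[str, int]) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(tokens.items()) if v > 0)


def simulate_pileup_counts(
    reference: dict[str, str],
    truth: CohortTruthSet,
    noise: NoiseModel,
    seed: int,
) -> pd.DataFrame:
    """Noisy per-position count table for every sample.

    The table is sparse-complete: it contains a row for *every* sample at
    every position where *any* sample has non-reference evidence (sequencing
    errors, implanted variants, germline sites). Positions absent from the
    table are pure reference in all samples and carry no calling signal.
    Implanted and germline variants are heterozygous: alternate reads are
    Binomial(depth, 0.5). Reads supporting an indel are counted in ``depth``
    and in the indel token but not in the base counts.
    """
    samples = truth.sample_ids
    chrom_names = list(reference)
    by_site: dict[tuple[str, int], list[TruthRecord]] = {}
    for r in truth.records:
        by_site.setdefault((r.chrom, r.pos - 1), []).append(r)
    germ_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, _ref, alt in truth.germline:
        germ_by_chrom.setdefault(chrom, []).append((pos - 1, alt))

    frames = []
    for ci, chrom in enumerate(chrom_names):
        seq = reference[chrom]
        L = len(seq)
        codes = gn.encode_sequence(seq)
        per_sample = []
        union: set[int] = set()
        for si, sample in enumerate(samples):
            cov_rng = np.random.default_rng([seed, ci, si, 0])
            err_rng = np.random.default_rng([seed, ci, si, 1])
            var_rng = np.random.default_rng([seed, ci, si, 2])
            cov = noise.draw_coverage(cov_rng, L)

            # heterozygous variant reads at this sample's sites + germline
            var_reads: dict[int, tuple[str, int]] = {}  # pos0 -> (kind, n)
            sites: list[tuple[int, TruthRecord | None, str]] = []
            for (vchrom, p0), recs in by_site.items():
                if vchrom != chrom:
                    continue
                for r in recs:
                    if r.sample == sample:
                        sites.append((p0, r, ""))
            for p0, alt in germ_by_chrom.get(chrom, []):
                sites.append((p0, None, alt))
            site_info: dict[int, tuple[str, str, int]] = {}
            for p0, rec, galt in sorted(sites):
                c = int(cov[p0])
                n_alt = int(var_rng.binomial(c, 0.5)) if c > 0 else 0
                if rec is None:
                    site_info[p0] = ("SNV", galt, n_alt)
                elif rec.mclass == "SNV":
                    site_info[p0] = ("SNV", rec.alt, n_alt)
                elif rec.mclass == "INS":
                    site_info[p0] = ("INS", rec.alt[1:], n_alt)
                else:  # DEL: anchor row, token carries length and sequence
                    site_info[p0] = ("DEL", rec.ref[1:], n_alt)

            # sequencing errors among reads not supporting a variant
            n_for_err = cov.copy()
            for p0, (_k, _a, n_alt) in site_info.items():
                n_for_err[p0] = max(0, n_for_err[p0] - n_alt)
            n_err = err_rng.binomial(n_for_err, noise.per_base_error)
            err_pos = np.nonzero(n_err)[0]
            err_split = (
                err_rng.multinomial(n_err[err_pos], [1 / 3] * 3)
                if err_pos.size
                else np.zeros((0, 3), dtype=np.int64)
            )
            per_sample.append((cov, site_info, dict(
                zip(err_pos.tolist(), err_split.tolist()))))
            union.update(err_pos.tolist())
            union.update(site_info.keys())

        if not union:
            continue
        upos = np.array(sorted(union), dtype=np.int64)
        for (cov, site_info, errs), sample in zip(per_sample, samples):
            n = upos.size
            base_counts = np.zeros((n, 4), dtype=np.int64)
            depth = cov[upos].astype(np.int64)
            ins_col = [""] * n
            del_col = [""] * n
            ref_codes = codes[upos]
            # default: pure reference at full depth; fix up event rows below
            base_counts[np.arange(n), ref_codes] = depth
            event_pos = set(site_info) | set(errs)
            for p0 in event_pos:
                j = int(np.searchsorted(upos, p0))
                rc = int(ref_codes[j])
                base_counts[j, :] = 0
                n_ref = int(depth[j])
                if p0 in site_info:
                    kind, payload, n_alt = site_info[p0]
                    n_alt = min(n_alt, n_ref)
                    if kind == "SNV":
                        base_counts[j, gn.BASE_INDEX[payload]] += n_alt
                        n_ref -= n_alt
                    elif kind == "INS":
                        if n_alt:
                            ins_col[j] = _format_tokens({payload: n_alt})
                        n_ref -= n_alt
                    else:
                        if n_alt:
                            del_col[j] = _format_tokens(
                                {f"{len(payload)}:{payload}": n_alt}
                            )
                        n_ref -= n_alt
                if p0 in errs:
                    others = [b for b in range(4) if b != rc]
                    for b, ne in zip(others, errs[p0]):
                        ne = min(ne, n_ref)
                        base_counts[j, b] += ne
                        n_ref -= ne
                base_counts[j, rc] += max(0, n_ref)
            del event_pos
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "pos": upos + 1,
                        "ref_base": [gn.BASES[c] for c in ref_codes],
                        "A": base_counts[:, 0],
                        "C": base_counts[:, 1],
                        "G": base_counts[:, 2],
                        "T": base_counts[:, 3],
                        "ins": ins_col,
                        "del": del_col,
                        "depth": depth,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "sample"], kind="mergesort").reset_index(
        drop=True
    )


def place_uniform_positions(
    chromosome_lengths: Sequence[int], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Place n positions uniformly over a genome; the unclustered null."""
    lengths = np.asarray(chromosome_lengths, dtype=np.int64)
    p = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n, p=p)
    pos = rng.integers(1, lengths[chrom_idx] + 1)
    # two point mutations cannot share a site: redraw collisions
    df = pd.DataFrame({"chrom_i": chrom_idx, "pos": pos})
    while df.duplicated(["chrom_i", "pos"]).any():
        dup = df.duplicated(["chrom_i", "pos"])
        df.loc[dup, "pos"] = rng.integers(
            1, lengths[df.loc[dup, "chrom_i"]] + 1
        )
    df = pd.DataFrame(
        {"chrom": [f"chr{i + 1}" for i in df["chrom_i"]], "pos": df["pos"]}
    )
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)
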