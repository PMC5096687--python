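import math

import numpy as np
import pandas as pd
import pytest

from conftest import counts_frame, make_counts
from mutaccum.calling import (
    CallerConfig,
    MutationCall,
    call_at_position,
    call_unique_mutations,
    quality_score,
    screen_position,
)


# ---------------------------------------------------------------------------
# independent oracles (straight re-statements of the filter definitions)


def fisher_p_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        # P(table with top-left = x | margins)
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def oracle_calls(df, cfg, sample_ids):
    """Brute-force filter cascade applied literally, position by position."""
    out = []
    for (chrom, pos), grp in df.groupby(["chrom", "pos"], sort=True):
        if sorted(grp["sample"]) != sorted(sample_ids):
            continue
        rows = grp.to_dict("records")
        candidates = []
        for r in rows:
            if r["depth"] < cfg.min_mutated_coverage:
                continue
            events = []
            for b in "ACGT":
                if b != r["ref_base"] and r[b] > 0 and (
                    r[b] / r["depth"] >= cfg.min_alt_allele_fraction
                ):
                    events.append(("SNV", b, r[b]))
            for col, kind in (("ins", "INS"), ("del", "DEL")):
                if r[col]:
                    for tok in r[col].split(";"):
                        key, _, nn = tok.rpartition(":")
                        nn = int(nn)
                        if nn > 0 and nn / r["depth"] >= cfg.min_alt_allele_fraction:
                            events.append((kind, key, nn))
            if events:
                candidates.append((r, events))
        if len(candidates) != 1:
            continue
        cand, events = candidates[0]
        others = [r for r in rows if r["sample"] != cand["sample"]]
        if any(o["depth"] == 0 for o in others):
            continue
        fracs = [o[o["ref_base"]] / o["depth"] for o in others]
        if min(fracs) < cfg.min_other_ref_fraction:
            continue
        comp = others[int(np.argmin(fracs))]
        for kind, key, nn in events:
            if kind == "SNV":
                comp_alt = comp[key]
                ref, alt = cand["ref_base"], key
            elif kind == "INS":
                if len(key) > cfg.max_indel_length:
                    continue
                toks = dict(
                    t.rpartition(":")[::2] for t in comp["ins"].split(";") if t
                )
                comp_alt = int(toks.get(key, 0))
                ref, alt = cand["ref_base"], cand["ref_base"] + key
            else:
                seq = key.partition(":")[2]
                if len(seq) > cfg.max_indel_length:
                    continue
                toks = dict(
                    t.rpartition(":")[::2] for t in comp["del"].split(";") if t
                )
                comp_alt = int(toks.get(key, 0))
                ref, alt = cand["ref_base"] + seq, cand["ref_base"]
            p = fisher_p_oracle(
                cand[cand["ref_base"]], nn, comp[comp["ref_base"]], comp_alt
            )
            score = -math.log10(p)
            if score >= cfg.min_quality_score:
                out.append((cand["sample"], chrom, pos, ref, alt))
    return sorted(out)


def random_table(rng, n_samples, n_positions, with_indels=False):
    rows = []
    samples = [f"s{i}" for i in range(n_samples)]
    for p in range(n_positions):
        ref = "ACGT"[rng.integers(4)]
        for s in samples:
            depth = int(rng.integers(0, 30))
            ref_n = int(rng.binomial(depth, 0.9))
            rest = depth - ref_n
            split = rng.multinomial(rest, [1 / 3] * 3)
            base = {b: 0 for b in "ACGT"}
            base[ref] = ref_n
            for b, v in zip([b for b in "ACGT" if b != ref], split):
                base[b] = int(v)
            ins = {}
            dele = {}
            if with_indels and rng.random() < 0.15 and depth > 0:
                k = int(rng.integers(1, 5))
                take = min(base[ref], k)
                base[ref] -= take
                if rng.random() < 0.5:
                    ins["AC"] = take
                else:
                    dele["2:AC"] = take
            rows.append(
                make_counts(s, "chr1", p + 1, ref, **{x.lower(): base[x] for x in "ACGT"},
                            ins=ins, dele=dele, depth=depth)
            )
    return counts_frame(rows), samples


# ---------------------------------------------------------------------------
# quality score


class TestQualityScore:
    def test_identical_tables_score_zero(self):
        assert quality_score((6, 4), (6, 4)) == pytest.approx(0.0)

    def test_matches_hypergeometric_oracle(self):
        p = fisher_p_oracle(6, 4, 10, 0)
        assert quality_score((6, 4), (10, 0)) == pytest.approx(
            -math.log10(p), rel=1e-9
        )

    def test_extreme_separation(self):
        assert quality_score((0, 20), (20, 0)) > 5

    def test_all_zero_table_signalled(self):
        with pytest.raises(ValueError):
            quality_score((0, 0), (0, 0))

    def test_random_tables_match_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b == 0 or c + d == 0 or a + b + c + d == 0:
                continue
            expect = fisher_p_oracle(a, b, c, d)
            got = 10 ** (-quality_score((a, b), (c, d)))
            assert got == pytest.approx(expect, rel=1e-6)


# ---------------------------------------------------------------------------
# screen_position


class TestScreenPosition:
    cfg = CallerConfig()

    def test_passing_candidate(self):
        rows = [
            make_counts("a", "chr1", 10, "C", c=6, t=4),
            make_counts("b", "chr1", 10, "C", c=10),
            make_counts("c", "chr1", 10, "C", c=12),
        ]
        cand = screen_position(rows, self.cfg)
        assert cand is not None
        assert cand.counts.sample_id == "a"
        assert cand.events == [("SNV", "T", 4)]
        assert cand.comparison.sample_id in {"b", "c"}

    def test_unclean_other_sample_blocks(self):
        rows = [
            make_counts("a", "chr1", 10, "C", c=6, t=4),
            make_counts("b", "chr1", 10, "C", c=9, t=1),  # ref frac 0.90
        ]
        assert screen_position(rows, self.cfg) is None

    def test_all_reference_gives_none(self):
        rows = [make_counts(f"s{i}", "chr1", 5, "G", g=20) for i in range(30)]
        assert screen_position(rows, self.cfg) is None

    def test_two_candidates_give_none(self):
        rows = [
            make_counts("a", "chr1", 10, "C", c=6, t=4),
            make_counts("b", "chr1", 10, "C", c=6, t=4),
            make_counts("c", "chr1", 10, "C", c=12),
        ]
        assert screen_position(rows, self.cfg) is None

    def test_zero_depth_other_sample_skips(self):
        rows = [
            make_counts("a", "chr1", 10, "C", c=6, t=4),
            make_counts("b", "chr1", 10, "C"),
        ]
        assert screen_position(rows, self.cfg) is None

    def test_comparison_is_lowest_ref_fraction_first_on_ties(self):
        rows = [
            make_counts("a", "chr1", 10, "C", c=5, t=5),
            make_counts("b", "chr1", 10, "C", c=19, a=1),
            make_counts("c", "chr1", 10, "C", c=19, g=1),
        ]
        cand = screen_position(rows, self.cfg)
        assert cand.comparison.sample_id == "b"

    def test_inconsistent_ref_base_is_error(self):
        rows = [
            make_counts("a", "chr1", 10, "C", c=10),
            make_counts("b", "chr1", 10, "G", g=10),
        ]
        with pytest.raises(ValueError, match="ref_base"):
            screen_position(rows, self.cfg)


# ---------------------------------------------------------------------------
# call_unique_mutations


class TestCallUniqueMutations:
    def test_engineered_toy_table(self):
        cfg = CallerConfig()
        rows = []
        for p in range(1, 11):
            for s in ("a", "b", "c"):
                if p == 4 and s == "b":
                    rows.append(make_counts(s, "chr1", p, "A", a=10, g=10))
                else:
                    rows.append(make_counts(s, "chr1", p, "A", a=20))
        df = counts_frame(rows)
        calls = call_unique_mutations(df, cfg, ["a", "b", "c"])
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row["sample"], row.chrom, row.pos, row.ref, row.alt) == (
            "b", "chr1", 4, "A", "G"
        )
        assert oracle_calls(df, cfg, ["a", "b", "c"]) == [
            ("b", "chr1", 4, "A", "G")
        ]

    def test_no_mutations_no_calls(self, small_reference):
        from mutaccum import synthetic as syn

        cohort = syn.CohortSpec(samples=[("a", "WT"), ("b", "WT")], seed=40)
        truth = syn.implant_mutations(small_reference, cohort)
        noise = syn.NoiseModel(mean_coverage=25, per_base_error=0.0)
        counts = syn.simulate_pileup_counts(small_reference, truth, noise, seed=41)
        calls = call_unique_mutations(counts) if len(counts) else counts
        assert len(calls) == 0

    def test_oracle_equivalence_random_tables(self, rng):
        cfg = CallerConfig()
        for i in range(60):
            n_samples = int(rng.integers(2, 6))
            n_positions = int(rng.integers(1, 51))
            df, samples = random_table(rng, n_samples, n_positions,
                                       with_indels=(i % 2 == 0))
            got = call_unique_mutations(df, cfg, samples)
            got_keys = sorted(
                (r["sample"], r.chrom, int(r.pos), r.ref, r.alt)
                for r in (row for _, row in got.iterrows())
            )
            assert got_keys == oracle_calls(df, cfg, samples)

    def test_monotonicity_in_thresholds(self, rng):
        base = CallerConfig()
        df, samples = random_table(rng, 4, 40, with_indels=True)
        n_base = len(call_unique_mutations(df, base, samples))
        for stricter in (
            CallerConfig(min_alt_allele_fraction=0.3),
            CallerConfig(min_mutated_coverage=10),
            CallerConfig(min_other_ref_fraction=0.98),
            CallerConfig(min_quality_score=3.0),
        ):
            assert len(call_unique_mutations(df, stricter, samples)) <= n_base

    def test_uniqueness_of_output_sites(self, small_cohort):
        _, _, counts = small_cohort
        calls = call_unique_mutations(counts)
        per_site = calls.groupby(["chrom", "pos"])["sample"].nunique()
        assert (per_site == 1).all()

    def test_unsorted_input_raises(self):
        rows = [
            make_counts("a", "chr1", 5, "A", a=20),
            make_counts("b", "chr1", 5, "A", a=20),
            make_counts("a", "chr1", 2, "A", a=20),
            make_counts("b", "chr1", 2, "A", a=20),
        ]
        df = counts_frame(rows).iloc[[2, 3, 0, 1]].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            call_unique_mutations(df, CallerConfig(), ["a", "b"])

    def test_missing_sample_position_skipped(self, caplog):
        rows = [
            make_counts("a", "chr1", 4, "A", a=10, g=10),
            make_counts("b", "chr1", 4, "A", a=20),
            # sample c missing at pos 4
            make_counts("a", "chr1", 9, "A", a=20),
            make_counts("b", "chr1", 9, "A", a=20),
            make_counts("c", "chr1", 9, "A", a=20),
        ]
        df = counts_frame(rows)
        with caplog.at_level("WARNING"):
            calls = call_unique_mutations(df, CallerConfig(), ["a", "b", "c"])
        assert len(calls) == 0
        assert any("skipped" in r.message for r in caplog.records)

    def test_long_indels_never_emitted(self):
        cfg = CallerConfig()
        long_del = "60:" + "A" * 60
        rows = [
            make_counts("a", "chr1", 4, "C", c=10, dele={long_del: 10}),
            make_counts("b", "chr1", 4, "C", c=20),
        ]
        calls = call_unique_mutations(counts_frame(rows), cfg, ["a", "b"])
        assert len(calls) == 0

    def test_chunking_independence(self, small_cohort):
        _, _, counts = small_cohort
        cfg = CallerConfig()
        whole = call_unique_mutations(counts, cfg)
        parts = []
        for chrom, grp in counts.groupby("chrom"):
            parts.append(call_unique_mutations(grp.reset_index(drop=True), cfg,
                                               sorted(counts["sample"].unique())))
        chunked = (
            pd.concat(parts, ignore_index=True)
            .sort_values(["chrom", "pos", "sample"], kind="mergesort")
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(whole, chunked)

    def test_detection_rate_on_simulated_cohort(self, small_reference):
        # miniature version of the coverage/detection benchmark
        from mutaccum import synthetic as syn

        cohort = syn.CohortSpec(
            samples=[("a", "WT"), ("b", "WT"), ("c", "WT")],
            per_sample_burdens={"a": 100, "b": 0, "c": 0}, seed=42,
        )
        truth = syn.implant_mutations(small_reference, cohort)
        noise = syn.NoiseModel(mean_coverage=25, per_base_error=0.002)
        counts = syn.simulate_pileup_counts(small_reference, truth, noise, seed=43)
        calls = call_unique_mutations(counts)
        truth_keys = {
            (r.sample, r.chrom, r.pos, r.ref, r.alt) for r in truth.records
        }
        call_keys = {
            (r["sample"], r.chrom, int(r.pos), r.ref, r.alt)
            for _, r in calls.iterrows()
        }
        assert len(truth_keys & call_keys) / len(truth_keys) >= 0.9
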