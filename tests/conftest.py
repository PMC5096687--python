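import numpy as np
import pandas as pd
import pytest

from mutaccum import synthetic as syn
from mutaccum.calling import PositionCounts


@pytest.fixture(scope="session")
def small_reference():
    spec = syn.SyntheticGenomeSpec([200_000, 100_000], gc_content=0.42, seed=11)
    return syn.generate_reference(spec)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    cohort = syn.CohortSpec(
        samples=[("s1", "WT"), ("s2", "WT"), ("s3", "MUT")],
        snv_burden=30,
        insertion_burden=3,
        deletion_burden=6,
        deletion_mix=(0.2, 0.5, 0.3),
        germline_het_density=1e-4,
        seed=21,
    )
    truth = syn.implant_mutations(small_reference, cohort)
    noise = syn.NoiseModel(mean_coverage=25, coverage_dispersion=0.0,
                           per_base_error=0.002)
    counts = syn.simulate_pileup_counts(small_reference, truth, noise, seed=31)
    return cohort, truth, counts


def make_counts(sample, chrom, pos, ref, a=0, c=0, g=0, t=0, ins=None,
                dele=None, depth=None):
    base = {"A": a, "C": c, "G": g, "T": t}
    d = depth if depth is not None else (
        sum(base.values())
        + sum((ins or {}).values())
        + sum((dele or {}).values())
    )
    return PositionCounts(
        sample_id=sample, chrom=chrom, pos=pos, ref_base=ref,
        base_counts=base, insertion_counts=ins or {}, deletion_counts=dele or {},
        depth=d,
    )


def counts_frame(rows):
    """Build a count-table DataFrame from PositionCounts objects."""
    recs = []
    for pc in rows:
        recs.append(
            {
                "sample": pc.sample_id, "chrom": pc.chrom, "pos": pc.pos,
                "ref_base": pc.ref_base,
                **{b: pc.base_counts.get(b, 0) for b in "ACGT"},
                "ins": ";".join(f"{k}:{v}" for k, v in pc.insertion_counts.items()),
                "del": ";".join(f"{k}:{v}" for k, v in pc.deletion_counts.items()),
                "depth": pc.depth,
            }
        )
    df = pd.DataFrame(recs)
    return df.sort_values(["chrom", "pos", "sample"], kind="mergesort").reset_index(
        drop=True
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
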