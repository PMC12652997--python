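import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ffpebench as fb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome():
    return fb.GenomeModel.toy()


@pytest.fixture(scope="session")
def small_truth(genome):
    """A small but fully featured truth set (multiallelics, failing filters)."""
    return fb.generate_truth(
        genome,
        fb.TruthParams(n_snv=600, n_indel=200, multiallelic_fraction=0.02,
                       fail_fraction=0.2, seed=31),
    )


@pytest.fixture(scope="session")
def medium_truth(genome):
    """~25k-record truth set for statistical recovery checks."""
    return fb.generate_truth(
        genome, fb.TruthParams(n_snv=20_000, n_indel=5_000, seed=77)
    )


def make_callset(samples, entries, provenance="test"):
    """Build a CallSet from (contig, pos, ref, alt, [gt_str...], extras) tuples.

    gt_str like "0/1", "1|0", "./." or "./1"; extras is an optional dict of
    VariantRecord fields (qual, annotations, impact, multiallelic_origin).
    """
    cs = fb.CallSet(samples, provenance=provenance)
    for entry in entries:
        contig, pos, ref, alt, gts = entry[:5]
        extras = entry[5] if len(entry) > 5 else {}
        calls = []
        for g in gts:
            phased = "|" in g
            a, b = g.replace("|", "/").split("/")
            calls.append(fb.genotype(None if a == "." else int(a),
                                     None if b == "." else int(b), phased))
        cs.add(fb.VariantRecord(key=fb.AlleleKey(contig, pos, ref, alt),
                                genotypes=tuple(calls), **extras))
    return cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
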