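"""Shared fixtures: tiny hand-checkable alignments and simulated datasets."""

import numpy as np
import pytest

from mitopop import coalsim
from mitopop.iohap import Alignment, PopulationMap


@pytest.fixture
def toy_trio() -> Alignment:
    """3 sequences, 4 sites: pairwise differences 1, 1, 2."""
    return Alignment.from_records([("a", "AAAA"), ("b", "AAAT"), ("c", "CAAA")])


@pytest.fixture
def toy_quartet() -> Alignment:
    """4 sequences collapsing to 3 haplotypes with counts 1, 2, 1."""
    return Alignment.from_records(
        [("a", "AAAA"), ("b", "AAAT"), ("c", "AAAT"), ("d", "CAAA")]
    )


@pytest.fixture
def toy_five() -> Alignment:
    """n=5, 12 sites; mixed singleton/shared variants, no gaps.

    Columns (0-based) with variation: 1 (C singleton in s2), 3 (T in s3,s4),
    5 (G singleton in s5), 8 (A singleton in s1), 10 (C/T split 2/3).
    """
    return Alignment.from_records([
        ("s1", "AATGCTACATCA"),
        ("s2", "ACTGCTACGTCA"),
        ("s3", "AATTCTACGTTA"),
        ("s4", "AATTCTACGTTA"),
        ("s5", "AATGCGACGTTA"),
    ])


@pytest.fixture
def neutral_sample() -> Alignment:
    aln, _ = coalsim.simulate_dataset(
        coalsim.DemographyModel.constant(theta=5.0, n=12), seed=2024
    )
    return aln


@pytest.fixture
def expansion_sample() -> Alignment:
    aln, _ = coalsim.simulate_dataset(
        coalsim.DemographyModel.stepwise_expansion(
            theta0=0.0, theta1=16.98, tau=4.56, n=40
        ),
        seed=2025,
    )
    return aln


@pytest.fixture
def two_pop_dataset() -> tuple[Alignment, Alignment]:
    m = coalsim.DemographyModel.split_with_migration(
        theta=5.0, M=0.0, T=2.0, n1=8, n2=8
    )
    aln, pmap = coalsim.simulate_dataset(m, seed=91)
    ids1 = [i for i in aln.ids if pmap.group_of(i) == "G1"]
    ids2 = [i for i in aln.ids if pmap.group_of(i) == "G2"]
    return aln.subset(ids1), aln.subset(ids2)


def grouped_alignment(group_specs, seed=0):
    """Concatenate per-group simulations into one alignment + map.

    group_specs: list of (label, DemographyModel).
    """
    rng = np.random.default_rng(seed)
    recs, assigns = [], {}
    for label, model in group_specs:
        sub_seed = int(rng.integers(2**31))
        aln, _ = coalsim.simulate_dataset(model, seed=sub_seed)
        for sid, seq in zip(aln.ids, aln.seqs):
            nid = f"{label}_{sid}"
            recs.append((nid, seq))
            assigns[nid] = (f"{label}loc", label)
    return Alignment.from_records(recs), PopulationMap(assigns)
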