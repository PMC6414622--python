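import pytest

from clonevo import AnalysisParams, CohortConfig, VariantCall, generate


def make_variant(patient_id="P1", chrom="1", pos=1000, ref="A", alt="T",
                 gene="GENE1", effect="missense", alt_id=0, depth_id=100,
                 alt_rel=0, depth_rel=100):
    return VariantCall(patient_id=patient_id, chrom=chrom, pos=pos, ref=ref,
                       alt=alt, gene=gene, effect=effect, alt_id=alt_id,
                       depth_id=depth_id, alt_rel=alt_rel, depth_rel=depth_rel)


@pytest.fixture
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-patient default-condition cohort with ground truth."""
    patients, chrom_lengths, truth = generate(CohortConfig(n_patients=50, seed=11))
    return patients, chrom_lengths, truth


@pytest.fixture(scope="session")
def preset_cohort():
    """The published-table preset cohort (25/25 early-late, 26/24 ped-adult)."""
    from clonevo import preset_table1

    patients, chrom_lengths, truth = generate(preset_table1(seed=5))
    return patients, chrom_lengths, truth
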