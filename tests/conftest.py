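import numpy as np
import pytest

from ncmkit.tables import AbundanceTable, Cohort, SampleRecord


def make_table(counts, taxa=None, samples=None) -> AbundanceTable:
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return AbundanceTable(tuple(taxa), tuple(samples), counts)


def infant(sample_id, subject, age, village="V1", dyad=None, site="stool", country="X"):
    return SampleRecord(sample_id, subject, "infant", site, age, country,
                        dyad_id=dyad, village=village, village_type="forest")


def mother(sample_id, subject, dyad, village="V1", site="stool", country="X"):
    return SampleRecord(sample_id, subject, "mother", site, 300.0, country,
                        dyad_id=dyad, village=village, village_type="forest")


@pytest.fixture
def mixed_cohort() -> Cohort:
    """3 taxa, 5 samples mixing roles and body sites."""
    counts = np.array(
        [
            [5, 0, 3, 1, 2],
            [1, 2, 0, 4, 0],
            [0, 7, 1, 0, 6],
        ]
    )
    records = (
        infant("i_stool_1", "S1", 3.0, dyad="D1"),
        infant("i_tongue_1", "S1", 3.0, dyad="D1", site="tongue"),
        infant("i_stool_2", "S2", 9.5, dyad="D2"),
        mother("m_stool_1", "M1", "D1"),
        mother("m_tongue_1", "M1", "D1", site="tongue"),
    )
    table = make_table(
        counts, samples=[r.sample_id for r in records]
    )
    return Cohort(table, records)


@pytest.fixture
def dyad_cohort() -> Cohort:
    """Hand-built dyad fixture: infant I1 carries all 10 taxa; 4 are in the
    mother's stool, 3 only in another village adult's stool, 3 nowhere."""
    taxa = [f"t{i}" for i in range(10)]
    presence = {
        # infant stool: all ten taxa
        "I1": [1] * 10,
        # mother same-site (stool, two time points): t0..t3
        "M1a": [5, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        "M1b": [2, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        # mother other-site (tongue): subset of same-site taxa
        "M1t": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        # same-village unrelated mother, stool: t4..t6
        "M2a": [1, 0, 0, 0, 3, 2, 1, 0, 0, 0],
        # her infant, for sharing-rate denominators
        "I2": [1, 0, 0, 0, 1, 1, 0, 0, 0, 0],
    }
    records = (
        infant("I1", "S_I1", 4.0, dyad="D1"),
        mother("M1a", "S_M1", "D1"),
        mother("M1b", "S_M1", "D1"),
        mother("M1t", "S_M1", "D1", site="tongue"),
        mother("M2a", "S_M2", "D2"),
        infant("I2", "S_I2", 10.0, dyad="D2"),
    )
    cols = [presence[r.sample_id] for r in records]
    table = make_table(np.array(cols).T, taxa=taxa,
                       samples=[r.sample_id for r in records])
    return Cohort(table, records)
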