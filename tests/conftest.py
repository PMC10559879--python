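import numpy as np
import pandas as pd
import pytest

from redoxtmt import SampleDesign, PeptideTable, SimulationConfig, simulate
from redoxtmt.model import DESIGN_COLUMNS


def make_design_frame(rows):
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


@pytest.fixture
def mini_design():
    """One proteome mix and one redox mix for a single replicate/timepoint."""
    rows = [
        ("prot-1", "126", 1, 1, "4h", "control", "NA", "proteome"),
        ("prot-1", "127", 1, 1, "4h", "treated", "NA", "proteome"),
        ("redox-1", "126", 1, 1, "4h", "control", "TMT1", "redoxome"),
        ("redox-1", "127", 1, 1, "4h", "treated", "TMT1", "redoxome"),
        ("redox-1", "128", 1, 1, "4h", "control", "TMT2", "redoxome"),
        ("redox-1", "129", 1, 1, "4h", "treated", "TMT2", "redoxome"),
    ]
    return SampleDesign(make_design_frame(rows))


def make_peptide_table(rows, channels):
    """rows: (mix, accession, sequence, sites, {channel: value})."""
    records = []
    for mix, acc, seq, sites, intensities in rows:
        row = {
            "mix_id": mix,
            "protein_accession": acc,
            "peptide_sequence": seq,
            "sites": sites,
        }
        for ch in channels:
            row[ch] = intensities.get(ch, np.nan)
        records.append(row)
    return PeptideTable(pd.DataFrame(records), list(channels))


@pytest.fixture(scope="session")
def small_experiment():
    """A complete small simulated experiment shared across tests."""
    return simulate(SimulationConfig(seed=11, n_proteins=60))
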