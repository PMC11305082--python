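import warnings

import numpy as np
import pytest

from sipef.core_io import SampleMeta
from sipef.preprocess import AbundanceTable
from sipef.synthetic import SimConfig, default_incorporators, simulate_experiment


@pytest.fixture
def tiny_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "taxon_id\tS1\tS2\n"
        "t1\t5\t0\n"
        "t2\t10\t2\n"
        "t3\t0\t8\n"
    )
    return path


@pytest.fixture
def tiny_sheet_tsv(tmp_path):
    path = tmp_path / "sheet.tsv"
    path.write_text(
        "sample_id\tsoil\tisotope\tpool\treplicate\tday\n"
        "S1\tST\t13C\theavy\t1\t0\n"
        "S2\tST\t13C\tlight\t1\t0\n"
    )
    return path


def full_design_sheet(days=(0, 7, 15, 30), replicates=3):
    """The complete 2-soil x 2-isotope x replicate x day x pool sheet."""
    sheet = []
    for soil in ("ST", "LT"):
        for isotope in ("13C", "12C"):
            for rep in range(1, replicates + 1):
                for day in days:
                    for pool in ("heavy", "light"):
                        sheet.append(
                            SampleMeta(
                                sample_id=f"{soil}_{isotope}_r{rep}_d{day}_{pool}",
                                soil=soil,
                                isotope=isotope,
                                pool=pool,
                                replicate=rep,
                                day=day,
                            )
                        )
    return sheet


@pytest.fixture
def design_sheet():
    return full_design_sheet()


def abundance_from_shares(sheet, genus_shares):
    """Build a two-taxon AbundanceTable realising given heavy shares.

    ``genus_shares`` maps sample_id -> relative abundance of taxon "gX";
    the remainder goes to a filler taxon so columns sum to 1.
    """
    samples = [m.sample_id for m in sheet]
    values = np.zeros((2, len(samples)))
    for j, sid in enumerate(samples):
        ra = genus_shares.get(sid, 0.0)
        values[0, j] = ra
        values[1, j] = 1.0 - ra
    return AbundanceTable(["gX", "filler"], samples, values)


@pytest.fixture(scope="session")
def small_sim():
    """A small labelled simulation shared across tests (speed)."""
    config = SimConfig(n_genera=25, depth=4000, seed=11)
    config.incorporators = default_incorporators(config, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, truth = simulate_experiment(config)
    return config, bundle, truth
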