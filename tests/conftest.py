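import numpy as np
import pandas as pd
import pytest

from magicscan import (CrossingScheme, GeneticMap, default_config,
                       simulate_dataset, simulate_founders, simulate_magic_dh)

SMALL_CONFIG = {
    "marker_spacing_cM": 2.0,
    "n_lines": 200,
    "missing_rate": 0.0,
    "traits": {
        "TKW": {"mean": 50.0, "treatment_effects": {"WW": 0.0, "TD": -3.0},
                "polygenic_variance": 4.0, "year_variance": 1.0,
                "line_treatment_variance": 0.5, "residual_variance": 4.0,
                "qtls": [{"chromosome": "2H", "position_cM": 20.0,
                          "founder_effects": {"Ragusa": 6.0},
                          "treatment_interaction": {"TD": 1.5}}]},
        "NK": {"mean": 21.0, "treatment_effects": {"WW": 0.0, "TD": -4.0},
               "polygenic_variance": 3.0, "year_variance": 0.5,
               "line_treatment_variance": 0.5, "residual_variance": 3.0,
               "qtls": []},
    },
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_chrom_map():
    return GeneticMap.uniform({"1H": 100.0, "2H": 100.0}, spacing_cM=5.0)


@pytest.fixture(scope="session")
def small_dataset():
    """200 DH lines, two traits, one strong planted QTL (TKW on 2H)."""
    return simulate_dataset(SMALL_CONFIG, seed=7)


@pytest.fixture(scope="session")
def magic_genotypes():
    """Medium MAGIC genotype panel reused across scan tests: 300 lines,
    ~350 markers over 7 chromosomes."""
    cfg = default_config()
    gmap = GeneticMap.uniform(cfg["chrom_lengths"], spacing_cM=3.0)
    rng = np.random.default_rng(99)
    scheme = CrossingScheme(tuple(cfg["founders"]))
    alleles = simulate_founders(gmap, (0.125, 0.5), 8, rng)
    mosaic, genotypes = simulate_magic_dh(scheme, alleles, gmap, 300, rng)
    return gmap, mosaic, genotypes
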