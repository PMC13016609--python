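import numpy as np
import pytest

import mtbind as m


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down chamber simulation (600-nt genome) for fast tests."""
    return m.SimulationConfig(seed=7, genome_length=600, n_controls=40,
                              replicates=5)


@pytest.fixture(scope="session")
def small_library(small_config):
    genome = m.simulate_genome(small_config)
    return m.tile_circular_genome(genome, window=small_config.window,
                                  step=small_config.step)


@pytest.fixture(scope="session")
def small_chamber_pair(small_config, small_library):
    landscape = m.simulate_landscape(small_library, small_config)
    no_uv, uv = m.simulate_chamber_pair(small_library, landscape,
                                        small_config)
    return no_uv, uv, landscape


@pytest.fixture(scope="session")
def full_config():
    """Study-scale conditions: 16,569-nt genome, 116 controls, 10 reps."""
    return m.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def full_run(full_config):
    """One study-scale chamber pair taken through the whole pipeline."""
    genome = m.simulate_genome(full_config)
    library = m.tile_circular_genome(genome)
    landscape = m.simulate_landscape(library, full_config)
    no_uv, uv = m.simulate_chamber_pair(library, landscape, full_config)
    z_no = m.chamber_to_zscores(no_uv)
    z_uv = m.chamber_to_zscores(uv)
    return {
        "config": full_config,
        "genome": genome,
        "library": library,
        "landscape": landscape,
        "chambers": (no_uv, uv),
        "zscores": (z_no, z_uv),
    }
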