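import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from straitgen.io_core import Raster
from straitgen.synthetic_world import (default_config, generate_world,
                                       simulate_haplotypes,
                                       simulate_presences)


@pytest.fixture(scope="session")
def world_bundle():
    """Default synthetic world (seed 1) shared by the slower tests."""
    cfg = default_config(seed=1)
    world = generate_world(cfg)
    aln, loc, truth = simulate_haplotypes(cfg, world)
    presences = simulate_presences(cfg, world)
    return {"cfg": cfg, "world": world, "aln": aln, "loc": loc,
            "truth": truth, "presences": presences}


@pytest.fixture
def small_raster():
    """5x4 template raster covering lon [0,4), lat [10,15)."""
    return Raster(nrows=5, ncols=4, x_origin=0.0, y_origin=10.0,
                  cell_size=1.0, nodata=-9999.0,
                  values=np.zeros((5, 4)))
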