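import numpy as np
import pytest

from mediaperm import (BinaryMicrostructure, SolverConfig,
                       generate_microstructure, preset_params)


@pytest.fixture(scope="session")
def baseline_micro():
    """One baseline-preset microstructure (64^3, seed 1), shared read-only."""
    return generate_microstructure(preset_params("baseline", seed=1))


@pytest.fixture(scope="session")
def rendered_baseline():
    """Emulated confocal stack of the baseline microstructure plus its
    generating mask (ground truth for recovery tests)."""
    from mediaperm import ConfocalEmulationParams, render_confocal

    micro = generate_microstructure(preset_params("baseline", seed=7))
    emu = ConfocalEmulationParams(seed=7)
    return micro, render_confocal(micro, emu)


@pytest.fixture(scope="session")
def cube_micro():
    """Periodic cell with a centred impermeable cube filling 12.5% of the
    volume: the canonical single-inclusion flow fixture."""
    mask = np.ones((16, 16, 16), dtype=bool)
    mask[4:12, 4:12, 4:12] = False
    return BinaryMicrostructure(mask, (1.25, 1.25, 1.25))


@pytest.fixture(scope="session")
def solver_cfg():
    return SolverConfig()


def ellipse_slice_mask(shape=(64, 64), center=(32, 32), semi=(8, 20)):
    """2D boolean ellipse (True inside)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (((yy - center[0]) / semi[0]) ** 2
            + ((xx - center[1]) / semi[1]) ** 2) <= 1


def cells_to_micro(cell_mask_2d):
    """Wrap a 2D cell-phase mask into a 3-slice microstructure whose middle
    slice carries the cells (mask True = ECM, False = cell)."""
    mask = np.ones(cell_mask_2d.shape + (3,), dtype=bool)
    mask[..., 1] = ~cell_mask_2d
    return BinaryMicrostructure(mask, (1.0, 1.0, 1.0))
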