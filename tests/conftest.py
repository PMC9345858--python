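import numpy as np
import pandas as pd
import pytest

from tcellprox.cell_io import CellClass, CoreSample, Marker, Region, Window


def make_core(
    tumour_xy,
    tcell_xy=(),
    other_xy=(),
    *,
    core_id="c1",
    patient_id="P1",
    region=Region.CT,
    marker=Marker.CD3,
    window=None,
):
    """Assemble a CoreSample from explicit coordinate lists."""
    rows = []
    for xy, cls in (
        (tumour_xy, CellClass.TUMOUR),
        (tcell_xy, CellClass.T_CELL),
        (other_xy, CellClass.OTHER),
    ):
        for x, y in xy:
            rows.append({"x": float(x), "y": float(y), "cell_class": cls})
    cells = pd.DataFrame(rows, columns=["x", "y", "cell_class"])
    return CoreSample(
        core_id=core_id, patient_id=patient_id, region=region, marker=marker,
        cells=cells, window=window,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def disc_window():
    return Window.disc(0.0, 0.0, 500.0)


def random_core(rng, n_tumour, n_tcell, radius=500.0, **meta):
    """Uniform random core inside a disc window, for oracle comparisons."""
    def uniform(n):
        r = radius * np.sqrt(rng.random(n))
        a = 2 * np.pi * rng.random(n)
        return np.column_stack([r * np.cos(a), r * np.sin(a)])

    return make_core(
        uniform(n_tumour), uniform(n_tcell),
        window=Window.disc(0.0, 0.0, radius), **meta,
    )
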