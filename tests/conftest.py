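import numpy as np
import pytest

import thermolead as tl
from thermolead import synthetic_data as synth


@pytest.fixture(scope="session")
def hexa_library():
    return tl.enumerate_library(synth.HEXA_LIBRARY)


@pytest.fixture(scope="session")
def hexa_classes(hexa_library):
    return tl.isobaric_classes(hexa_library)


def relaxation_series_from_table(frame):
    pivot = frame.pivot_table(index="delay_s", columns="region", values="intensity")
    return tl.RelaxationSeries(
        pivot.index.to_numpy(), {str(c): pivot[c].to_numpy() for c in pivot.columns}
    )


def titration_series_from_table(frame, receptor_total):
    return [
        tl.TitrationSeries(
            g["conc_M"].to_numpy(), g["signal"].to_numpy(), receptor_total, replicate=r
        )
        for r, g in frame.groupby("replicate")
    ]


def dose_series_from_table(frame):
    return [
        tl.DoseResponseSeries(g["conc_M"].to_numpy(), g["response"].to_numpy(), r)
        for r, g in frame.groupby("replicate")
    ]
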