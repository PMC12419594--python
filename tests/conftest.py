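import numpy as np
import pandas as pd
import pytest

from musselscape.data import CatchmentFrame


@pytest.fixture
def toy_frame():
    """Six catchments in two HUC10s of one HUC8; HUC10 B entirely unsurveyed."""
    df = pd.DataFrame(
        {
            "catchment_id": [f"c{i}" for i in range(1, 7)],
            "huc12": ["0000000100A1"] * 3 + ["0000000100B1"] * 3,
            "huc10": ["0000000100"] * 3 + ["0000000101"] * 3,
            "huc8": ["00000001"] * 6,
            "state": ["MA"] * 6,
            "centroid_x": np.arange(6, dtype=float),
            "centroid_y": np.zeros(6),
            "survey_count": [4, 2, 0, 0, 0, 0],
        }
    )
    return CatchmentFrame(df)


@pytest.fixture
def nested_frame():
    """2 HUC8s x 2 HUC10s x 1 HUC12 x 2 catchments, all surveyed once."""
    rows = []
    k = 0
    for i8 in range(2):
        for i10 in range(2):
            for ic in range(2):
                rows.append(
                    {
                        "catchment_id": f"c{k}",
                        "huc12": f"{i8:08d}{i10:02d}00",
                        "huc10": f"{i8:08d}{i10:02d}",
                        "huc8": f"{i8:08d}",
                        "state": "ME" if i8 else "VT",
                        "centroid_x": float(k),
                        "centroid_y": 0.0,
                        "survey_count": 1,
                    }
                )
                k += 1
    return CatchmentFrame(pd.DataFrame(rows))
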