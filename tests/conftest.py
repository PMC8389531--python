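import numpy as np
import pandas as pd
import pytest

from uqmd.synthetic import InputParameter, InputSpace, MockConfig, mock_esmacs
from uqmd.tables import EvaluationTable


def unit_space(d: int) -> InputSpace:
    """Input space that is literally the unit cube (identity affine map)."""
    return InputSpace(
        tuple(InputParameter(f"x{i}", 0.5, 0.0, 1.0) for i in range(d))
    )


@pytest.fixture
def mock_table():
    """A small complete campaign table from the default synthetic model."""
    cfg = MockConfig(seeds=tuple(range(1, 11)))
    space = cfg.input_space
    rng = np.random.default_rng(11)
    unit = rng.uniform(size=(12, space.dimension))
    rows = []
    for cid, u in enumerate(unit):
        x = space.to_physical(u)
        for s in cfg.seeds:
            rows.append(
                {"config_id": cid, **dict(zip(space.names, x)),
                 "seed": s, "energy": mock_esmacs(cfg, x, s)}
            )
    return EvaluationTable(pd.DataFrame(rows))


def table_from_matrix(E: np.ndarray) -> EvaluationTable:
    """Build a minimal table from a configs x seeds energy matrix."""
    n_cfg, n_seed = E.shape
    rows = [
        {"config_id": c, "x0": 0.1 + 0.8 * c / max(n_cfg - 1, 1),
         "seed": s + 1, "energy": float(E[c, s])}
        for c in range(n_cfg)
        for s in range(n_seed)
    ]
    return EvaluationTable(pd.DataFrame(rows))
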