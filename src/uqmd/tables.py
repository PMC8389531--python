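"""The evaluation table: the bridge between the sampler and the simulator.

One row per (parametric configuration, random seed) pair, carrying the
configuration id, the physical input values, the seed and the resulting
binding energy in kcal/mol.  The same fixed seed list must appear for every
configuration — the ensemble protocol reuses identical seeds across
configurations so that per-seed statistics are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = ["EvaluationTable"]

_META_COLS = ("config_id", "seed", "energy")


@dataclass
class EvaluationTable:
    """Validated wrapper around the (config, seed) -> energy long table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"evaluation table missing columns {missing}")
        if self.frame.duplicated(["config_id", "seed"]).any():
            raise ValueError("duplicate (config_id, seed) pairs")

    # ---- construction / IO --------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "EvaluationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # ---- structure -----------------------------------------------------
    @property
    def input_names(self) -> List[str]:
        return [c for c in self.frame.columns if c not in _META_COLS]

    @property
    def config_ids(self) -> np.ndarray:
        return np.sort(self.frame["config_id"].unique())

    @property
    def seeds(self) -> np.ndarray:
        return np.sort(self.frame["seed"].unique())

    @property
    def n_configs(self) -> int:
        return self.config_ids.size

    @property
    def n_seeds(self) -> int:
        return self.seeds.size

    def require_complete(self) -> None:
        """Raise unless every configuration carries the identical seed list."""
        counts = self.frame.groupby("config_id")["seed"].apply(
            lambda s: tuple(np.sort(s))
        )
        expected = tuple(self.seeds)
        bad = [cid for cid, t in counts.items() if t != expected]
        if bad:
            raise ValueError(
                f"ragged seed coverage: configurations {bad[:5]} do not carry "
                f"the common seed list"
            )

    # ---- views ----------------------------------------------------------
    def energy_matrix(self) -> pd.DataFrame:
        """Configurations x seeds pivot of energies (complete tables only)."""
        self.require_complete()
        return self.frame.pivot(index="config_id", columns="seed", values="energy")

    def per_config_means(self) -> pd.Series:
        """Ensemble-averaged energy per configuration (epistemic view)."""
        return self.energy_matrix().mean(axis=1)

    def per_seed_means(self) -> pd.Series:
        """Energy averaged over configurations per seed (aleatoric view)."""
        return self.energy_matrix().mean(axis=0)

    def energies(self) -> np.ndarray:
        return self.frame["energy"].to_numpy()

    def config_inputs(self) -> pd.DataFrame:
        """One row of physical input values per configuration."""
        cols = ["config_id", *self.input_names]
        return (
            self.frame[cols].drop_duplicates("config_id").set_index("config_id").sort_index()
        )

    def ensemble(self, config_id) -> np.ndarray:
        """Replica energies of one configuration, ordered by seed."""
        sub = self.frame[self.frame["config_id"] == config_id]
        return sub.sort_values("seed")["energy"].to_numpy()
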