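"""Coefficient-of-variation bookkeeping and the uncertainty amplification factor.

The coefficient of variation CV(X) = sigma_X / mu_X is a dimensionless
variability measure, which makes inputs and outputs on wildly different
scales comparable.  The amplification factor CVR is the ratio of the output
CV to the mean input CV (absolute values throughout): CVR > 1 means the code
amplifies the assumed input uncertainty, CVR < 1 means it damps it.

Two output conventions are supported.  In *ensemble* mode the output is the
ensemble-averaged binding energy per configuration, so aleatoric spread is
averaged away before the CV is taken.  In *per-seed* mode the CV over
configurations is computed for each replica seed separately and the absolute
CVs are averaged — the uncertainty one would face without ensemble
averaging.  The mean of per-seed spreads always dominates the spread of the
ensemble mean, so the per-seed CVR is an upper bound on the ensemble CVR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .tables import EvaluationTable

__all__ = [
    "CVReport",
    "uniform_cv",
    "mean_input_cv",
    "cvr_from_cvs",
    "cvr_ensemble",
    "cvr_per_seed",
]


def uniform_cv(lo: float, hi: float) -> float:
    """Analytic |CV| of a uniform distribution on [lo, hi].

    sd = (hi - lo) / sqrt(12), mean = (lo + hi) / 2.  For bounds at
    +/-15% of a positive nominal this is 0.15 / sqrt(3) ~= 0.0866,
    independent of the nominal value.
    """
    if lo > hi:
        raise ValueError(f"invalid bounds: lo={lo} > hi={hi}")
    mean = 0.5 * (lo + hi)
    if mean == 0.0:
        raise ValueError("uniform CV undefined for zero mean")
    return abs(((hi - lo) / math.sqrt(12.0)) / mean)


def mean_input_cv(input_space, assume_pm15: bool = False) -> float:
    """Average of the d input CVs (seeds are never part of the input side).

    With ``assume_pm15`` every input — including any input with a specially
    restricted range such as the temperature — is treated as +/-15% about its
    nominal, i.e. CV = 0.15/sqrt(3) for all, the convention under which the
    mean input CV of the study space rounds to 0.087.
    """
    if assume_pm15:
        return 0.15 / math.sqrt(3.0)
    return float(np.mean([uniform_cv(p.lo, p.hi) for p in input_space.parameters]))


def cvr_from_cvs(output_cv: float, input_cv: float) -> float:
    """Amplification factor from already-computed CVs: |output| / |input|."""
    if input_cv == 0.0:
        raise ValueError("mean input CV is zero; CVR undefined")
    return abs(output_cv) / abs(input_cv)


@dataclass
class CVReport:
    """Input CVs, output CV and their ratio in one of the two modes."""

    mode: str  # "ensemble" | "per_seed"
    input_cvs: Dict[str, float]
    mean_input_cv: float
    output_cv: float
    cvr: float
    per_seed_cvs: Optional[Dict[int, float]] = None

    @property
    def amplifies(self) -> bool:
        return self.cvr > 1.0

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "mean_input_cv": self.mean_input_cv,
            "output_cv": self.output_cv,
            "cvr": self.cvr,
            "amplifies": self.amplifies,
            "input_cvs": self.input_cvs,
        }
        if self.per_seed_cvs is not None:
            out["per_seed_cvs"] = {str(k): v for k, v in self.per_seed_cvs.items()}
        return out


def _sample_cv(x: np.ndarray, ddof: int) -> float:
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("output mean is zero; CV undefined")
    return abs(float(np.std(x, ddof=ddof)) / mean)


def cvr_ensemble(
    table: EvaluationTable,
    input_space,
    assume_pm15: bool = False,
    ddof: int = 1,
) -> CVReport:
    """CVR with ensemble averaging: output CV of per-configuration means."""
    table.require_complete()
    in_cvs = {p.name: uniform_cv(p.lo, p.hi) for p in input_space.parameters}
    mcv = mean_input_cv(input_space, assume_pm15=assume_pm15)
    out_cv = _sample_cv(table.per_config_means().to_numpy(), ddof)
    return CVReport(
        mode="ensemble",
        input_cvs=in_cvs,
        mean_input_cv=mcv,
        output_cv=out_cv,
        cvr=cvr_from_cvs(out_cv, mcv),
    )


def cvr_per_seed(
    table: EvaluationTable,
    input_space,
    assume_pm15: bool = False,
    ddof: int = 1,
) -> CVReport:
    """CVR without ensemble averaging: mean of the per-seed |CV| values.

    For each replica seed the CV of the energy over configurations is taken;
    the output CV is the average of those absolute values over the S seeds.
    """
    table.require_complete()
    in_cvs = {p.name: uniform_cv(p.lo, p.hi) for p in input_space.parameters}
    mcv = mean_input_cv(input_space, assume_pm15=assume_pm15)
    mat = table.energy_matrix()
    per_seed = {int(s): _sample_cv(mat[s].to_numpy(), ddof) for s in mat.columns}
    out_cv = float(np.mean(list(per_seed.values())))
    return CVReport(
        mode="per_seed",
        input_cvs=in_cvs,
        mean_input_cv=mcv,
        output_cv=out_cv,
        cvr=cvr_from_cvs(out_cv, mcv),
        per_seed_cvs=per_seed,
    )
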