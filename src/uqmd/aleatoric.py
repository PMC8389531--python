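"""Seed-driven (aleatoric) uncertainty analysis of replica ensembles.

Fixing the random seed and sweeping the parametric configurations yields one
empirical cdf of the binding energy per seed.  The family of per-seed cdfs is
summarized by its probability box (p-box): the pointwise lower and upper
envelopes.  The horizontal width of the p-box is governed by aleatoric
(seed-induced) spread, the slant of each member cdf by parametric spread.
Confidence intervals read off the envelopes are conservative by construction
— they bound the interval of every member cdf.

Per-configuration ensembles are further characterized by their skewness and
excess kurtosis with percentile-bootstrap confidence intervals, and binned
into the conventional symmetry regions: A (|skew| < 0.5, approximately
symmetric), B (0.5 <= |skew| <= 1, moderately skewed), C (|skew| > 1, highly
skewed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tables import EvaluationTable

__all__ = [
    "ECDF",
    "PBox",
    "ShapeEntry",
    "ShapeReport",
    "ecdf",
    "pbox",
    "pbox_interval",
    "shape_stats",
    "shape_report",
    "ensemble_vs_parametric",
    "skewness_region",
]


@dataclass(frozen=True)
class ECDF:
    """Right-continuous empirical cdf F(x) = #{samples <= x} / n."""

    sorted_samples: np.ndarray

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.sorted_samples, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out

    @property
    def n(self) -> int:
        return self.sorted_samples.size

    def inverse(self, q: float) -> float:
        """Generalized inverse min{x : F(x) >= q} (left-continuous infimum).

        The index ceil(q n) - 1 is computed with a relative tolerance so a
        level like (1 - 0.95)/2, which is not exactly representable, still
        lands on the intended order statistic.
        """
        if not 0.0 < q <= 1.0:
            raise ValueError("quantile level must be in (0, 1]")
        qn = q * self.n
        k = int(np.ceil(qn - 1e-9 * max(1.0, qn))) - 1
        return float(self.sorted_samples[min(max(k, 0), self.n - 1)])


def ecdf(samples: Sequence[float]) -> ECDF:
    """Empirical cdf of a sample; ties counted with multiplicity."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf requires at least one sample")
    return ECDF(np.sort(arr))


@dataclass
class PBox:
    """Envelope of per-seed empirical cdfs over parametric configurations."""

    per_seed_cdfs: Dict[int, ECDF]

    @property
    def support(self) -> np.ndarray:
        """Union of all jump locations, sorted."""
        return np.unique(
            np.concatenate([c.sorted_samples for c in self.per_seed_cdfs.values()])
        )

    def lower(self, x) -> np.ndarray | float:
        """Lower envelope: pointwise minimum over the per-seed cdfs."""
        vals = np.stack([c(np.atleast_1d(x)) for c in self.per_seed_cdfs.values()])
        out = vals.min(axis=0)
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    def upper(self, x) -> np.ndarray | float:
        """Upper envelope: pointwise maximum over the per-seed cdfs."""
        vals = np.stack([c(np.atleast_1d(x)) for c in self.per_seed_cdfs.values()])
        out = vals.max(axis=0)
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    def lower_inverse(self, q: float) -> float:
        """min{x : lower(x) >= q} — the largest of the per-seed quantiles."""
        return max(c.inverse(q) for c in self.per_seed_cdfs.values())

    def upper_inverse(self, q: float) -> float:
        """min{x : upper(x) >= q} — the smallest of the per-seed quantiles."""
        return min(c.inverse(q) for c in self.per_seed_cdfs.values())


def pbox(table: EvaluationTable) -> PBox:
    """Build the p-box from an evaluation table (>= 2 configurations per seed)."""
    table.require_complete()
    if table.n_configs < 2:
        raise ValueError("p-box needs at least 2 configurations per seed")
    mat = table.energy_matrix()
    return PBox(
        per_seed_cdfs={int(s): ecdf(mat[s].to_numpy()) for s in mat.columns}
    )


def pbox_interval(p: PBox, level: float = 0.95) -> Tuple[float, float, float]:
    """Conservative central interval read off the p-box envelopes.

    The lower endpoint is the generalized inverse of the *upper* envelope at
    (1-level)/2 and the upper endpoint that of the *lower* envelope at
    1-(1-level)/2, so the interval contains the corresponding central interval
    of every member cdf.  Returns (lo, hi, width).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo = p.upper_inverse(alpha)
    hi = p.lower_inverse(1.0 - alpha)
    return lo, hi, hi - lo


def per_seed_intervals(p: PBox, level: float = 0.95) -> pd.DataFrame:
    """Central interval of each member cdf individually (seed fixed)."""
    alpha = (1.0 - level) / 2.0
    rows = []
    for seed, c in p.per_seed_cdfs.items():
        lo, hi = c.inverse(alpha), c.inverse(1.0 - alpha)
        rows.append({"seed": seed, "lo": lo, "hi": hi, "width": hi - lo})
    return pd.DataFrame(rows).set_index("seed")


def skewness_region(skew: float) -> str:
    """A: |skew| < 0.5; B: 0.5 <= |skew| <= 1; C: |skew| > 1."""
    a = abs(skew)
    return "A" if a < 0.5 else ("B" if a <= 1.0 else "C")


@dataclass
class ShapeEntry:
    """Shape statistics of one replica ensemble."""

    skewness: float
    excess_kurtosis: float
    skew_ci: Tuple[float, float]
    kurt_ci: Tuple[float, float]
    region: str
    defined: bool = True


def shape_stats(
    samples: Sequence[float],
    n_boot: int = 2000,
    ci_level: float = 0.90,
    seed: int = 0,
    bias: bool = True,
) -> ShapeEntry:
    """Skewness, excess kurtosis and percentile-bootstrap confidence intervals.

    Moment-based (biased) estimators by default: skewness m3 / m2^{3/2} and
    excess kurtosis m4 / m2^2 - 3 with central sample moments m_k.  Setting
    ``bias=False`` switches to the bias-corrected variants.  The bootstrap
    resamples the replicas with replacement ``n_boot`` times using an explicit
    integer seed and takes the central percentile interval.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 3:
        raise ValueError("shape statistics need at least 3 samples")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if np.ptp(arr) == 0.0:
        return ShapeEntry(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                          region="undefined", defined=False)
    skew = float(stats.skew(arr, bias=bias))
    kurt = float(stats.kurtosis(arr, fisher=True, bias=bias))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot = arr[idx]
    # a resample can be degenerate (all entries identical); its shape values
    # are NaN and are excluded from the percentile interval
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bskew = stats.skew(boot, axis=1, bias=bias)
        bkurt = stats.kurtosis(boot, axis=1, fisher=True, bias=bias)
    alpha = (1.0 - ci_level) / 2.0
    qs = [100.0 * alpha, 100.0 * (1.0 - alpha)]
    skew_ci = tuple(np.nanpercentile(bskew, qs))
    kurt_ci = tuple(np.nanpercentile(bkurt, qs))
    return ShapeEntry(
        skewness=skew,
        excess_kurtosis=kurt,
        skew_ci=(float(skew_ci[0]), float(skew_ci[1])),
        kurt_ci=(float(kurt_ci[0]), float(kurt_ci[1])),
        region=skewness_region(skew),
    )


@dataclass
class ShapeReport:
    """Per-configuration shape statistics for a whole campaign."""

    entries: pd.DataFrame  # indexed by config_id

    def to_dict(self) -> dict:
        return {
            str(cid): {
                k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                for k, v in row.items()
            }
            for cid, row in self.entries.to_dict(orient="index").items()
        }


def shape_report(
    table: EvaluationTable,
    n_boot: int = 2000,
    ci_level: float = 0.90,
    seed: int = 0,
    bias: bool = True,
) -> ShapeReport:
    """Shape statistics of every configuration's replica ensemble.

    Each configuration gets its own derived bootstrap seed so reports are
    reproducible yet resamples are independent across configurations.
    """
    table.require_complete()
    rows = {}
    for k, cid in enumerate(table.config_ids):
        ens = table.ensemble(cid)
        entry = shape_stats(ens, n_boot=n_boot, ci_level=ci_level,
                            seed=(seed + 1000003 * k) % (2**31 - 1), bias=bias)
        rows[cid] = {
            "mean_energy": float(np.mean(ens)),
            "skewness": entry.skewness,
            "excess_kurtosis": entry.excess_kurtosis,
            "skew_lo": entry.skew_ci[0],
            "skew_hi": entry.skew_ci[1],
            "kurt_lo": entry.kurt_ci[0],
            "kurt_hi": entry.kurt_ci[1],
            "region": entry.region,
        }
    return ShapeReport(entries=pd.DataFrame.from_dict(rows, orient="index"))


def ensemble_vs_parametric(
    table: EvaluationTable,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three views of a complete campaign table.

    Returns ``(raw, per_seed_means, per_config_means)``:

    - raw: every replica energy, size n_config * n_seed;
    - per_seed_means: energy averaged over configurations for each seed
      (aleatoric view), size n_seed;
    - per_config_means: ensemble-averaged energy for each configuration
      (epistemic view), size n_config.
    """
    table.require_complete()
    raw = table.energies()
    per_seed = table.per_seed_means().to_numpy()
    per_config = table.per_config_means().to_numpy()
    return raw, per_seed, per_config


def kde_summary(samples: Sequence[float], grid_size: int = 256):
    """Gaussian KDE with Scott's bandwidth — presentation only.

    Returns (grid, density, mode_location).  Never used in any statistic that
    feeds quantitative analysis.
    """
    arr = np.asarray(samples, dtype=float)
    kde = stats.gaussian_kde(arr, bw_method="scott")
    grid = np.linspace(arr.min() - 3 * arr.std(), arr.max() + 3 * arr.std(), grid_size)
    dens = kde(grid)
    return grid, dens, float(grid[np.argmax(dens)])
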