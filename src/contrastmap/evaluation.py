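"""Evaluation of reconstructed spatial relationships.

Three complementary metrics:

* **neighbor hit** — per cell, how many of its true spatial k nearest
  neighbors appear among the predicted k nearest neighbors; averaged over
  cells for a range of k. Random predictions give ~k^2/(n-1) expected hits.
* **neighborhood JSD** — Jensen-Shannon distance between the cell-type
  composition of the predicted and the true k-neighborhood (natural log by
  default, so values lie in [0, sqrt(ln 2)]).
* **global Spearman** — per cell, the rank correlation between predicted
  and true Euclidean distances to all other cells; invariant to rotation,
  translation and uniform scaling of either coordinate set.

A shuffled-location null (metric recomputed under random permutations of
the true coordinates) provides the no-signal baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence

import numpy as np
from scipy.spatial.distance import cdist, jensenshannon
from scipy.stats import rankdata

from .data_io import ValidationError

DEFAULT_K_VALUES = tuple(range(20, 201, 20))


@dataclass
class EvaluationReport:
    hit_curve: Dict[int, float] = field(default_factory=dict)
    jsd_per_cell: np.ndarray = None
    jsd_per_type: Dict[str, float] = field(default_factory=dict)
    spearman_per_cell: np.ndarray = None
    spearman_mean: float = None
    n_spearman_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "hit_curve": {int(k): float(v) for k, v in self.hit_curve.items()},
            "jsd_mean": (None if self.jsd_per_cell is None
                         else float(np.mean(self.jsd_per_cell))),
            "jsd_per_type": {k: float(v) for k, v in self.jsd_per_type.items()},
            "spearman_mean": (None if self.spearman_mean is None
                              else float(self.spearman_mean)),
            "n_spearman_excluded": int(self.n_spearman_excluded),
        }


def true_spatial_knn(coords: np.ndarray, k: int) -> np.ndarray:
    """True Euclidean kNN indices per cell, self excluded, stable ties."""
    coords = np.asarray(coords, float)
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    return np.argsort(dist, axis=1, kind="stable")[:, :k]


def neighbor_hit(pred_knn: np.ndarray, true_coords: np.ndarray,
                 k_values: Sequence[int] = DEFAULT_K_VALUES) -> Dict[int, float]:
    """Mean per-cell overlap between predicted and true top-k neighbors."""
    pred_knn = np.asarray(pred_knn, int)
    true_coords = np.asarray(true_coords, float)
    n = true_coords.shape[0]
    if pred_knn.shape[0] != n:
        raise ValidationError("prediction and truth cell counts differ")
    k_values = [int(k) for k in k_values]
    k_max = max(k_values)
    if k_max > pred_knn.shape[1]:
        raise ValidationError(
            f"k={k_max} exceeds predicted neighbor width {pred_knn.shape[1]}"
        )
    if k_max >= n:
        raise ValidationError(f"k={k_max} must be below n={n}")
    truth = true_spatial_knn(true_coords, k_max)
    curve = {}
    for k in k_values:
        hits = np.empty(n)
        for i in range(n):
            hits[i] = len(np.intersect1d(pred_knn[i, :k], truth[i, :k],
                                         assume_unique=True))
        curve[k] = float(hits.mean())
    return curve


def _type_proportions(types: np.ndarray, idx: np.ndarray,
                      categories: np.ndarray) -> np.ndarray:
    counts = np.array([(types[idx] == c).sum() for c in categories], float)
    return counts / counts.sum()


def neighborhood_jsd(pred_knn: np.ndarray, true_coords: np.ndarray,
                     cell_types: np.ndarray, k: int = 20, base=None):
    """JSD between predicted and true k-neighborhood type compositions.

    ``base=None`` uses the natural log (range [0, sqrt(ln 2)]); ``base=2``
    rescales to [0, 1]. Returns (per-cell vector, per-type means grouped by
    the focal cell's type).
    """
    if cell_types is None:
        raise ValidationError("cell_types are required for neighborhood JSD")
    cell_types = np.asarray(cell_types, dtype=object)
    if np.any([t is None for t in cell_types]):
        raise ValidationError("missing cell-type labels")
    pred_knn = np.asarray(pred_knn, int)
    n = len(cell_types)
    if pred_knn.shape[0] != n or len(true_coords) != n:
        raise ValidationError("prediction, truth and label cell counts differ")
    if k > pred_knn.shape[1]:
        raise ValidationError("k exceeds predicted neighbor width")
    truth = true_spatial_knn(np.asarray(true_coords, float), k)
    categories = np.unique(cell_types)
    per_cell = np.empty(n)
    for i in range(n):
        p = _type_proportions(cell_types, pred_knn[i, :k], categories)
        q = _type_proportions(cell_types, truth[i], categories)
        d = jensenshannon(p, q, base=base)
        per_cell[i] = 0.0 if np.isnan(d) else d  # identical distributions
    per_type = {
        str(c): float(per_cell[cell_types == c].mean()) for c in categories
    }
    return per_cell, per_type


def global_spearman(pred_coords: np.ndarray, true_coords: np.ndarray):
    """Per-cell Spearman correlation of predicted vs true distance profiles.

    Cells whose predicted or true distance vector is constant (e.g., all
    query cells clumped onto one location) have undefined rank correlation;
    they are excluded and counted. Returns (per-cell values with NaN for
    excluded cells, mean over defined cells, n_excluded).
    """
    pred_coords = np.asarray(pred_coords, float)
    true_coords = np.asarray(true_coords, float)
    n = pred_coords.shape[0]
    if true_coords.shape[0] != n:
        raise ValidationError("coordinate sets differ in cell count")
    if n < 3:
        raise ValidationError("need at least 3 cells")
    d_pred = cdist(pred_coords, pred_coords)
    d_true = cdist(true_coords, true_coords)
    mask = ~np.eye(n, dtype=bool)
    rho = np.full(n, np.nan)
    for i in range(n):
        a, b = d_pred[i][mask[i]], d_true[i][mask[i]]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        ra, rb = rankdata(a), rankdata(b)
        with np.errstate(invalid="ignore"):
            rho[i] = np.corrcoef(ra, rb)[0, 1]
    defined = np.isfinite(rho)
    n_excluded = int(n - defined.sum())
    mean = float(rho[defined].mean()) if defined.any() else float("nan")
    return rho, mean, n_excluded


def shuffled_null(metric: Callable[[np.ndarray], float], true_coords: np.ndarray,
                  n_perm: int, seed: int,
                  quantiles: Sequence[float] = (0.05, 0.5, 0.95)) -> dict:
    """Distribution of a coordinate-dependent metric under location shuffling.

    ``metric`` is called with a row-permuted copy of ``true_coords`` for
    each of ``n_perm`` seeded permutations. Returns mean, sd and empirical
    quantiles of the resulting values.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    true_coords = np.asarray(true_coords, float)
    values = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(true_coords.shape[0])
        values[t] = metric(true_coords[perm])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if n_perm > 1 else 0.0,
        "quantiles": {str(q): float(np.quantile(values, q)) for q in quantiles},
        "values": values,
    }


def evaluate(pred_knn: np.ndarray, true_coords: np.ndarray,
             cell_types: np.ndarray = None,
             pred_coords: np.ndarray = None,
             k_values: Sequence[int] = DEFAULT_K_VALUES,
             jsd_k: int = 20) -> EvaluationReport:
    """Bundle the three metrics into one report (labels/coords optional)."""
    report = EvaluationReport(hit_curve=neighbor_hit(pred_knn, true_coords, k_values))
    if cell_types is not None:
        per_cell, per_type = neighborhood_jsd(pred_knn, true_coords, cell_types, k=jsd_k)
        report.jsd_per_cell = per_cell
        report.jsd_per_type = per_type
    if pred_coords is not None:
        rho, mean, excl = global_spearman(pred_coords, true_coords)
        report.spearman_per_cell = rho
        report.spearman_mean = mean
        report.n_spearman_excluded = excl
    return report
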