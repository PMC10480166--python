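"""Precision/Recall scoring of a distance's same-model pair recognition.

Two graphs form an actual-positive pair when they come from the same
generating model. A pair is predicted positive when its distance falls
below a threshold ε; sweeping ε over the observed distances traces a
Precision/Recall curve whose area (AUPR) summarizes how well the distance
recognizes same-model pairs. Optionally the evaluation is restricted to
pairs of equal size and density, the easier task where size and density no
longer act as confounders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, DistanceSpec, _features_of, pairwise_distance_matrix
from .generators import generate_grid

__all__ = ["PairLabeling", "PRCurve", "label_pairs", "pr_curve", "aupr", "run_experiment"]


@dataclass(frozen=True)
class PairLabeling:
    """Condensed-order labels for all unordered graph pairs.

    ``actual`` flags same-model pairs; ``keep`` masks the pairs entering the
    evaluation (all of them, or only the same-size/density ones). Both are
    aligned with scipy's condensed pair ordering over ``labels``.
    """

    labels: tuple[str, ...]
    actual: np.ndarray
    keep: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.keep.sum())


@dataclass(frozen=True)
class PRCurve:
    """Precision/Recall points over the sweep of the distance threshold ε."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    best_f1: float


def label_pairs(manifest: pd.DataFrame, restrict_same_size_density: bool = False) -> PairLabeling:
    """Label all unordered graph pairs from a grid manifest.

    The manifest needs columns ``label``, ``model``, ``N``, ``rho``. With
    the restriction flag, only pairs sharing (N, rho) are retained.
    """
    for col in ("label", "model", "N", "rho"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    models = manifest["model"].to_numpy()
    i, j = np.triu_indices(len(manifest), k=1)
    actual = models[i] == models[j]
    if restrict_same_size_density:
        cells = pd.factorize(manifest["N"].astype(str) + "|" + manifest["rho"].astype(str))[0]
        keep = cells[i] == cells[j]
    else:
        keep = np.ones(i.size, dtype=bool)
    return PairLabeling(labels=tuple(manifest["label"]), actual=actual, keep=keep)


def pr_curve(distances: DistanceMatrix, labeling: PairLabeling) -> PRCurve:
    """Precision/Recall curve of a distance matrix against pair labels.

    ε sweeps the distinct pair-distance values; all tied pairs enter at the
    same threshold, making the curve deterministic. The stored AUPR is the
    non-interpolated average precision (step integration over recall).
    """
    if distances.labels != labeling.labels:
        raise ValueError("distance matrix and labeling cover different graphs")
    d = distances.condensed()[labeling.keep]
    y = labeling.actual[labeling.keep]
    return _pr_from_scores(d, y)


def _pr_from_scores(d: np.ndarray, y: np.ndarray) -> PRCurve:
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no actual-positive pairs: recall is undefined")
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    y_sorted = y[order]
    # last index of each tie group
    distinct = np.nonzero(np.diff(d_sorted))[0]
    last = np.concatenate([distinct, [d.size - 1]])
    tp = np.cumsum(y_sorted)[last].astype(np.float64)
    pred = last + 1.0
    precision = tp / pred
    recall = tp / n_pos
    thresholds = d_sorted[last]
    ap = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        aupr=ap,
        best_f1=float(f1.max()),
    )


def aupr(curve: PRCurve, method: str = "step") -> float:
    """Area under a PR curve.

    ``step`` is non-interpolated average precision (the default used
    throughout); ``trapezoid`` is available for sensitivity checks.
    """
    if method == "step":
        return curve.aupr
    if method == "trapezoid":
        r = np.concatenate([[0.0], curve.recall])
        p = np.concatenate([[curve.precision[0]], curve.precision])
        return float(np.trapezoid(p, r))
    raise ValueError(f"unknown AUPR method {method!r}")


def run_experiment(
    models: list[str],
    sizes: list[int],
    densities: list[float],
    replicas: int,
    seed: int,
    metrics: list[str | DistanceSpec],
    delta: float = 0.01,
    cap: float = 1.0,
    graphs=None,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classification benchmark: AUPR per metric, unrestricted and restricted.

    Generates the model/size/density grid (unless precomputed ``graphs`` and
    ``manifest`` are supplied), computes features once per graph, then each
    requested distance matrix and its AUPR over all pairs and over the
    same-size/density pairs only. Returns a table indexed by metric name
    with columns ``aupr_all`` and ``aupr_same_cell``.
    """
    if graphs is None or manifest is None:
        graphs, manifest = generate_grid(models, sizes, densities, replicas, seed)
    feats = [_features_of(g) for g in graphs]
    labels = tuple(manifest["label"])
    lab_all = label_pairs(manifest, restrict_same_size_density=False)
    lab_cell = label_pairs(manifest, restrict_same_size_density=True)
    rows = []
    for metric in metrics:
        spec = metric if isinstance(metric, DistanceSpec) else DistanceSpec(metric, delta=delta, cap=cap)
        dmat = pairwise_distance_matrix(feats, spec, labels=labels)
        rows.append(
            {
                "metric": spec.name,
                "aupr_all": pr_curve(dmat, lab_all).aupr,
                "aupr_same_cell": pr_curve(dmat, lab_cell).aupr,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
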