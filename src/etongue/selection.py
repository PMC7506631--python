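"""F clustering factor and backward elimination of sensors.

The F factor is the ratio of between-class to pooled within-class
variance of a response — for scalar responses exactly the one-way ANOVA
F statistic:

    F = [ Σ_i n_i ||z̄_i − z̿||² / (k − 1) ] /
        [ Σ_i Σ_j ||z_ji − z̄_i||² / (N − k) ]

computed here on the 2-D score-plot coordinates of the compressed array
response (vector responses use squared Euclidean norms, which reduces to
the scalar form in one dimension).  Array optimization proceeds by
leave-one-sensor-out: at each iteration the F factor is recomputed with
every remaining sensor excluded in turn, the sensor whose exclusion
raises F the most is discarded, and the process stops once even the best
exclusion makes F decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .compression import FeatureBlockMatrix, WaveletSpec, build_feature_blocks, drop_sensor_columns
from .core_data import Dataset, ValidationError, drop_sensors
from .score_models import fit_cva, fit_pca

__all__ = [
    "ClassPartition",
    "SelectionStep",
    "SelectionTrace",
    "f_factor",
    "f_of_blocks",
    "f_of_roster",
    "backward_eliminate",
]


@dataclass
class ClassPartition:
    """Class-labelled responses with precomputed class and grand means.

    ``z`` is ``n x d`` (``d = 1`` for scalar responses); ``labels`` has one
    entry per row.
    """

    z: np.ndarray
    labels: list[str]
    classes: list[str]
    n_i: np.ndarray
    class_means: np.ndarray
    grand_mean: np.ndarray

    @classmethod
    def from_labels(cls, z: np.ndarray, labels: Sequence[str]) -> "ClassPartition":
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] == 1 and len(labels) > 1:
            z = z.T
        labels = [str(l) for l in labels]
        if z.shape[0] != len(labels):
            raise ValidationError("one label per sample required")
        classes = list(dict.fromkeys(labels))
        y = np.array(labels)
        n_i = np.array([int(np.sum(y == c)) for c in classes])
        class_means = np.vstack([z[y == c].mean(axis=0) for c in classes])
        grand_mean = z.mean(axis=0)
        return cls(z, labels, classes, n_i, class_means, grand_mean)

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def n_total(self) -> int:
        return self.z.shape[0]


def f_factor(partition: ClassPartition) -> float:
    """Between-class over within-class variance ratio of the partition.

    Equals the one-way ANOVA F statistic for scalar responses; vector
    responses generalize via squared Euclidean norms (trace of the
    scatter matrices).
    """
    k, N = partition.k, partition.n_total
    if k < 2:
        raise ValidationError(f"F factor needs >= 2 classes, got {k}")
    if N <= k:
        raise ValidationError(f"F factor needs more samples ({N}) than classes ({k})")
    between = float(
        np.sum(
            partition.n_i
            * np.sum((partition.class_means - partition.grand_mean) ** 2, axis=1)
        )
    )
    y = np.array(partition.labels)
    within = 0.0
    for c, mean in zip(partition.classes, partition.class_means):
        d = partition.z[y == c] - mean
        within += float(np.sum(d**2))
    if within == 0.0:
        raise ValidationError("zero within-class scatter: F factor undefined")
    return (between / (k - 1)) / (within / (N - k))


def f_of_blocks(
    fb: FeatureBlockMatrix,
    n_score_components: int = 2,
    method: str = "pca",
) -> float:
    """F factor of a feature-block matrix via its 2-D score plot."""
    labels = fb.class_labels
    if len(set(labels)) < 2:
        raise ValidationError("F factor needs >= 2 classes in the dataset")
    if method == "pca":
        model = fit_pca(fb, n_components=n_score_components)
    elif method == "cva":
        model = fit_cva(fb, n_components=n_score_components)
    else:
        raise ValidationError(f"unknown score method {method!r}")
    part = ClassPartition.from_labels(model.scores[:, :n_score_components], labels)
    return f_factor(part)


def f_of_roster(
    ds: Dataset,
    roster: Iterable[str] | None = None,
    wavelet: WaveletSpec | None = None,
    n_score_components: int = 2,
    method: str = "pca",
) -> float:
    """F factor of a dataset restricted to ``roster`` sensors.

    Pipeline: DWT feature blocks -> score projection (default PCA, first
    two components) -> F factor over the dataset's class labels.
    """
    wavelet = wavelet or WaveletSpec()
    if roster is not None:
        roster = list(roster)
        removed = set(ds.sensor_roster) - set(roster)
        if set(roster) - set(ds.sensor_roster):
            raise ValidationError(
                f"unknown sensors: {sorted(set(roster) - set(ds.sensor_roster))}"
            )
        if removed:
            ds = drop_sensors(ds, removed)
    fb = build_feature_blocks(ds, wavelet)
    return f_of_blocks(fb, n_score_components=n_score_components, method=method)


@dataclass
class SelectionStep:
    """One backward-elimination iteration."""

    roster: tuple[str, ...]
    reference_f: float
    candidate_f: dict[str, float]  # sensor -> F obtained when that sensor is excluded
    removed: str | None
    stop_reason: str | None

    def to_dict(self) -> dict:
        return {
            "roster": list(self.roster),
            "reference_f": self.reference_f,
            "candidate_f": dict(self.candidate_f),
            "removed": self.removed,
            "stop_reason": self.stop_reason,
        }


@dataclass
class SelectionTrace:
    """Full record of a backward-elimination run."""

    steps: list[SelectionStep]
    final_roster: tuple[str, ...]
    final_f: float

    @property
    def removed_sensors(self) -> list[str]:
        return [s.removed for s in self.steps if s.removed is not None]

    def reference_f_sequence(self) -> list[float]:
        return [s.reference_f for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "final_roster": list(self.final_roster),
            "final_f": self.final_f,
        }

    def candidate_table(self):
        """Iterations × sensors table of candidate F values (NaN once removed)."""
        import pandas as pd

        sensors = list(self.steps[0].roster)
        rows = []
        for i, step in enumerate(self.steps):
            row = {s: step.candidate_f.get(s, np.nan) for s in sensors}
            row["iteration"] = i + 1
            row["reference_f"] = step.reference_f
            row["removed"] = step.removed if step.removed is not None else ""
            rows.append(row)
        return pd.DataFrame(rows).set_index("iteration")


def backward_eliminate(
    ds: Dataset,
    wavelet: WaveletSpec | None = None,
    n_score_components: int = 2,
    tolerance_frac: float = 0.02,
    min_sensors: int | None = None,
    method: str = "pca",
) -> SelectionTrace:
    """Leave-one-sensor-out backward elimination guided by the F factor.

    At each iteration the reference F of the current roster is computed,
    then F with each sensor excluded in turn; the exclusion yielding the
    highest F (ties broken by roster order) is accepted if it reaches at
    least ``(1 - tolerance_frac)`` of the reference — so a small positive
    tolerance also permits removals that leave F essentially unchanged,
    while ``tolerance_frac = 0`` demands strict non-decrease.  Stops when
    the best exclusion makes F decay or ``min_sensors`` is reached.

    ``min_sensors`` defaults to ``n_analytes + 1`` (at least 2): an array
    cannot quantify its analytes with fewer channels than analytes, and
    one extra channel is the customary margin against background and
    drift.  At replicate counts typical of selection campaigns the
    within-class scatter of the 2-D scores is estimated from few degrees
    of freedom, so the F-decay criterion alone can overshoot by one
    sensor; the floor makes the endpoint robust while the decay rule
    still governs everything above it.

    Scores are refit from scratch at every candidate evaluation; DWT
    coefficients are sensor-local and therefore computed once.
    """
    wavelet = wavelet or WaveletSpec()
    if tolerance_frac < 0:
        raise ValidationError("tolerance_frac must be >= 0")
    if min_sensors is None:
        min_sensors = max(2, len(ds.analytes) + 1)
    if min_sensors < 1:
        raise ValidationError("min_sensors must be >= 1")

    fb = build_feature_blocks(ds, wavelet)
    roster = list(ds.sensor_roster)
    steps: list[SelectionStep] = []

    def score_f(blocks: FeatureBlockMatrix) -> float:
        return f_of_blocks(blocks, n_score_components=n_score_components, method=method)

    while True:
        ref = score_f(fb)
        if len(roster) <= min_sensors:
            steps.append(SelectionStep(tuple(roster), ref, {}, None, "min_sensors"))
            break
        candidates = {
            sid: score_f(drop_sensor_columns(fb, {sid})) for sid in roster
        }
        best = max(roster, key=lambda sid: candidates[sid])  # first max in roster order
        if candidates[best] >= (1.0 - tolerance_frac) * ref:
            steps.append(SelectionStep(tuple(roster), ref, candidates, best, None))
            fb = drop_sensor_columns(fb, {best})
            roster.remove(best)
        else:
            steps.append(SelectionStep(tuple(roster), ref, candidates, None, "f_decayed"))
            break
    return SelectionTrace(
        steps=steps, final_roster=tuple(roster), final_f=steps[-1].reference_f
    )
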