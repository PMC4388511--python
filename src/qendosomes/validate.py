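"""Scoring detections against simulation ground truth.

Reproduces the detector's accuracy benchmark: fields with a known number of
simulated endosomes are rendered, detected, and matched to ground truth;
accuracy is the proportion of simulated endosomes correctly recovered.
Parameter sweeps (patch radius; background threshold x correlation cut-off)
report the relative error between detected and simulated counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detect import (
    DetectionParams,
    ImageStack,
    _score_all,
    detect_endosomes,
    find_candidates,
    max_project,
)
from .synthetic import SimulatedField, SimulationSpec, render_field

__all__ = [
    "Matching",
    "AccuracyResult",
    "match_detections",
    "evaluate_field",
    "accuracy_curve",
    "radius_sweep",
    "threshold_correlation_surface",
]


@dataclass(frozen=True)
class Matching:
    """One-to-one assignment between truth and detections.

    ``pairs`` holds (truth_index, detection_index, distance) triples.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_truth: list[int]
    unmatched_detections: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class AccuracyResult:
    """Detection accuracy on a single simulated field."""

    n_simulated: int
    n_detected: int
    n_matched: int
    accuracy: float
    relative_error: float
    false_positives: int

    @classmethod
    def from_counts(cls, n_simulated: int, n_detected: int, n_matched: int):
        if n_matched > min(n_simulated, n_detected):
            raise ValueError("n_matched exceeds min(n_simulated, n_detected)")
        if n_simulated > 0:
            accuracy = n_matched / n_simulated
            rel_err = (n_detected - n_simulated) / n_simulated
        else:
            # No true spots: accuracy is defined as 1 and false positives
            # are reported separately.
            accuracy = 1.0
            rel_err = float("nan")
        return cls(
            n_simulated=n_simulated,
            n_detected=n_detected,
            n_matched=n_matched,
            accuracy=accuracy,
            relative_error=rel_err,
            false_positives=n_detected - n_matched,
        )


def _as_positions(obj) -> np.ndarray:
    """Coerce truth spots / detections / arrays to an (n, 2) float array."""
    if isinstance(obj, np.ndarray):
        arr = obj.astype(float)
    else:
        rows = []
        for item in obj:
            if hasattr(item, "row"):
                rows.append((float(item.row), float(item.col)))
            else:
                rows.append((float(item[0]), float(item[1])))
        arr = np.array(rows) if rows else np.empty((0, 2))
    if arr.size and (arr.ndim != 2 or arr.shape[1] != 2):
        raise ValueError("positions must be an (n, 2) array of (row, col)")
    return arr.reshape(-1, 2)


def match_detections(truth, detections, tolerance: float = 2.0) -> Matching:
    """Greedy nearest-neighbor one-to-one matching within a distance tolerance.

    Candidate pairs are taken in ascending distance order (ties broken by
    index), each truth point and each detection used at most once; a pair is
    valid iff its Euclidean distance is <= tolerance. The result is
    invariant to the order of the input lists up to relabeling.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    t = _as_positions(truth)
    d = _as_positions(detections)
    if t.shape[0] == 0 or d.shape[0] == 0:
        return Matching([], list(range(t.shape[0])), list(range(d.shape[0])))

    dist = np.sqrt(((t[:, None, :] - d[None, :, :]) ** 2).sum(axis=2))
    ti, di = np.nonzero(dist <= tolerance)
    order = np.lexsort((di, ti, dist[ti, di]))
    used_t = np.zeros(t.shape[0], dtype=bool)
    used_d = np.zeros(d.shape[0], dtype=bool)
    pairs = []
    for k in order:
        a, b = int(ti[k]), int(di[k])
        if used_t[a] or used_d[b]:
            continue
        used_t[a] = used_d[b] = True
        pairs.append((a, b, float(dist[a, b])))
    return Matching(
        pairs=pairs,
        unmatched_truth=[int(i) for i in np.nonzero(~used_t)[0]],
        unmatched_detections=[int(i) for i in np.nonzero(~used_d)[0]],
    )


def evaluate_field(
    field: SimulatedField,
    params: DetectionParams | None = None,
    tolerance: float = 2.0,
) -> AccuracyResult:
    """Detect on a simulated field and score against its ground truth."""
    params = params or DetectionParams()
    detections = detect_endosomes(ImageStack(field.image[None]), params)
    matching = match_detections(field.positions, detections, tolerance)
    return AccuracyResult.from_counts(
        n_simulated=len(field.truth),
        n_detected=len(detections),
        n_matched=matching.n_matched,
    )


def _sub_seed(seed: int, n: int, rep: int) -> int:
    """Deterministic replicate seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(seed), int(n), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def accuracy_curve(
    spec: SimulationSpec,
    params: DetectionParams | None = None,
    n_grid=(0, 100, 200, 300, 400, 500, 600, 700, 800),
    reps: int = 10,
    tolerance: float = 2.0,
    per_rep: bool = False,
) -> pd.DataFrame:
    """Mean detection accuracy as a function of the number of simulated spots.

    For each n in ``n_grid``, runs ``reps`` independent simulate -> detect ->
    match cycles with distinct sub-seeds and reports per-n means. With
    ``per_rep=True`` the individual replicate rows are returned instead.
    """
    params = params or DetectionParams()
    rows = []
    for n in n_grid:
        for rep in range(reps):
            sub = replace(spec, n_endosomes=int(n), seed=_sub_seed(spec.seed, n, rep))
            res = evaluate_field(render_field(sub), params, tolerance)
            rows.append(
                {
                    "n_simulated": int(n),
                    "rep": rep,
                    "accuracy": res.accuracy,
                    "n_detected": res.n_detected,
                    "n_matched": res.n_matched,
                    "relative_error": res.relative_error,
                    "false_positives": res.false_positives,
                }
            )
    table = pd.DataFrame(rows)
    if per_rep:
        return table
    return (
        table.drop(columns="rep")
        .groupby("n_simulated", as_index=False)
        .mean()
        .sort_values("n_simulated", ignore_index=True)
    )


def radius_sweep(
    spec: SimulationSpec,
    params: DetectionParams | None = None,
    radii=(2, 3, 4, 5, 6, 7),
    n_grid=(100, 400, 800),
    reps: int = 10,
    tolerance: float = 2.0,
) -> pd.DataFrame:
    """Accuracy and count error as the fitted-patch radius varies.

    The same replicate fields (same sub-seeds) are reused for every radius,
    so radii are compared on identical data.
    """
    params = params or DetectionParams()
    rows = []
    for r in radii:
        if r < 2:
            raise ValueError("patch radius must be >= 2")
        curve = accuracy_curve(
            spec,
            replace(params, patch_radius=int(r)),
            n_grid=n_grid,
            reps=reps,
            tolerance=tolerance,
        )
        rows.append(
            {
                "patch_radius": int(r),
                "accuracy": curve["accuracy"].mean(),
                "relative_error": curve["relative_error"].abs().mean(),
                "false_positives": curve["false_positives"].mean(),
            }
        )
    return pd.DataFrame(rows)


def threshold_correlation_surface(
    spec: SimulationSpec,
    params: DetectionParams | None = None,
    thresholds=(0, 30, 60, 90, 120, 150),
    correlations=(0.0, 0.25, 0.5, 0.75, 0.9),
    reps: int = 10,
) -> pd.DataFrame:
    """Mean relative count error over a (threshold, correlation) grid.

    Per replicate field the candidate stage is run once at the loosest
    background threshold and every grid cell is evaluated by re-applying the
    two acceptance predicates — valid because both acceptances are monotone.
    The error is (n_detected - n_simulated) / n_simulated, as in the
    detected/simulated-ratio benchmark. Rows are thresholds (%), columns
    correlation cut-offs; the default operating point is (90, 0.75).
    """
    params = params or DetectionParams()
    thresholds = sorted(float(t) for t in thresholds)
    correlations = sorted(float(c) for c in correlations)
    if not thresholds or not correlations:
        raise ValueError("threshold and correlation grids must be nonempty")
    if thresholds[0] < 0:
        raise ValueError("thresholds must be >= 0")
    if spec.n_endosomes <= 0:
        raise ValueError("spec.n_endosomes must be > 0 for a relative-error surface")

    n = spec.n_endosomes
    err = np.zeros((len(thresholds), len(correlations)))
    for rep in range(reps):
        sub = replace(spec, seed=_sub_seed(spec.seed, n, rep))
        field = render_field(sub)
        loose = replace(params, background_threshold_pct=thresholds[0])
        projection = max_project(ImageStack(field.image[None]), params.smooth_sigma)
        candidates = find_candidates(projection, loose)
        if candidates:
            peak = np.array([c.peak_intensity for c in candidates])
            background = np.array([c.local_background for c in candidates])
            scores = _score_all(projection, candidates, params)
        else:
            peak = background = scores = np.empty(0)
        for i, t in enumerate(thresholds):
            pass_t = peak >= (1.0 + t / 100.0) * background
            for j, c in enumerate(correlations):
                n_det = int(np.count_nonzero(pass_t & (scores > c)))
                err[i, j] += (n_det - n) / n
    err /= reps
    return pd.DataFrame(err, index=thresholds, columns=correlations)
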