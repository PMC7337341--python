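"""One-class SVM niche hypervolumes in principal-component space.

A realized-niche hypervolume is the positive region of a one-class support
vector machine with an RBF kernel, fitted on presence points only.  The two
tunable parameters are the kernel width γ (default 0.5) and ν (default
0.01), which bounds the fraction of training points left outside the
boundary — the thresholding that excludes a few climatically extreme
records.

Volume, centroid and per-axis extent are estimated by Monte-Carlo: uniform
draws over an axis-aligned box spanning the training cloud (plus a margin so
a boundary bulging past the extremes is not clipped) are classified by the
decision function; volume = box volume × inlier fraction, with a binomial
standard error.  The inlier cloud is retained so overlap statistics can
reuse it, and everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import OneClassSVM

__all__ = ["NicheHypervolume", "fit_hypervolume", "contains", "centroid", "axis_extent"]

DEFAULT_GAMMA = 0.5
DEFAULT_NU = 0.01
DEFAULT_MC_DRAWS = 100_000
DEFAULT_BOX_MARGIN = 0.10  # per-side fraction of each axis range

MIN_POINTS = 10

#: membership threshold tolerance: support vectors sit exactly on the f=0
#: boundary and land an epsilon below it in floating point, so strict f >= 0
#: would misclassify a large share of boundary training points
DECISION_TOL = 1e-6


@dataclass
class NicheHypervolume:
    """Fitted niche boundary plus its Monte-Carlo integration state."""

    model: OneClassSVM
    train_points: np.ndarray  # (n, m) raw PC coordinates
    gamma: float
    nu: float
    box_lo: np.ndarray  # (m,) sampling box
    box_hi: np.ndarray
    mc_draws: int
    seed: int
    inliers: np.ndarray  # (n_in, m) Monte-Carlo points inside the boundary
    volume: float
    volume_se: float
    label: str = ""
    scale_mean: np.ndarray | None = None  # set when fitted with rescale=True
    scale_sd: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.train_points.shape[1]

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_hi - self.box_lo))

    @property
    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the Monte-Carlo inlier sample."""
        if len(self.inliers) == 0:
            raise ValueError("inlier sample is empty; cannot form a centroid")
        return self.inliers.mean(axis=0)

    def decision(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.m:
            raise ValueError(f"expected {self.m}-dimensional points, got {pts.shape[1]}")
        if self.scale_mean is not None:
            pts = (pts - self.scale_mean) / self.scale_sd
        return self.model.decision_function(pts)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership: decision function ≥ 0 (within numerical tolerance)."""
        return self.decision(points) >= -DECISION_TOL

    def axis_extent(self, axis: int) -> tuple[float, float]:
        """(lo, hi) of the inlier sample along one PC axis, in PC units."""
        if not 0 <= axis < self.m:
            raise IndexError(f"axis {axis} out of range for m={self.m}")
        if len(self.inliers) == 0:
            raise ValueError("inlier sample is empty")
        col = self.inliers[:, axis]
        return float(col.min()), float(col.max())

    def to_json(self, path: str | Path) -> None:
        """Serialize fit inputs and MC summaries (model is refit on load)."""
        payload = {
            "label": self.label,
            "gamma": self.gamma,
            "nu": self.nu,
            "mc_draws": self.mc_draws,
            "seed": self.seed,
            "box_lo": self.box_lo.tolist(),
            "box_hi": self.box_hi.tolist(),
            "volume": self.volume,
            "volume_se": self.volume_se,
            "centroid": self.centroid.tolist(),
            "rescale": self.scale_mean is not None,
            "train_points": self.train_points.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NicheHypervolume":
        payload = json.loads(Path(path).read_text())
        hv = fit_hypervolume(
            np.asarray(payload["train_points"]),
            gamma=payload["gamma"],
            nu=payload["nu"],
            mc_draws=payload["mc_draws"],
            seed=payload["seed"],
            label=payload.get("label", ""),
            rescale=payload.get("rescale", False),
        )
        return hv


def fit_hypervolume(
    pc_points: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    nu: float = DEFAULT_NU,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed: int = 0,
    box_margin: float = DEFAULT_BOX_MARGIN,
    label: str = "",
    rescale: bool = False,
) -> NicheHypervolume:
    """Fit a one-class SVM boundary on raw PC coordinates and integrate it.

    The PC axes are the predictor space itself (already variance-scaled by
    the PCA), so by default no internal rescaling is applied before the SVM
    fit; ``rescale=True`` standardizes each axis internally (some reference
    hypervolume implementations do), changing the effective kernel metric.
    Requires at least max(10, m+1) points and a non-degenerate range on
    every axis.
    """
    x = np.atleast_2d(np.asarray(pc_points, dtype=float))
    n, m = x.shape
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not 0 < nu < 1:
        raise ValueError("nu must lie in (0, 1)")
    if n < max(MIN_POINTS, m + 1):
        raise ValueError(
            f"hypervolumes require at least {max(MIN_POINTS, m + 1)} records, got {n}"
        )
    lo, hi = x.min(axis=0), x.max(axis=0)
    rng_axis = hi - lo
    if np.any(rng_axis == 0):
        raise ValueError("degenerate axis with zero range; cannot define a sampling box")
    box_lo = lo - box_margin * rng_axis
    box_hi = hi + box_margin * rng_axis

    scale_mean = scale_sd = None
    x_fit = x
    if rescale:
        scale_mean = x.mean(axis=0)
        scale_sd = x.std(axis=0, ddof=1)
        x_fit = (x - scale_mean) / scale_sd
    # tight solver tolerance keeps boundary support vectors within DECISION_TOL
    # of f = 0, so the membership epsilon only absorbs numerical noise
    model = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu, tol=1e-8)
    model.fit(x_fit)

    rng = np.random.default_rng(seed)
    draws = rng.uniform(box_lo, box_hi, size=(mc_draws, m))
    d_fit = (draws - scale_mean) / scale_sd if rescale else draws
    inside = model.decision_function(d_fit) >= -DECISION_TOL
    frac = inside.mean()
    box_vol = float(np.prod(box_hi - box_lo))
    volume = box_vol * float(frac)
    volume_se = box_vol * float(np.sqrt(frac * (1 - frac) / mc_draws))

    return NicheHypervolume(
        model=model,
        train_points=x,
        gamma=gamma,
        nu=nu,
        box_lo=box_lo,
        box_hi=box_hi,
        mc_draws=mc_draws,
        seed=seed,
        inliers=draws[inside],
        volume=volume,
        volume_se=volume_se,
        label=label,
        scale_mean=scale_mean,
        scale_sd=scale_sd,
    )


def contains(hv: NicheHypervolume, points: np.ndarray) -> np.ndarray:
    return hv.contains(points)


def centroid(hv: NicheHypervolume) -> np.ndarray:
    return hv.centroid


def axis_extent(hv: NicheHypervolume, axis: int) -> tuple[float, float]:
    return hv.axis_extent(axis)
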