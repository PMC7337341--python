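"""Monte-Carlo Jaccard and Sorensen overlap between niche hypervolumes.

Both indices are estimated from one shared uniform sample over the union of
the two hypervolumes' sampling boxes, classified by both membership
functions:

    J = V(A∩B) / V(A∪B)        S = 2·V(A∩B) / (V(A) + V(B))

Because the volumes come from shared counts, the functional identity
S = 2J/(1+J) holds exactly (to floating point), and binomial standard
errors give principled tolerances for downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypervolume import NicheHypervolume

__all__ = ["OverlapResult", "overlap_pair", "overlap_matrix", "matrix_to_frame"]

DEFAULT_OVERLAP_DRAWS = 200_000


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap statistics from one shared Monte-Carlo draw set."""

    label_a: str
    label_b: str
    jaccard: float
    sorensen: float
    volume_a: float
    volume_b: float
    volume_intersection: float
    volume_union: float
    draws: int
    seed: int
    jaccard_se: float
    degenerate: bool = False


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n))


def overlap_pair(
    a: NicheHypervolume,
    b: NicheHypervolume,
    draws: int = DEFAULT_OVERLAP_DRAWS,
    seed: int = 0,
) -> OverlapResult:
    """Estimate Jaccard/Sorensen similarity of two hypervolumes.

    Uniform draws over the componentwise union of the two sampling boxes are
    classified by both boundaries; all four volumes (A, B, intersection,
    union) come from the same draws.  A pair whose union receives no inlier
    is flagged degenerate with both indices 0.
    """
    if a.m != b.m:
        raise ValueError(f"dimension mismatch: {a.m} vs {b.m}")
    lo = np.minimum(a.box_lo, b.box_lo)
    hi = np.maximum(a.box_hi, b.box_hi)
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(draws, a.m))
    in_a = a.contains(pts)
    in_b = b.contains(pts)
    n_a = int(in_a.sum())
    n_b = int(in_b.sum())
    n_and = int((in_a & in_b).sum())
    n_or = int((in_a | in_b).sum())
    v = box_vol / draws
    if n_or == 0:
        return OverlapResult(
            a.label, b.label, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, draws, seed, 0.0, True
        )
    jac = n_and / n_or
    sor = 2 * n_and / (n_a + n_b) if (n_a + n_b) else 0.0
    # SE of the ratio estimator, binomial numerator at fixed denominator scale
    jac_se = _binomial_se(n_and / draws, draws) / (n_or / draws)
    return OverlapResult(
        label_a=a.label,
        label_b=b.label,
        jaccard=jac,
        sorensen=sor,
        volume_a=n_a * v,
        volume_b=n_b * v,
        volume_intersection=n_and * v,
        volume_union=n_or * v,
        draws=draws,
        seed=seed,
        jaccard_se=jac_se,
    )


def overlap_matrix(
    hypervolumes: list[NicheHypervolume],
    draws: int = DEFAULT_OVERLAP_DRAWS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[OverlapResult]]:
    """All-pairs overlap: (jaccard matrix, sorensen matrix, long results).

    Matrices are symmetric with unit diagonal; the conventional triangular
    report (Jaccard above the diagonal, Sorensen below) is produced by
    :func:`matrix_to_frame`.
    """
    p = len(hypervolumes)
    if p < 2:
        raise ValueError("need at least two hypervolumes")
    jac = np.eye(p)
    sor = np.eye(p)
    results = []
    for i in range(p):
        for j in range(i + 1, p):
            pair_seed = (seed + 1_000_003 * (i * p + j)) % 2**31
            res = overlap_pair(hypervolumes[i], hypervolumes[j], draws, pair_seed)
            jac[i, j] = jac[j, i] = res.jaccard
            sor[i, j] = sor[j, i] = res.sorensen
            results.append(res)
    return jac, sor, results


def matrix_to_frame(
    jaccard: np.ndarray, sorensen: np.ndarray, labels: list[str]
) -> pd.DataFrame:
    """Triangular layout: Jaccard above the diagonal, Sorensen below."""
    p = len(labels)
    out = np.full((p, p), np.nan)
    iu = np.triu_indices(p, 1)
    il = np.tril_indices(p, -1)
    out[iu] = jaccard[iu]
    out[il] = sorensen[il]
    return pd.DataFrame(out, index=labels, columns=labels)


def results_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    """Long-format table of pairwise overlap results with standard errors."""
    return pd.DataFrame([r.__dict__ for r in results])
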