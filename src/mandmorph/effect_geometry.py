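"""Geometry of shape-effect vectors and the shape score.

Each fixed effect of the multivariate shape model has, per posterior draw, a
coefficient vector over the shape variables (PC scores).  Comparing two such
vectors by their angle and by the Pearson correlation of their elements asks
whether two factors push shape in related directions; an interval containing
90 degrees (angle) or 0 (correlation) is read as independence.

The shape score projects specimens' shape variables onto a coefficient
vector:  s = y beta' (beta beta')^(-1/2), i.e. the scalar projection onto
the unit vector along beta.  It is invariant to positive rescaling of beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .blmm import PosteriorDraws

__all__ = [
    "EffectVector",
    "ShapeScore",
    "effect_vector",
    "vector_angle",
    "vector_correlation",
    "compare_effects",
    "shape_score",
    "score_axis_correlation",
    "score_shape_change",
]


@dataclass
class EffectVector:
    """Posterior draws of one predictor's coefficient vector over the shape
    variables (draws x p) plus their mean — the beta of the shape score."""

    predictor: str
    beta_draws: np.ndarray  # S x p
    beta_mean: np.ndarray  # p

    def __post_init__(self) -> None:
        self.beta_draws = np.atleast_2d(np.asarray(self.beta_draws, float))
        self.beta_mean = np.asarray(self.beta_mean, float)
        if self.beta_draws.shape[1] != self.beta_mean.shape[0]:
            raise ValueError("beta_mean length does not match draws")


def effect_vector(draws: PosteriorDraws, predictor: str) -> EffectVector:
    """Extract a predictor's coefficient-vector draws from a multivariate
    fit (one element per shape response, on the standardized scale)."""
    b = draws.fixed_draws(predictor)  # S x R
    return EffectVector(predictor, b, b.mean(axis=0))


@dataclass
class ShapeScore:
    """Specimen scores along a regression-defined shape direction."""

    scores: np.ndarray  # n
    beta_used: np.ndarray  # p
    shape_matrix: np.ndarray  # n x p, the y used


def vector_angle(v: np.ndarray, w: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        raise ValueError("zero vector has no direction")
    cos = np.clip(v @ w / (nv * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def vector_correlation(v: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation of the elements of two vectors."""
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    if v.shape != w.shape or v.size < 3:
        raise ValueError("vectors must share length >= 3")
    if v.std() == 0.0 or w.std() == 0.0:
        raise ValueError("constant vector has no correlation")
    return float(np.corrcoef(v, w)[0, 1])


def _angles_and_corrs(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise angles/correlations between paired rows of A and B."""
    angles = np.array([vector_angle(a, b) for a, b in zip(A, B)])
    corrs = np.array([vector_correlation(a, b) for a, b in zip(A, B)])
    return angles, corrs


def compare_effects(
    a: EffectVector, b: EffectVector, mode: str = "within"
) -> dict:
    """Posterior distribution of the angle and element-wise correlation
    between two effect directions.

    ``within`` pairs draw t of ``a`` with draw t of ``b`` (both effects from
    one model, one posterior).  ``between`` compares ``a``'s draws with
    ``b``'s mean vector and vice versa, concatenating the two sets (for
    effects taken from different models).  Reports means, 95% intervals and
    whether the interval contains the independence reference (90 degrees /
    zero correlation).
    """
    if a.beta_draws.shape[1] != b.beta_draws.shape[1]:
        raise ValueError("effect vectors have different lengths")
    if mode == "within":
        if a.beta_draws.shape[0] != b.beta_draws.shape[0]:
            raise ValueError("within-mode comparison needs paired draws")
        angles, corrs = _angles_and_corrs(a.beta_draws, b.beta_draws)
    elif mode == "between":
        ang1, cor1 = _angles_and_corrs(
            a.beta_draws, np.broadcast_to(b.beta_mean, a.beta_draws.shape)
        )
        ang2, cor2 = _angles_and_corrs(
            b.beta_draws, np.broadcast_to(a.beta_mean, b.beta_draws.shape)
        )
        angles = np.concatenate([ang1, ang2])
        corrs = np.concatenate([cor1, cor2])
    else:
        raise ValueError("mode must be 'within' or 'between'")

    a_lo, a_hi = np.quantile(angles, [0.025, 0.975])
    c_lo, c_hi = np.quantile(corrs, [0.025, 0.975])
    return {
        "pair": (a.predictor, b.predictor),
        "mode": mode,
        "angle_mean": float(angles.mean()),
        "angle_lower": float(a_lo),
        "angle_upper": float(a_hi),
        "angle_independent": bool(a_lo <= 90.0 <= a_hi),
        "correlation_mean": float(corrs.mean()),
        "correlation_lower": float(c_lo),
        "correlation_upper": float(c_hi),
        "correlation_independent": bool(c_lo <= 0.0 <= c_hi),
        "angles": angles,
        "correlations": corrs,
    }


def shape_score(y: np.ndarray, beta: np.ndarray) -> ShapeScore:
    """Shape score s = y beta' (beta beta')^(-1/2): the scalar projection of
    each specimen's shape variables onto the direction of beta."""
    y = np.atleast_2d(np.asarray(y, float))
    beta = np.asarray(beta, float).reshape(-1)
    if y.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape matrix has {y.shape[1]} variables, beta has {beta.shape[0]}"
        )
    norm = np.linalg.norm(beta)
    if norm == 0.0:
        raise ValueError("beta must be non-zero")
    return ShapeScore(scores=y @ beta / norm, beta_used=beta, shape_matrix=y)


def score_axis_correlation(
    score: ShapeScore, axis_scores: np.ndarray
) -> tuple[float, float]:
    """Pearson r (and p) of the shape score against a PC axis or any
    specimen-level covariate."""
    axis_scores = np.asarray(axis_scores, float)
    if axis_scores.shape[0] != score.scores.shape[0]:
        raise ValueError("length mismatch")
    if score.scores.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    if score.scores.std() == 0.0 or axis_scores.std() == 0.0:
        raise ValueError("constant input has no correlation")
    r, p = stats.pearsonr(score.scores, axis_scores)
    return float(r), float(p)


def score_shape_change(
    shapes: np.ndarray,
    score: ShapeScore,
    magnification: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Landmark-coordinate shape change along the shape score.

    Coordinates are regressed on the score; the two returned shapes sit at
    -/+ magnification * (score range)/2 along the fitted direction about the
    mean shape (exaggeration for display, as in wireframe figures).
    """
    shapes = np.asarray(shapes, float)
    orig_shape = shapes.shape[1:]
    flat = shapes.reshape(shapes.shape[0], -1)
    s = score.scores
    if flat.shape[0] != s.shape[0]:
        raise ValueError("score and shapes cover different specimens")
    sc = s - s.mean()
    denom = float(sc @ sc)
    if denom == 0.0:
        raise ValueError("degenerate score variance")
    slope = (sc @ (flat - flat.mean(axis=0))) / denom  # per-coordinate
    half_range = 0.5 * (s.max() - s.min())
    disp = magnification * half_range * slope
    mean = flat.mean(axis=0)
    return (mean - disp).reshape(orig_shape), (mean + disp).reshape(orig_shape)
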