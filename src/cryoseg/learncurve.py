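"""Learning-curve regression and sample-size planning.

Dice score as a function of training-set size x is fitted with two candidate
forms by weighted nonlinear least squares:

* exponential-log:  Dice = a * exp(b x) + c * ln(x + d) + e   (5 parameters)
* power law:        Dice = (1 - a) - b * x^c                  (3 parameters)

The weight of each point is j/m, the ratio of its training-set size to the
largest size on the curve, so large-sample points dominate the fit.  Model
selection uses the finite-sample-corrected Akaike criterion

    AICc = 2 p + 2 C + 2 p (p + 1) / (n - p - 1),

with p the parameter count, n the number of points, and C the (weighted) sum
of squared errors at the optimum; the lower AICc wins.  The fitted curve is
then inverted by integer scan for the smallest training-set size reaching a
target Dice (default 0.9), reporting "> x_max" when the curve never gets
there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LearningCurvePoint",
    "CurveFit",
    "CurveFitError",
    "curve_model",
    "make_points",
    "fit_curve",
    "aicc",
    "select_model",
    "samples_for_dice",
    "build_learning_curve",
    "design_sizes",
]


class CurveFitError(RuntimeError):
    """No optimizer start converged to a usable fit."""


@dataclass
class LearningCurvePoint:
    """One (training-set size, achieved Dice) point with its fit weight."""

    x: int
    dice: float
    weight: float

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("x must be a positive sample count")
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice must lie in [0, 1]")


@dataclass
class CurveFit:
    """A fitted learning-curve model and its AICc."""

    model_id: str  # "exp_log" (5 params) or "power" (3 params)
    params: tuple[float, ...]
    p: int
    C: float  # weighted SSE at the optimum
    n_points: int

    @property
    def aicc(self) -> float:
        return aicc(self)

    def predict(self, x) -> np.ndarray:
        return curve_model(self.model_id, self.params, x)


def curve_model(model_id: str, params, x) -> np.ndarray:
    """Evaluate one of the two learning-curve forms at sizes x."""
    x = np.asarray(x, dtype=np.float64)
    if model_id == "exp_log":
        a, b, c, d, e = params
        return a * np.exp(b * x) + c * np.log(x + d) + e
    if model_id == "power":
        a, b, c = params
        return (1.0 - a) - b * np.power(x, c)
    raise ValueError(f"unknown model_id {model_id!r}")


_N_PARAMS = {"exp_log": 5, "power": 3}

# Bounds keep the fits well-posed: decaying exponential (b <= 0), positive
# log shift (d > 0), decaying power term (c <= 0).
_BOUNDS = {
    "exp_log": (
        np.array([-np.inf, -5.0, -np.inf, 0.01, -np.inf]),
        np.array([np.inf, 0.0, np.inf, 1000.0, np.inf]),
    ),
    "power": (
        np.array([-np.inf, -np.inf, -5.0]),
        np.array([np.inf, np.inf, 0.0]),
    ),
}


def make_points(sizes, dices) -> list[LearningCurvePoint]:
    """Attach j/m weights (size over max size) to (size, dice) pairs."""
    sizes = list(sizes)
    m = max(sizes)
    return [
        LearningCurvePoint(int(j), float(d), float(j) / m)
        for j, d in zip(sizes, dices)
    ]


def _random_start(model_id: str, rng: np.random.Generator) -> np.ndarray:
    if model_id == "exp_log":
        return np.array([
            rng.uniform(-0.5, 0.5), rng.uniform(-1.0, -0.01),
            rng.uniform(-0.3, 0.3), rng.uniform(0.1, 50.0),
            rng.uniform(0.0, 1.0),
        ])
    return np.array([
        rng.uniform(-0.2, 0.4), rng.uniform(0.0, 2.0), rng.uniform(-2.0, -0.05),
    ])


def fit_curve(
    points: list[LearningCurvePoint],
    model_id: str,
    n_starts: int = 20,
    seed: int = 0,
) -> CurveFit:
    """Weighted bounded nonlinear least squares with multi-start.

    Minimizes sum_j w_j (dice_j - model(x_j))^2 from ``n_starts`` seeded
    random initializations within the bounds; the best weighted SSE is kept.
    """
    p = _N_PARAMS[model_id]
    if len(points) <= p:
        raise ValueError(f"need more than {p} points to fit {model_id}")
    xs = np.array([pt.x for pt in points], dtype=np.float64)
    if len(np.unique(xs)) != len(xs):
        raise ValueError("x values must be distinct")
    ys = np.array([pt.dice for pt in points])
    sw = np.sqrt(np.array([pt.weight for pt in points]))

    def residuals(theta):
        return sw * (ys - curve_model(model_id, theta, xs))

    lo, hi = _BOUNDS[model_id]
    rng = np.random.default_rng(seed)
    best = None
    last_err = None
    for _ in range(n_starts):
        theta0 = np.clip(_random_start(model_id, rng), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=150)
        except Exception as exc:  # pragma: no cover - solver failure path
            last_err = exc
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, tuple(float(v) for v in res.x))
        if best[0] < 1e-12:  # an (effectively) exact fit: further starts cannot win
            break
    if best is None:
        raise CurveFitError(
            f"no start of the {model_id} fit converged "
            f"(last solver error: {last_err})"
        )
    return CurveFit(model_id, best[1], p, best[0], len(points))


def aicc(fit: CurveFit) -> float:
    """Finite-sample-corrected AIC: 2p + 2C + 2p(p+1)/(n-p-1)."""
    n, p = fit.n_points, fit.p
    if n - p - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, p={p} (need n > p + 1)")
    return 2.0 * p + 2.0 * fit.C + 2.0 * p * (p + 1) / (n - p - 1)


def select_model(points: list[LearningCurvePoint], seed: int = 0) -> CurveFit:
    """Fit both curve forms and return the one with the lower AICc."""
    fits = []
    errors = []
    for model_id in ("exp_log", "power"):
        try:
            fits.append(fit_curve(points, model_id, seed=seed))
        except (ValueError, CurveFitError) as exc:
            errors.append(exc)
    if not fits:
        raise CurveFitError(f"both curve fits failed: {errors}")
    return min(fits, key=lambda f: f.aicc)


def samples_for_dice(
    fit: CurveFit, target: float = 0.9, x_max: int = 1000
) -> int | str:
    """Smallest integer x with model(x) >= target, by integer scan.

    Returns the string ``"> {x_max}"`` when the fitted curve never reaches
    the target within the scan bound.
    """
    xs = np.arange(1, x_max + 1)
    preds = fit.predict(xs)
    hits = np.nonzero(preds >= target)[0]
    if hits.size == 0:
        return f"> {x_max}"
    return int(xs[hits[0]])


def design_sizes(largest: int = 63, smallest: int = 7, step: int = 8) -> list[int]:
    """Training-set sizes of the learning-curve design: 63, 55, ..., 7."""
    return list(range(largest, smallest - 1, -step))


def build_learning_curve(
    pool_size: int,
    sizes: list[int],
    train_eval_fn,
    seed: int = 0,
) -> list[LearningCurvePoint]:
    """Run the learning-curve experiment over a pool of training cases.

    For each size a random subset of the pool is drawn (seeded, validation
    and test sets stay fixed inside ``train_eval_fn``), the model is trained
    and evaluated, and the resulting mean Dice becomes one curve point with
    weight j/m.  ``train_eval_fn(subset_indices, sub_seed)`` must return the
    achieved Dice score in [0, 1].
    """
    if any(s > pool_size for s in sizes):
        raise ValueError("a requested size exceeds the training pool")
    rng = np.random.default_rng(seed)
    dices = []
    for size in sizes:
        subset = rng.choice(pool_size, size=size, replace=False)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dices.append(float(train_eval_fn(np.sort(subset), sub_seed)))
    return make_points(sizes, dices)
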