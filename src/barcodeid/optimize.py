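"""Seeded Bayesian optimization over box-bounded hyperparameter spaces.

Maximizes a black-box objective over a mix of integer and continuous
parameters.  Two proposal strategies:

``random``
    Pure random search: every point uniform over the box.
``gp``
    Random initial points, then a Gaussian-process surrogate (Matern 5/2,
    normalized outputs) with expected-improvement acquisition maximized over
    a seeded random candidate set.

All randomness flows from one ``numpy`` generator, so a fixed seed fixes the
full proposal sequence.  A proposal whose objective comes back non-finite is
recorded with score -inf and the search continues; such points are excluded
from the surrogate fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = ["Parameter", "Evaluation", "BayesianSearch"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Parameter:
    """One box-bounded search dimension."""

    name: str
    low: float
    high: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")

    def from_unit(self, u: float) -> float | int:
        """Map a unit-interval coordinate to a parameter value."""
        value = self.low + u * (self.high - self.low)
        if self.integer:
            return int(min(max(round(value), math.ceil(self.low)), math.floor(self.high)))
        return float(value)


@dataclass
class Evaluation:
    """One evaluated point: parameters, objective, auxiliary scores."""

    params: dict[str, float | int]
    objective: float
    aux: dict[str, float]
    best_so_far: float


class BayesianSearch:
    """Sequential maximizer of an expensive black-box objective.

    Parameters
    ----------
    space:
        Search dimensions.
    init_points:
        Number of uniform random evaluations before guided proposals.
    n_iter:
        Number of guided (or further random) evaluations.
    strategy:
        ``"gp"`` (default) or ``"random"``.
    seed:
        Seed for the proposal generator and the surrogate fit.
    n_candidates:
        Size of the random candidate set over which the acquisition is
        maximized each guided step.
    """

    def __init__(
        self,
        space: Sequence[Parameter],
        init_points: int = 5,
        n_iter: int = 25,
        strategy: str = "gp",
        seed: int = 0,
        n_candidates: int = 512,
        xi: float = 0.01,
    ) -> None:
        if strategy not in ("gp", "random"):
            raise ValueError(f"unknown strategy {strategy!r}")
        if init_points < 1 or n_iter < 0:
            raise ValueError("need init_points >= 1 and n_iter >= 0")
        self.space = list(space)
        self.init_points = init_points
        self.n_iter = n_iter
        self.strategy = strategy
        self.seed = seed
        self.n_candidates = n_candidates
        self.xi = xi
        self.history: list[Evaluation] = []

    # -- internals -----------------------------------------------------------

    def _to_params(self, unit: np.ndarray) -> dict[str, float | int]:
        return {p.name: p.from_unit(u) for p, u in zip(self.space, unit)}

    def _propose(self, rng: np.random.Generator, X: list[np.ndarray], y: list[float]) -> np.ndarray:
        finite = [(x, v) for x, v in zip(X, y) if math.isfinite(v)]
        if self.strategy == "random" or len(finite) < 2:
            return rng.random(len(self.space))
        Xf = np.vstack([x for x, _ in finite])
        yf = np.asarray([v for _, v in finite])
        # fixed length scale on the unit cube: objectives here are smooth and
        # flat near the optimum, and marginal-likelihood fits degenerate on
        # the handful of points a small budget provides
        gp = GaussianProcessRegressor(
            kernel=Matern(
                nu=2.5,
                length_scale=np.full(len(self.space), 0.25),
                length_scale_bounds="fixed",
            ),
            alpha=1e-6,
            normalize_y=True,
            optimizer=None,
            random_state=self.seed,
        )
        gp.fit(Xf, yf)
        candidates = rng.random((self.n_candidates, len(self.space)))
        mu, sigma = gp.predict(candidates, return_std=True)
        best = yf.max()
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best - self.xi) / sigma
        ei = (mu - best - self.xi) * norm.cdf(z) + sigma * norm.pdf(z)
        return candidates[int(np.argmax(ei))]

    # -- public API ----------------------------------------------------------

    def maximize(
        self,
        objective: Callable[[Mapping[str, float | int]], tuple[float, dict[str, float]]],
    ) -> Evaluation:
        """Run the search; returns the best evaluation.

        ``objective(params)`` returns ``(score, aux)`` where ``aux`` holds any
        auxiliary scores worth keeping alongside the objective (used by the
        caller for tie-breaking).  The running best-so-far is recorded on
        every evaluation, so it is non-decreasing along ``history``.
        """
        rng = np.random.default_rng(self.seed)
        X: list[np.ndarray] = []
        y: list[float] = []
        best_eval: Evaluation | None = None
        total = self.init_points + self.n_iter
        for step in range(total):
            if step < self.init_points:
                unit = rng.random(len(self.space))
            else:
                unit = self._propose(rng, X, y)
            params = self._to_params(unit)
            score, aux = objective(params)
            if not math.isfinite(score):
                logger.warning("non-finite objective at %s; scored as -inf", params)
                score = float("-inf")
            X.append(unit)
            y.append(score)
            best = max(y)
            evaluation = Evaluation(
                params=params, objective=score, aux=aux, best_so_far=best
            )
            self.history.append(evaluation)
            if best_eval is None or score > best_eval.objective:
                best_eval = evaluation
            logger.info(
                "eval %d/%d: objective=%.4f best=%.4f params=%s",
                step + 1, total, score, best, params,
            )
        assert best_eval is not None
        return best_eval
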