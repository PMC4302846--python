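"""Uniform sampling of the feasible flux polytope and flux correlations.

The sampler is the artificially centered hit-and-run (ACHR) scheme: warmup
points are obtained by optimizing random objective directions over the
polytope, then the chain repeatedly picks a stored point, takes the direction
from the running center through it, and moves the current point to a uniform
position on the feasible chord.  Directions are differences of feasible
points, so they lie in the null space of the balance constraints by
construction; accumulated floating-point drift is removed by periodic
projection back onto the affine constraint space.

The default chain parameters (warmup = min(2 * n_fluxes, 2000) points,
thinning = 100, mandatory seed) favor reproducibility; every recorded sample
is checked against the balances (1e-6) and bounds (1e-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import ModelError, WholePlantModel
from .optimize import LPProblem, model_lp, _with_objective_fixed

__all__ = [
    "Polytope",
    "SampleSet",
    "CorrelationMatrix",
    "achr_sample",
    "sample_polytope",
    "correlate",
]

BALANCE_TOL = 1e-6
BOUND_TOL = 1e-9

#: re-project the chain onto the affine constraint space this often
_PROJECT_EVERY = 50


class SamplingError(RuntimeError):
    pass


@dataclass
class Polytope:
    """{x : A x = b, lb <= x <= ub} with named coordinates."""

    A: sparse.spmatrix
    b: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.lb)) and np.all(np.isfinite(self.ub))):
            raise SamplingError(
                "polytope is potentially unbounded: tighten the infinite "
                "flux bounds before sampling"
            )
        self._pinv = None

    @classmethod
    def from_model(
        cls, model: WholePlantModel, fix_objective_at: float | None = None
    ) -> "Polytope":
        lp = model_lp(model)
        if fix_objective_at is not None:
            lp = _with_objective_fixed(lp, lp.c, fix_objective_at)
        return cls(lp.A.tocsr(), lp.b, lp.lb, lp.ub, model.column_ids)

    # -- geometry helpers -------------------------------------------------
    def residual(self, x: np.ndarray) -> float:
        if self.A.shape[0] == 0:
            return 0.0
        return float(np.max(np.abs(self.A @ x - self.b)))

    def project(self, x: np.ndarray) -> np.ndarray:
        """Least-squares projection onto {A x = b} (exact for small models)."""
        if self.A.shape[0] == 0:
            return x
        if self._pinv is None:
            self._pinv = np.linalg.pinv(self.A.toarray())
        return x - self._pinv @ (self.A @ x - self.b)

    def contains(self, x: np.ndarray,
                 balance_tol: float = BALANCE_TOL,
                 bound_tol: float = BOUND_TOL) -> bool:
        return (
            self.residual(x) <= balance_tol
            and np.all(x >= self.lb - bound_tol)
            and np.all(x <= self.ub + bound_tol)
        )


@dataclass
class SampleSet:
    samples: np.ndarray  # n_samples x n_fluxes
    flux_ids: list[str]
    seed: int
    n_warmup: int
    thinning: int
    scenario_tag: str = ""

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, flux_id: str) -> np.ndarray:
        return self.samples[:, self.flux_ids.index(flux_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.samples, columns=self.flux_ids)


def _warmup_points(poly: Polytope, n_warmup: int, rng: np.random.Generator):
    """Vertices found by optimizing random +-coordinate and Gaussian mixes."""
    n = len(poly.lb)
    points = []
    for k in range(n_warmup):
        if n_warmup >= 2 * n and k < 2 * n:
            c = np.zeros(n)
            c[k // 2] = 1.0 if k % 2 else -1.0
        else:
            c = rng.standard_normal(n)
        lp = LPProblem(c, poly.A.tocsc(), poly.b, poly.lb, poly.ub)
        res = lp.solve()
        if res.status == "infeasible":
            raise SamplingError("polytope is empty (infeasible constraints)")
        if res.status != "optimal":
            raise SamplingError(f"warmup LP ended with status {res.status!r}")
        points.append(res.x)
    pts = np.array(points)
    return pts


def sample_polytope(
    poly: Polytope,
    n_samples: int,
    seed: int,
    n_warmup: int | None = None,
    thinning: int = 100,
    scenario_tag: str = "",
) -> SampleSet:
    """Draw near-uniform points from a bounded polytope with ACHR."""
    if n_samples < 1:
        raise ModelError("n_samples must be >= 1")
    if thinning < 1:
        raise ModelError("thinning must be >= 1")
    n = len(poly.lb)
    if n_warmup is None:
        n_warmup = min(2 * n, 2000)
    n_warmup = max(n_warmup, 2)
    rng = np.random.default_rng(seed)
    warmup = _warmup_points(poly, n_warmup, rng)

    center = warmup.mean(axis=0)
    x = center.copy()
    n_centered = n_warmup
    free = (poly.ub - poly.lb) > BOUND_TOL  # fixed coordinates never move

    records = np.empty((n_samples, n), dtype=float)
    recorded = 0
    step = 0
    while recorded < n_samples:
        step += 1
        d = warmup[rng.integers(n_warmup)] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        d[~free] = 0.0
        # chord of the bounding box along d through x
        with np.errstate(divide="ignore", invalid="ignore"):
            to_ub = np.where(np.abs(d) > 1e-12, (poly.ub - x) / d, np.nan)
            to_lb = np.where(np.abs(d) > 1e-12, (poly.lb - x) / d, np.nan)
        alphas = np.concatenate([to_ub, to_lb])
        pos = alphas[alphas > 0]
        neg = alphas[alphas < 0]
        a_max = np.min(pos) if pos.size else 0.0
        a_min = np.max(neg) if neg.size else 0.0
        if a_max - a_min < 1e-12:
            continue
        x = x + rng.uniform(a_min, a_max) * d
        n_centered += 1
        center += (x - center) / n_centered
        if step % _PROJECT_EVERY == 0:
            x = poly.project(x)
            np.clip(x, poly.lb, poly.ub, out=x)
        if step % thinning == 0:
            x = poly.project(x)
            np.clip(x, poly.lb, poly.ub, out=x)
            if not poly.contains(x):
                raise SamplingError(
                    "chain left the polytope beyond tolerance; the constraint "
                    "matrix may be badly conditioned"
                )
            records[recorded] = x
            recorded += 1
    return SampleSet(records, list(poly.names), seed, n_warmup, thinning,
                     scenario_tag)


def achr_sample(
    model: WholePlantModel,
    n_samples: int = 100_000,
    seed: int = 0,
    n_warmup: int | None = None,
    thinning: int = 100,
    fix_objective_at: float | None = None,
) -> SampleSet:
    """Sample the flux polytope of an assembled model.

    Remove blocked reactions first (:func:`multigem.optimize.remove_blocked`);
    pass ``fix_objective_at=z_opt`` to sample the photon-optimal face instead
    of the full scenario polytope.
    """
    poly = Polytope.from_model(model, fix_objective_at=fix_objective_at)
    tag = "optimum-fixed" if fix_objective_at is not None else "scenario"
    return sample_polytope(poly, n_samples, seed, n_warmup, thinning, tag)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    rho: np.ndarray  # n_included x n_included, symmetric, unit diagonal
    flux_ids: list[str]  # included fluxes, in rho order
    excluded: set[str] = field(default_factory=set)

    def pair(self, a: str, b: str) -> float:
        return float(
            self.rho[self.flux_ids.index(a), self.flux_ids.index(b)]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.flux_ids,
                            columns=self.flux_ids)


def correlate(samples: SampleSet, variance_floor: float = 1e-12) -> CorrelationMatrix:
    """Pearson correlation of every flux pair across the samples.

    Fluxes whose sample variance falls below ``variance_floor`` (constant or
    numerically constant) are excluded from the matrix and reported in
    ``excluded`` rather than yielding undefined correlations.
    """
    if samples.n_samples < 2:
        raise ModelError("need at least 2 samples to correlate")
    variances = samples.samples.var(axis=0)
    keep = variances >= variance_floor
    excluded = {fid for fid, k in zip(samples.flux_ids, keep) if not k}
    kept_ids = [fid for fid, k in zip(samples.flux_ids, keep) if k]
    if not kept_ids:
        return CorrelationMatrix(np.empty((0, 0)), [], excluded)
    rho = np.corrcoef(samples.samples[:, keep], rowvar=False)
    rho = np.atleast_2d(rho)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho, kept_ids, excluded)
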