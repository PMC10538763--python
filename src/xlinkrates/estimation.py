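"""Bounded maximum-likelihood estimation of recombination and mutation rates.

Minimizes the dataset negative log-likelihood over the 2n-1 parameters
(n-1 recombination rates, n mutation rates) with L-BFGS-B box constraints
[eps, 0.5]; mutation rates can alternatively be shared across markers or
fixed.  Non-convergence is reported, never silently accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .likelihood import (
    LikelihoodZeroError,
    RateParams,
    TypeIBatch,
    TypeIIEvaluator,
    dataset_negloglik,
)
from .pedigree_io import MarkerPanel

__all__ = ["EstimationConfig", "EstimationResult", "EstimationError", "estimate_rates"]

logger = logging.getLogger("xlinkrates")

MU_MODES = ("per-marker", "shared", "fixed")


class EstimationError(ValueError):
    pass


@dataclass
class EstimationConfig:
    engine: str = "dynamic"
    mu_mode: str = "per-marker"
    fixed_mu: float = 0.001
    theta0: float = 0.1
    mu0: float = 0.001
    lower: float = 1e-8
    upper: float = 0.5
    max_iter: int = 15000
    max_dense_phasings: int = 1024
    check_flatness: bool = True

    def __post_init__(self) -> None:
        if self.mu_mode not in MU_MODES:
            raise EstimationError(f"mu_mode must be one of {MU_MODES}")
        if self.engine not in ("dynamic", "direct"):
            raise EstimationError("engine must be 'dynamic' or 'direct'")
        if not (0.0 < self.lower < self.upper <= 0.5):
            raise EstimationError(
                f"invalid bounds [{self.lower}, {self.upper}]; need 0 < lower < upper <= 0.5"
            )
        if self.fixed_mu < 0 or self.fixed_mu > 0.5:
            raise EstimationError("fixed_mu must lie in [0, 0.5]")


@dataclass
class EstimationResult:
    theta_hat: np.ndarray
    mu_hat: Optional[np.ndarray]
    converged: bool
    final_negloglik: float
    n_iterations: int
    message: str
    initial_negloglik: float = float("nan")
    flat_theta: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _infer_n_markers(families) -> int:
    lengths = {len(fam.children[0]) for fam in families}
    if len(lengths) != 1:
        raise EstimationError(f"families disagree on marker count: {sorted(lengths)}")
    return lengths.pop()


def estimate_rates(families: Sequence, panel: MarkerPanel,
                   config: Optional[EstimationConfig] = None) -> EstimationResult:
    """Fit rates to the extracted families by bounded likelihood maximization."""
    if not families:
        raise EstimationError("no informative families to estimate from")
    config = config or EstimationConfig()
    n = panel.n_markers
    if _infer_n_markers(families) != n:
        raise EstimationError("family haplotype length does not match the panel")

    type_i = [f for f in families if f.kind == "typeI"]
    type_ii = [f for f in families if f.kind == "typeII"]

    if config.engine == "dynamic":
        batch = TypeIBatch(type_i, panel)
        evaluators = [
            TypeIIEvaluator(f, panel, config.max_dense_phasings) for f in type_ii
        ]

        def negloglik(theta: np.ndarray, mu: np.ndarray) -> float:
            params = RateParams(theta, mu)
            total = batch.negloglik(theta, mu)
            dead = []
            for ev in evaluators:
                value = ev.loglik(params)
                if value == -np.inf:
                    dead.append(ev.provenance)
                else:
                    total -= value
            if dead:
                raise LikelihoodZeroError(dead)
            return total
    else:
        def negloglik(theta: np.ndarray, mu: np.ndarray) -> float:
            return dataset_negloglik(
                families, RateParams(theta, mu), panel, engine="direct"
            )

    n_theta = n - 1
    if config.mu_mode == "per-marker":
        n_mu = n
    elif config.mu_mode == "shared":
        n_mu = 1
    else:
        n_mu = 0
    fixed_mu = np.full(n, config.fixed_mu)

    def unpack(x: np.ndarray) -> tuple:
        theta = x[:n_theta]
        if config.mu_mode == "per-marker":
            mu = x[n_theta:]
        elif config.mu_mode == "shared":
            mu = np.full(n, x[n_theta])
        else:
            mu = fixed_mu
        return theta, mu

    def objective(x: np.ndarray) -> float:
        return negloglik(*unpack(x))

    x0 = np.concatenate([
        np.full(n_theta, np.clip(config.theta0, config.lower, config.upper)),
        np.full(n_mu, np.clip(config.mu0, config.lower, config.upper)),
    ])
    bounds = [(config.lower, config.upper)] * len(x0)

    try:
        f0 = objective(x0)
    except LikelihoodZeroError as exc:
        raise EstimationError(
            f"cannot start estimation: {exc}"
        ) from exc

    result = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.max_iter, "maxfun": max(2 * config.max_iter, 15000)},
    )

    theta_hat, mu_full = unpack(np.clip(result.x, config.lower, config.upper))
    theta_hat = np.asarray(theta_hat, dtype=float).copy()
    mu_hat = None if config.mu_mode == "fixed" else np.asarray(mu_full, dtype=float).copy()

    warnings_list = []
    flat = []
    if config.check_flatness and n_theta and len(x0) <= 256:
        flat = _flat_thetas(objective, result.x, result.fun, n_theta, config)
        for i in flat:
            warnings_list.append(
                f"theta[{i}] is flat (data carry no information on this interval); "
                "the reported value reflects the initial point"
            )
    if not result.success:
        warnings_list.append(f"optimizer did not converge: {result.message}")
        logger.warning("optimizer did not converge: %s", result.message)

    return EstimationResult(
        theta_hat=theta_hat,
        mu_hat=mu_hat,
        converged=bool(result.success),
        final_negloglik=float(result.fun),
        n_iterations=int(result.nit),
        message=str(result.message),
        initial_negloglik=float(f0),
        flat_theta=flat,
        warnings=warnings_list,
    )


def _flat_thetas(objective, x_opt, f_opt, n_theta, config, delta=1e-3, tol=1e-9):
    """Indices of recombination parameters the likelihood does not depend on."""
    flat = []
    for i in range(n_theta):
        changed = False
        for sign in (+1, -1):
            x = x_opt.copy()
            x[i] = np.clip(x[i] + sign * delta, config.lower, config.upper)
            if x[i] == x_opt[i]:
                continue
            try:
                if abs(objective(x) - f_opt) > tol:
                    changed = True
                    break
            except LikelihoodZeroError:
                changed = True
                break
        if not changed:
            flat.append(i)
    return flat
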