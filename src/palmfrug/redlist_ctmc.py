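"""Continuous-time Markov chain model of IUCN Red List category change.

The chain runs over the ordered categories LC, NT, VU, EN, CR, EX, where EX
merges Extinct, Extinct in the Wild and Critically Endangered taxa flagged as
possibly extinct. Instantaneous transitions are allowed only between adjacent
ranks, so the generator Q is tridiagonal with nonnegative off-diagonals and
rows summing to zero. Transition probabilities over an elapsed time ``t`` are
``P(t) = expm(Q t)``; observed category changes across species are treated as
independent realizations of the chain, giving the log-likelihood
``sum_ij n_ij * log P_ij(t)`` for a table of start/end counts ``n_ij``.

Rates are estimated by maximum likelihood in log-rate space with random
restarts; uncertainty is assessed by parametric bootstrap. The fitted chain
yields per-category probabilities of absorption into EX over a horizon
(default 100 years), the "low" defaunation scenario. The "high" scenario uses
externally supplied constant per-category extinction rates via
``P_ext = 1 - exp(-r t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

CATEGORIES: tuple[str, ...] = ("LC", "NT", "VU", "EN", "CR", "EX")
N_CAT = len(CATEGORIES)
#: transitions appearing in the generator, in parameter order: 5 up, 5 down
UP_TRANSITIONS = tuple((i, i + 1) for i in range(N_CAT - 1))
DOWN_TRANSITIONS = tuple((i + 1, i) for i in range(N_CAT - 1))


@dataclass(frozen=True)
class RateMatrix:
    """Tridiagonal CTMC generator over the six Red List categories."""

    up: np.ndarray    # rates LC->NT, NT->VU, VU->EN, EN->CR, CR->EX
    down: np.ndarray  # rates NT->LC, VU->NT, EN->VU, CR->EN, EX->CR
    fix_ex_cr_zero: bool = True

    def __post_init__(self) -> None:
        up = np.asarray(self.up, dtype=float)
        down = np.asarray(self.down, dtype=float)
        if up.shape != (N_CAT - 1,) or down.shape != (N_CAT - 1,):
            raise ValueError(f"expected {N_CAT - 1} up and down rates")
        if np.any(up < 0) or np.any(down < 0):
            raise ValueError("transition rates must be nonnegative")
        if self.fix_ex_cr_zero:
            down = down.copy()
            down[-1] = 0.0  # EX -> CR suppressed: EX is absorbing
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    @property
    def q(self) -> np.ndarray:
        """The 6x6 generator matrix (rows sum to zero)."""
        q = np.zeros((N_CAT, N_CAT))
        for k, (i, j) in enumerate(UP_TRANSITIONS):
            q[i, j] = self.up[k]
        for k, (i, j) in enumerate(DOWN_TRANSITIONS):
            q[i, j] = self.down[k]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def to_series(self) -> pd.Series:
        idx = [f"{CATEGORIES[i]}->{CATEGORIES[j]}" for i, j in UP_TRANSITIONS]
        idx += [f"{CATEGORIES[i]}->{CATEGORIES[j]}" for i, j in DOWN_TRANSITIONS]
        return pd.Series(np.concatenate([self.up, self.down]), index=idx)


def build_rate_matrix(up_rates, down_rates, fix_ex_cr_zero: bool = True) -> RateMatrix:
    """Assemble the adjacent-rank generator from 5 up- and 5 down-rates."""
    return RateMatrix(np.asarray(up_rates, float), np.asarray(down_rates, float),
                      fix_ex_cr_zero=fix_ex_cr_zero)


def transition_matrix(q: RateMatrix, t: float) -> np.ndarray:
    """Row-stochastic transition probabilities ``P(t) = expm(Q t)``."""
    if t < 0:
        raise ValueError("elapsed time must be nonnegative")
    if t == 0:
        return np.eye(N_CAT)
    p = expm(q.q * t)
    # expm can leave tiny negative round-off; clip and renormalize
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


@dataclass
class TransitionCountTable:
    """Counts n_ij of species starting in category i and ending in j."""

    counts: np.ndarray
    elapsed_years: float
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CAT, N_CAT):
            raise ValueError(f"counts must be {N_CAT}x{N_CAT}")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.elapsed_years <= 0:
            raise ValueError("elapsed_years must be positive")
        self.counts = c.astype(np.int64)

    @property
    def n_species(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CATEGORIES), columns=list(CATEGORIES))


def ctmc_loglik(q: RateMatrix, counts: TransitionCountTable) -> float:
    """Log-likelihood sum_ij n_ij log P_ij(t); -inf if an observed cell has P=0."""
    p = transition_matrix(q, counts.elapsed_years)
    n = counts.counts
    observed = n > 0
    if np.any(p[observed] <= 0):
        return -np.inf
    return float(np.sum(n[observed] * np.log(p[observed])))


@dataclass
class CtmcFit:
    """Maximum-likelihood CTMC fit with optional bootstrap replicates."""

    rate_matrix: RateMatrix
    loglik: float
    converged: bool
    n_restarts_succeeded: int
    boundary_rates: list[str] = field(default_factory=list)
    bootstrap: pd.DataFrame | None = None


def _pack(q: RateMatrix, fix: bool) -> np.ndarray:
    rates = np.concatenate([q.up, q.down[:-1] if fix else q.down])
    return np.log(np.maximum(rates, 1e-12))


def _unpack(x: np.ndarray, fix: bool) -> RateMatrix:
    rates = np.exp(x)
    up = rates[:5]
    down = np.append(rates[5:], 0.0) if fix else rates[5:]
    return RateMatrix(up, down, fix_ex_cr_zero=fix)


def fit_ctmc(counts: TransitionCountTable, fix_ex_cr_zero: bool = True,
             restarts: int = 10, seed: int | None = None) -> CtmcFit:
    """Estimate rates by ML with random multi-start optimization in log-rate space.

    Log-rates are initialized uniformly in [-8, 0]; the best converged restart
    is returned. Rates that collapse toward zero (below 1e-6 per year) are
    flagged as boundary estimates.
    """
    if counts.n_species < 1:
        raise ValueError("need at least one observed species transition")
    rng = np.random.default_rng(seed)
    fix = fix_ex_cr_zero
    n_par = 9 if fix else 10

    def nll(x: np.ndarray) -> float:
        ll = ctmc_loglik(_unpack(x, fix), counts)
        return np.inf if not np.isfinite(ll) else -ll

    best, best_val, n_ok = None, np.inf, 0
    for _ in range(restarts):
        x0 = rng.uniform(-8.0, 0.0, size=n_par)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-14.0, 3.0)] * n_par)
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best_val:
                best, best_val = res, res.fun
    if best is None:
        raise RuntimeError("all optimization restarts failed")

    q_hat = _unpack(best.x, fix)
    boundary = [name for name, r in q_hat.to_series().items()
                if 0.0 < r < 1e-6]
    return CtmcFit(rate_matrix=q_hat, loglik=-best_val, converged=bool(best.success),
                   n_restarts_succeeded=n_ok, boundary_rates=boundary)


def bootstrap_rates(fit: CtmcFit, counts: TransitionCountTable, n_boot: int,
                    seed: int | None = None, restarts: int = 3) -> pd.DataFrame:
    """Parametric bootstrap: resample end categories from the fitted P(t),
    keeping observed start-category totals, and refit each replicate.

    Returns one row per successful replicate with the refitted rates; failed
    refits are counted in the ``n_failed`` attribute of the frame.
    """
    rng = np.random.default_rng(seed)
    p = transition_matrix(fit.rate_matrix, counts.elapsed_years)
    starts = counts.counts.sum(axis=1)
    rows, n_failed = [], 0
    for _ in range(n_boot):
        sim = np.zeros((N_CAT, N_CAT), dtype=np.int64)
        for i in range(N_CAT):
            if starts[i] > 0:
                sim[i] = rng.multinomial(starts[i], p[i])
        table = TransitionCountTable(sim, counts.elapsed_years, label=f"boot:{counts.label}")
        try:
            refit = fit_ctmc(table, fix_ex_cr_zero=fit.rate_matrix.fix_ex_cr_zero,
                             restarts=restarts, seed=int(rng.integers(2**31 - 1)))
            rows.append(refit.rate_matrix.to_series())
        except (RuntimeError, ValueError):
            n_failed += 1
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.attrs["n_failed"] = n_failed
    return out


def average_rates(*fits: CtmcFit) -> RateMatrix:
    """Element-wise arithmetic mean of rate estimates across dataset fits.

    Rates held fixed at zero in a fit (EX->CR under the absorbing flag) enter
    the mean as zeros.
    """
    if not fits:
        raise ValueError("need at least one fit")
    up = np.mean([f.rate_matrix.up for f in fits], axis=0)
    down = np.mean([f.rate_matrix.down for f in fits], axis=0)
    fix = all(f.rate_matrix.fix_ex_cr_zero for f in fits)
    return RateMatrix(up, down, fix_ex_cr_zero=fix)


def extinction_probs_ctmc(q_average: RateMatrix, horizon: float = 100.0) -> pd.Series:
    """Per-category probability of being in EX after ``horizon`` years."""
    p = transition_matrix(q_average, horizon)
    out = pd.Series(p[:, N_CAT - 1], index=list(CATEGORIES), name="p_ext")
    out.attrs["scenario"] = "low"
    out.attrs["horizon"] = horizon
    return out


def extinction_probs_constant_rate(rates_by_category: dict[str, float] | pd.Series,
                                   horizon: float = 100.0) -> pd.Series:
    """Constant-rate extinction probabilities ``P_ext,i = 1 - exp(-r_i t)``."""
    rates = pd.Series(rates_by_category, dtype=float)
    if (rates < 0).any():
        raise ValueError("extinction rates must be nonnegative")
    out = pd.Series(1.0 - np.exp(-rates * horizon), index=rates.index, name="p_ext")
    out.attrs["scenario"] = "high"
    out.attrs["horizon"] = horizon
    return out


#: Per-category 100-year extinction probabilities commonly derived from Red
#: List criterion E, used as the default "high" scenario; converted to
#: constant rates. Override via config for other scenarios.
DEFAULT_HIGH_SCENARIO_P100: dict[str, float] = {
    "LC": 0.001, "NT": 0.01, "VU": 0.1, "EN": 0.667, "CR": 0.999,
}


def default_high_scenario_rates(horizon: float = 100.0) -> pd.Series:
    """Constant per-category rates implied by the default 100-year probabilities."""
    p = pd.Series(DEFAULT_HIGH_SCENARIO_P100, dtype=float)
    return -np.log(1.0 - p) / horizon
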