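"""Rank-correlation sensitivity analysis of the HQ output.

Attribution follows the spreadsheet risk-analysis convention: Spearman
rank correlation between each stochastic input's draws and the HQ draws,
normalized to signed contribution-to-variance percentages

    contribution_i = sign(rho_i) * 100 * rho_i^2 / sum_j rho_j^2 .

Fixed inputs are excluded (correlation with a constant is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .simulation import SimulationResult

__all__ = [
    "ParamSensitivity",
    "SensitivityResult",
    "spearman_rho",
    "contribution_to_variance",
    "sensitivity_analysis",
]


@dataclass(frozen=True)
class ParamSensitivity:
    name: str
    rho: float
    contribution_pct: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rho": self.rho,
            "contribution_pct": self.contribution_pct,
        }


@dataclass(frozen=True)
class SensitivityResult:
    """Per-parameter rank correlations with HQ, ranked by |rho|."""

    records: list[ParamSensitivity]
    ranking: list[str]

    def to_dict(self) -> dict:
        return {
            "records": [r.to_dict() for r in self.records],
            "ranking": list(self.ranking),
        }


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Constant vectors have undefined rank
    correlation and raise a :class:`DomainError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DomainError("rank correlation is undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def contribution_to_variance(rhos: dict[str, float]) -> dict[str, float]:
    """Signed contribution-to-variance percentages from rank correlations."""
    total = sum(r * r for r in rhos.values())
    if total == 0.0:
        raise DomainError("contribution undefined when all correlations are zero")
    return {
        name: float(np.sign(r)) * 100.0 * r * r / total for name, r in rhos.items()
    }


def sensitivity_analysis(sim: SimulationResult) -> SensitivityResult:
    """Attribute HQ output uncertainty to each stochastic input of a run.

    Requires the simulation to have retained its per-iteration input
    draws and at least two stochastic parameters; fixed parameters are
    excluded from the chart entirely.
    """
    params = sim.scenario.stochastic_params()
    if len(params) < 1:
        raise DomainError("no stochastic parameters to analyze")
    rhos = {p: spearman_rho(sim.input_draws[p], sim.hq_draws) for p in params}
    contrib = contribution_to_variance(rhos)
    ranking = sorted(params, key=lambda p: abs(rhos[p]), reverse=True)
    records = [
        ParamSensitivity(name=p, rho=rhos[p], contribution_pct=contrib[p])
        for p in ranking
    ]
    return SensitivityResult(records=records, ranking=ranking)
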