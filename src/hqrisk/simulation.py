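"""Monte-Carlo propagation of input distributions through the HQ model.

Each iteration draws the seven model inputs (Ci, IR, EF, ED, BW, AT, RfD)
from their declared distributions and pushes them through the same
:func:`~hqrisk.risk_model.compute_edi` / :func:`~hqrisk.risk_model.compute_hq`
arithmetic as the deterministic assessment, yielding an HQ distribution.
Inputs are treated as mutually independent; draws are retained per
parameter for downstream sensitivity analysis.

Convergence is checked in the style of the source method: two
independently seeded replicate runs must agree on mean, median and 95th
percentile within a relative tolerance (default 1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import (
    DistributionSpec,
    RandomStream,
    lognormal_underlying_params,
    sample,
)
from .errors import ConfigurationError, DomainError
from .risk_model import (
    UG_PER_MG,
    DeterministicResult,
    ExposureFactors,
    compute_edi,
    compute_hq,
)

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_ITERATIONS",
    "HISTOGRAM_BINS",
    "ProbabilisticScenario",
    "SummaryStats",
    "Histogram",
    "SimulationResult",
    "ConvergenceReport",
    "ComparisonRecord",
    "run_simulation",
    "summarize",
    "make_histogram",
    "analytic_mean_hq",
    "convergence_check",
    "compare_deterministic_probabilistic",
]

#: sampling order is fixed so that a given seed always maps to the same draws
PARAM_NAMES = ("Ci", "IR", "EF", "ED", "BW", "AT", "RfD")

DEFAULT_ITERATIONS = 100_000
HISTOGRAM_BINS = 50


@dataclass(frozen=True)
class ProbabilisticScenario:
    """Distribution specs for the seven model inputs of one cell."""

    group: str
    source: str
    specs: dict[str, DistributionSpec]

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_NAMES if p not in self.specs]
        extra = [p for p in self.specs if p not in PARAM_NAMES]
        if missing:
            raise ConfigurationError(f"missing distribution specs for {missing}")
        if extra:
            raise ConfigurationError(f"unknown parameters {extra}")

    def stochastic_params(self) -> list[str]:
        """Names of the non-fixed inputs, in sampling order."""
        return [p for p in PARAM_NAMES if self.specs[p].kind != "fixed"]


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    p5: float
    p95: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "p5": self.p5,
            "p95": self.p95,
        }


@dataclass(frozen=True)
class Histogram:
    """Equal-width histogram; counts sum to the number of draws."""

    edges: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {"edges": self.edges.tolist(), "counts": self.counts.tolist()}


@dataclass(frozen=True)
class SimulationResult:
    group: str
    source: str
    hq_draws: np.ndarray
    input_draws: dict[str, np.ndarray]
    summary: SummaryStats
    histogram: Histogram
    iterations: int
    seed: int
    scenario: ProbabilisticScenario


@dataclass(frozen=True)
class ConvergenceReport:
    """Agreement between two independently seeded replicate runs."""

    run_a_summary: SummaryStats
    run_b_summary: SummaryStats
    relative_differences: dict[str, float]
    converged: bool
    tolerance: float

    def to_dict(self) -> dict:
        return {
            "run_a": self.run_a_summary.to_dict(),
            "run_b": self.run_b_summary.to_dict(),
            "relative_differences": self.relative_differences,
            "converged": self.converged,
            "tolerance": self.tolerance,
        }


@dataclass(frozen=True)
class ComparisonRecord:
    """Deterministic point HQ vs simulated HQ distribution for one cell."""

    group: str
    source: str
    deterministic_hq: float
    simulated_mean_hq: float
    ratio: float  # simulated mean / deterministic point
    point_percentile: float  # percentile rank of the point HQ among draws

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "source": self.source,
            "deterministic_hq": self.deterministic_hq,
            "simulated_mean_hq": self.simulated_mean_hq,
            "ratio": self.ratio,
            "point_percentile": self.point_percentile,
        }


def summarize(hq_draws: np.ndarray) -> SummaryStats:
    """Mean, SD (n−1 denominator), median and 5th/95th percentiles.

    Percentiles use linear interpolation between order statistics (the
    common spreadsheet convention; numpy's default).
    """
    draws = np.asarray(hq_draws, dtype=float)
    if draws.size == 0:
        raise DomainError("cannot summarize an empty draw vector")
    if np.ptp(draws) == 0.0:
        # constant vectors summarize exactly (no pairwise-summation rounding)
        c = float(draws[0])
        return SummaryStats(mean=c, sd=0.0, median=c, p5=c, p95=c)
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    p5, p50, p95 = np.percentile(draws, [5.0, 50.0, 95.0])
    return SummaryStats(
        mean=float(np.mean(draws)),
        sd=sd,
        median=float(p50),
        p5=float(p5),
        p95=float(p95),
    )


def make_histogram(hq_draws: np.ndarray, bins: int = HISTOGRAM_BINS) -> Histogram:
    """Equal-width histogram spanning [min, max] of the draws."""
    draws = np.asarray(hq_draws, dtype=float)
    if draws.size == 0:
        raise DomainError("cannot histogram an empty draw vector")
    counts, edges = np.histogram(draws, bins=bins)
    return Histogram(edges=edges, counts=counts)


def run_simulation(
    scenario: ProbabilisticScenario,
    iterations: int = DEFAULT_ITERATIONS,
    stream: RandomStream | None = None,
    consistent_averaging_time: bool = False,
) -> SimulationResult:
    """Run the Monte-Carlo simulation for one (group, source) cell.

    Draws every input per :data:`PARAM_NAMES` order from ``stream``,
    evaluates EDI and HQ per iteration with the deterministic arithmetic,
    and returns the draws, summary statistics and a histogram.

    By default the averaging time AT is sampled from its own spec (fixed
    in the packaged scenario) even while ED varies, reproducing the
    published method.  With ``consistent_averaging_time=True`` AT is
    instead tied to the sampled exposure duration (AT = ED x 365 d), the
    conventional non-carcinogenic linkage; this is off by default.
    """
    if iterations < 1:
        raise DomainError("iterations must be >= 1")
    if stream is None:
        from .distributions import DEFAULT_SEED

        stream = RandomStream(DEFAULT_SEED)
    draws = {name: sample(scenario.specs[name], iterations, stream) for name in PARAM_NAMES}
    if consistent_averaging_time:
        draws["AT"] = draws["ED"] * 365.0
    factors = ExposureFactors(
        ir=draws["IR"], ef=draws["EF"], ed=draws["ED"], bw=draws["BW"], at=draws["AT"]
    )
    edi = compute_edi(draws["Ci"], factors)
    hq = compute_hq(edi, draws["RfD"])
    hq = np.asarray(hq, dtype=float)
    if not np.all(np.isfinite(hq)):
        i = int(np.flatnonzero(~np.isfinite(hq))[0])
        raise DomainError(f"non-finite HQ at iteration {i}")
    return SimulationResult(
        group=scenario.group,
        source=scenario.source,
        hq_draws=hq,
        input_draws=draws,
        summary=summarize(hq),
        histogram=make_histogram(hq),
        iterations=iterations,
        seed=stream.seed,
        scenario=scenario,
    )


def _spec_mean(spec: DistributionSpec) -> float:
    if spec.kind == "fixed":
        return float(spec.value)
    if spec.kind == "uniform":
        return (spec.low + spec.high) / 2.0
    # normal (truncation effect neglected) and lognormal: arithmetic mean
    return float(spec.mean)


def analytic_mean_hq(scenario: ProbabilisticScenario) -> float:
    """Closed-form expected HQ under input independence.

    E[HQ] = E[C]/1000 * E[IR] * E[EF] * E[ED] * E[1/BW] / (E[AT] * RfD),
    where E[1/BW] = exp(−mu + sigma²/2) for a lognormal body weight and
    1/BW otherwise.  Zero-truncation of normal concentrations is ignored
    (negligible when the mean sits several SD above zero).
    """
    s = scenario.specs
    bw = s["BW"]
    if bw.kind == "lognormal":
        mu, sigma = lognormal_underlying_params(bw.mean, bw.sd)
        e_inv_bw = math.exp(-mu + sigma**2 / 2.0)
    elif bw.kind == "fixed":
        e_inv_bw = 1.0 / bw.value
    else:
        raise ConfigurationError(
            "analytic mean requires fixed or lognormal body weight"
        )
    rfd = s["RfD"]
    at = s["AT"]
    if rfd.kind != "fixed" or at.kind != "fixed":
        raise ConfigurationError("analytic mean requires fixed RfD and AT")
    return (
        _spec_mean(s["Ci"]) / UG_PER_MG
        * _spec_mean(s["IR"])
        * _spec_mean(s["EF"])
        * _spec_mean(s["ED"])
        * e_inv_bw
        / (at.value * rfd.value)
    )


def _relative_difference(a: float, b: float) -> float:
    denom = 0.5 * (abs(a) + abs(b))
    if denom == 0.0:
        return 0.0
    return abs(a - b) / denom


def convergence_check(
    scenario: ProbabilisticScenario,
    iterations: int = DEFAULT_ITERATIONS,
    seed_a: int = 1,
    seed_b: int = 2,
    tolerance: float = 0.01,
) -> ConvergenceReport:
    """Compare two independently seeded runs of the same scenario.

    Tracked statistics are mean, median and the 95th percentile; the run
    is converged when every relative difference (|a−b| over the pair
    mean) is within ``tolerance``.
    """
    if seed_a == seed_b:
        raise DomainError("seed_a and seed_b must differ")
    res_a = run_simulation(scenario, iterations, RandomStream(seed_a))
    res_b = run_simulation(scenario, iterations, RandomStream(seed_b))
    tracked = ("mean", "median", "p95")
    rel = {
        stat: _relative_difference(
            getattr(res_a.summary, stat), getattr(res_b.summary, stat)
        )
        for stat in tracked
    }
    return ConvergenceReport(
        run_a_summary=res_a.summary,
        run_b_summary=res_b.summary,
        relative_differences=rel,
        converged=all(v <= tolerance for v in rel.values()),
        tolerance=tolerance,
    )


def compare_deterministic_probabilistic(
    det: DeterministicResult, sim: SimulationResult
) -> ComparisonRecord:
    """Point HQ vs the simulated HQ distribution for one cell."""
    if (det.group, det.source) != (sim.group, sim.source):
        raise ConfigurationError(
            f"cell mismatch: deterministic {(det.group, det.source)} vs "
            f"simulation {(sim.group, sim.source)}"
        )
    mean_hq = sim.summary.mean
    pct = float(np.mean(sim.hq_draws <= det.hq) * 100.0)
    ratio = mean_hq / det.hq if det.hq > 0 else math.inf
    return ComparisonRecord(
        group=det.group,
        source=det.source,
        deterministic_hq=det.hq,
        simulated_mean_hq=mean_hq,
        ratio=ratio,
        point_percentile=pct,
    )
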