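"""Scenario configuration I/O, the packaged case study, and report writers.

A scenario is a single YAML document with a versioned schema: contaminant
and reference dose, per-source concentration summaries (plus water-quality
metadata that is carried into reports but never computed on), per-group
deterministic exposure factors, per-group distribution specs for the
probabilistic assessment, and simulation settings.  Unknown keys are
errors, not warnings: risk assessments must be audit-stable.

Per-cell seeding policy: each (group, source) cell simulates with seed
``(base_seed + crc32("group|source")) mod 2**31``, so cells are mutually
independent and adding a cell never perturbs another cell's draws.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .distributions import DEFAULT_SEED, DistributionSpec, RandomStream
from .errors import ScenarioError
from .risk_model import (
    ContaminantSpec,
    DeterministicResult,
    ExposureFactors,
    ExposureScenario,
    deterministic_assessment,
)
from .sensitivity import SensitivityResult, sensitivity_analysis
from .simulation import (
    ComparisonRecord,
    ConvergenceReport,
    ProbabilisticScenario,
    SimulationResult,
    compare_deterministic_probabilistic,
    convergence_check,
    run_simulation,
)

__all__ = [
    "ScenarioConfig",
    "AssessmentReport",
    "load_scenario",
    "save_scenario",
    "builtin_glyphosate_scenario",
    "cell_seed",
    "run_full_assessment",
    "write_report",
]

_PARAM_KEYS = {"IR", "EF", "ED", "BW", "AT", "RfD"}

#: fixed offsets deriving the two replicate seeds of the convergence check
#: from a cell's seed (arbitrary large constants, part of the seed policy)
CONVERGENCE_OFFSET_A = 1_013_904_223
CONVERGENCE_OFFSET_B = 1_866_795_127


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DistSpecModel(_StrictModel):
    kind: Literal["fixed", "normal", "lognormal", "uniform"]
    mean: Optional[float] = None
    sd: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    value: Optional[float] = None
    truncate_at_zero: Optional[bool] = None

    @model_validator(mode="after")
    def _check(self) -> "DistSpecModel":
        self.to_spec()  # raises ConfigurationError -> ValueError on bad specs
        return self

    def to_spec(self) -> DistributionSpec:
        kwargs: dict[str, Any] = {"kind": self.kind}
        for name in ("mean", "sd", "low", "high", "value"):
            if getattr(self, name) is not None:
                kwargs[name] = getattr(self, name)
        if self.kind == "normal" and self.truncate_at_zero is not None:
            kwargs["truncate_at_zero"] = self.truncate_at_zero
        return DistributionSpec(**kwargs)

    @classmethod
    def from_spec(cls, spec: DistributionSpec) -> "DistSpecModel":
        return cls(**spec.to_dict())


class ConcentrationModel(_StrictModel):
    mean: float = Field(ge=0)
    sd: float = Field(ge=0)


class WaterSourceModel(_StrictModel):
    concentration: ConcentrationModel
    water_quality: dict[str, float] = Field(default_factory=dict)


class FactorsModel(_StrictModel):
    IR: float = Field(gt=0)
    EF: float = Field(gt=0, le=366)
    ED: float = Field(gt=0)
    BW: float = Field(gt=0)
    AT: float = Field(gt=0)

    def to_factors(self) -> ExposureFactors:
        return ExposureFactors(ir=self.IR, ef=self.EF, ed=self.ED, bw=self.BW, at=self.AT)


class ContaminantModel(_StrictModel):
    name: str
    reference_dose: float = Field(gt=0)


class SimulationSettings(_StrictModel):
    iterations: int = Field(default=100_000, ge=1)
    seed: int = DEFAULT_SEED
    convergence_tolerance: float = Field(default=0.01, gt=0)


class ScenarioConfig(_StrictModel):
    """Validated scenario: everything needed for a full assessment."""

    schema_version: Literal[1]
    metadata: dict[str, str] = Field(default_factory=dict)
    contaminant: ContaminantModel
    water_sources: dict[str, WaterSourceModel]
    deterministic_factors: dict[str, FactorsModel]
    probabilistic_specs: dict[str, dict[str, DistSpecModel]]
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)

    @model_validator(mode="after")
    def _check_structure(self) -> "ScenarioConfig":
        if not self.water_sources:
            raise ValueError("at least one water source is required")
        for group, specs in self.probabilistic_specs.items():
            keys = set(specs)
            if keys != _PARAM_KEYS:
                missing = sorted(_PARAM_KEYS - keys)
                extra = sorted(keys - _PARAM_KEYS)
                raise ValueError(
                    f"probabilistic_specs[{group}]: missing {missing}, unknown {extra}"
                )
        return self

    # -- derived views --------------------------------------------------
    def contaminant_for(self, source: str) -> ContaminantSpec:
        conc = self.water_sources[source].concentration
        return ContaminantSpec(
            name=self.contaminant.name,
            concentration_mean=conc.mean,
            concentration_sd=conc.sd,
            reference_dose=self.contaminant.reference_dose,
        )

    def exposure_scenarios(self) -> list[ExposureScenario]:
        """Deterministic (group x source) cells in config order."""
        return [
            ExposureScenario(
                group=group,
                source=source,
                contaminant=self.contaminant_for(source),
                factors=factors.to_factors(),
            )
            for group, factors in self.deterministic_factors.items()
            for source in self.water_sources
        ]

    def probabilistic_scenario(self, group: str, source: str) -> ProbabilisticScenario:
        """Build the seven-parameter stochastic scenario for one cell.

        The concentration input is a zero-truncated normal built from the
        source's mean/sd; the remaining six specs come from the group's
        probabilistic entry.
        """
        if group not in self.probabilistic_specs:
            raise ScenarioError(f"no probabilistic specs for group {group!r}")
        if source not in self.water_sources:
            raise ScenarioError(f"unknown water source {source!r}")
        conc = self.water_sources[source].concentration
        specs = {"Ci": DistributionSpec.normal(conc.mean, conc.sd)}
        for name, model in self.probabilistic_specs[group].items():
            specs[name] = model.to_spec()
        return ProbabilisticScenario(group=group, source=source, specs=specs)

    def probabilistic_cells(self) -> list[tuple[str, str]]:
        return [
            (group, source)
            for group in self.probabilistic_specs
            for source in self.water_sources
        ]

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML file.

    Raises :class:`~hqrisk.errors.ScenarioError` with the parse location
    for malformed YAML, or with the offending field path for schema
    violations.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.MarkedYAMLError as exc:  # parse error with line/column
        mark = exc.problem_mark
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ScenarioError(f"{path}: YAML parse error{loc}: {exc.problem}") from exc
    except OSError as exc:
        raise ScenarioError(f"cannot read scenario file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ScenarioError(f"{path}: scenario must be a mapping")
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ScenarioError(
            f"{path}: invalid scenario config:\n" + "\n".join(lines)
        ) from exc


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario back to YAML (round-trips through load_scenario)."""
    payload = config.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def builtin_glyphosate_scenario() -> ScenarioConfig:
    """The packaged Isfahan glyphosate case study (2 sources x 3 groups)."""
    ref = resources.files("hqrisk").joinpath("data/glyphosate_isfahan.yaml")
    raw = yaml.safe_load(ref.read_text())
    return ScenarioConfig.model_validate(raw)


def cell_seed(base_seed: int, group: str, source: str) -> int:
    """Deterministic per-cell seed: base + stable hash of the cell key."""
    h = zlib.crc32(f"{group}|{source}".encode())
    return (int(base_seed) + h) % 2**31


@dataclass(frozen=True)
class AssessmentReport:
    """Everything a full assessment produced, plus provenance.

    Every number here is recomputable from the config and the base seed.
    """

    config: ScenarioConfig
    deterministic: dict[tuple[str, str], DeterministicResult]
    simulations: dict[tuple[str, str], SimulationResult]
    convergence: dict[tuple[str, str], ConvergenceReport]
    sensitivity: dict[tuple[str, str], SensitivityResult]
    comparisons: dict[tuple[str, str], ComparisonRecord]
    base_seed: int
    iterations: int

    def provenance(self) -> dict:
        return {
            "toolkit_version": __version__,
            "base_seed": self.base_seed,
            "iterations": self.iterations,
            "rng_algorithm": RandomStream(0).algorithm,
            "config_hash": self.config.config_hash(),
            "cell_seeds": {
                f"{g}|{s}": cell_seed(self.base_seed, g, s)
                for (g, s) in self.simulations
            },
        }

    def to_dict(self) -> dict:
        """JSON-serializable master document (draw vectors excluded)."""
        def key(cell: tuple[str, str]) -> str:
            return f"{cell[0]}|{cell[1]}"

        return {
            "provenance": self.provenance(),
            "metadata": dict(self.config.metadata),
            "water_quality": {
                s: dict(m.water_quality) for s, m in self.config.water_sources.items()
            },
            "deterministic": {
                key(c): {"edi": r.edi, "hq": r.hq} for c, r in self.deterministic.items()
            },
            "simulation_summaries": {
                key(c): {
                    **r.summary.to_dict(),
                    "iterations": r.iterations,
                    "seed": r.seed,
                    "histogram": r.histogram.to_dict(),
                }
                for c, r in self.simulations.items()
            },
            "convergence": {key(c): r.to_dict() for c, r in self.convergence.items()},
            "sensitivity": {key(c): r.to_dict() for c, r in self.sensitivity.items()},
            "comparisons": {key(c): r.to_dict() for c, r in self.comparisons.items()},
        }


def run_full_assessment(
    config: ScenarioConfig,
    iterations: int | None = None,
    base_seed: int | None = None,
    check_convergence: bool = True,
) -> AssessmentReport:
    """Deterministic + probabilistic assessment over every cell.

    Runs the point assessment, then per (group, source) cell a
    Monte-Carlo simulation, an optional two-replicate convergence check,
    a sensitivity analysis and a deterministic-vs-probabilistic
    comparison.
    """
    iterations = config.simulation.iterations if iterations is None else iterations
    base_seed = config.simulation.seed if base_seed is None else base_seed
    det = deterministic_assessment(config.exposure_scenarios())
    sims: dict[tuple[str, str], SimulationResult] = {}
    conv: dict[tuple[str, str], ConvergenceReport] = {}
    sens: dict[tuple[str, str], SensitivityResult] = {}
    comps: dict[tuple[str, str], ComparisonRecord] = {}
    for group, source in config.probabilistic_cells():
        scenario = config.probabilistic_scenario(group, source)
        seed = cell_seed(base_seed, group, source)
        sim = run_simulation(scenario, iterations, RandomStream(seed))
        sims[(group, source)] = sim
        if check_convergence:
            conv[(group, source)] = convergence_check(
                scenario,
                iterations,
                seed_a=(seed + CONVERGENCE_OFFSET_A) % 2**31,
                seed_b=(seed + CONVERGENCE_OFFSET_B) % 2**31,
                tolerance=config.simulation.convergence_tolerance,
            )
        sens[(group, source)] = sensitivity_analysis(sim)
        if (group, source) in det:
            comps[(group, source)] = compare_deterministic_probabilistic(
                det[(group, source)], sim
            )
    return AssessmentReport(
        config=config,
        deterministic=det,
        simulations=sims,
        convergence=conv,
        sensitivity=sens,
        comparisons=comps,
        base_seed=base_seed,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# report writers


def _deterministic_frame(report: AssessmentReport) -> pd.DataFrame:
    rows = [
        {"group": g, "source": s, "EDI": r.edi, "HQ": r.hq}
        for (g, s), r in report.deterministic.items()
    ]
    return pd.DataFrame(rows, columns=["group", "source", "EDI", "HQ"])


def _summary_frame(report: AssessmentReport) -> pd.DataFrame:
    rows = [
        {
            "group": g,
            "source": s,
            **r.summary.to_dict(),
            "iterations": r.iterations,
            "seed": r.seed,
        }
        for (g, s), r in report.simulations.items()
    ]
    return pd.DataFrame(rows)


def _sensitivity_frame(report: AssessmentReport) -> pd.DataFrame:
    rows = [
        {"group": g, "source": s, "parameter": rec.name, "rho": rec.rho,
         "contribution_pct": rec.contribution_pct}
        for (g, s), res in report.sensitivity.items()
        for rec in res.records
    ]
    return pd.DataFrame(rows)


def write_report(
    report: AssessmentReport,
    out_dir: str | Path,
    formats: set[str] = frozenset({"csv", "json", "png"}),
) -> list[Path]:
    """Write the report to ``out_dir`` in the requested formats.

    json: one master document.  csv: deterministic table, simulation
    summaries, sensitivity table, per-cell histograms.  png: the
    deterministic-vs-probabilistic bar chart, per-cell HQ histograms and
    sensitivity tornado charts.  Returns the written paths.
    """
    unknown = set(formats) - {"csv", "json", "png"}
    if unknown:
        raise ScenarioError(f"unknown report formats: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)

    if "csv" in formats:
        for name, frame in (
            ("deterministic.csv", _deterministic_frame(report)),
            ("simulation_summary.csv", _summary_frame(report)),
            ("sensitivity.csv", _sensitivity_frame(report)),
        ):
            path = out / name
            frame.to_csv(path, index=False)
            written.append(path)
        for (g, s), sim in report.simulations.items():
            hist = sim.histogram
            frame = pd.DataFrame(
                {
                    "bin_left": hist.edges[:-1],
                    "bin_right": hist.edges[1:],
                    "count": hist.counts,
                }
            )
            path = out / f"histogram_{g}_{s}.csv"
            frame.to_csv(path, index=False)
            written.append(path)

    if "png" in formats:
        written.extend(_write_charts(report, out))
    return written


def _write_charts(report: AssessmentReport, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []

    # deterministic vs probabilistic mean HQ, grouped bars per cell
    cells = list(report.comparisons)
    if cells:
        fig, ax = plt.subplots(figsize=(8, 4.5))
        x = range(len(cells))
        det_vals = [report.comparisons[c].deterministic_hq for c in cells]
        sim_vals = [report.comparisons[c].simulated_mean_hq for c in cells]
        width = 0.38
        ax.bar([i - width / 2 for i in x], det_vals, width, label="deterministic")
        ax.bar([i + width / 2 for i in x], sim_vals, width, label="probabilistic mean")
        ax.set_xticks(list(x))
        ax.set_xticklabels([f"{g}\n{s}" for g, s in cells], fontsize=8)
        ax.set_ylabel("HQ")
        ax.set_title("Hazard quotient: deterministic vs probabilistic")
        ax.legend()
        fig.tight_layout()
        path = out / "hq_comparison.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    for (g, s), sim in report.simulations.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        centers = 0.5 * (sim.histogram.edges[:-1] + sim.histogram.edges[1:])
        widths = sim.histogram.edges[1:] - sim.histogram.edges[:-1]
        ax.bar(centers, sim.histogram.counts, width=widths, edgecolor="none")
        ax.set_xlabel("HQ")
        ax.set_ylabel("frequency")
        ax.set_title(f"HQ distribution: {g}, {s} water")
        fig.tight_layout()
        path = out / f"histogram_{g}_{s}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    for (g, s), res in report.sensitivity.items():
        fig, ax = plt.subplots(figsize=(6, 3.5))
        names = [r.name for r in reversed(res.records)]
        vals = [r.contribution_pct for r in reversed(res.records)]
        colors = ["#1f77b4" if v >= 0 else "#d62728" for v in vals]
        ax.barh(names, vals, color=colors)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("contribution to variance (%)")
        ax.set_title(f"Sensitivity: {g}, {s} water")
        fig.tight_layout()
        path = out / f"sensitivity_{g}_{s}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
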