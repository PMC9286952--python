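"""Benchmark run matrices and table-style reporting.

Runs every registered optimizer on every requested benchmark function for a
fixed number of independent seeded repetitions and aggregates Best / Mean /
Worst / Std per cell, in the layout optimizer-comparison tables use
(scientific notation, three significant digits). Per-run seeds derive from a
single master seed through a stable hash of (master seed, algorithm,
function, run), so the whole matrix is regenerable from one integer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .benchfuncs import get_function
from .registry import get_optimizer

__all__ = [
    "RunRecord",
    "RunReport",
    "derive_seed",
    "run_benchmark_matrix",
    "format_table",
    "sci3",
]

logger = logging.getLogger("iaoadbn")

STATISTICS = ("Best", "Mean", "Worst", "Std")


def derive_seed(master_seed: int, algorithm: str, function: str, run: int) -> int:
    """Stable per-run seed below 2**31 from the matrix coordinates."""
    key = f"{master_seed}:{algorithm}:{function}:{run}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31 - 1)


@dataclass
class RunRecord:
    function: str
    algorithm: str
    run: int
    seed: int
    best_fitness: float
    wall_time: float
    trace: np.ndarray | None = field(default=None, repr=False)
    error: str | None = None


@dataclass
class RunReport:
    """All per-run results plus the configuration that regenerates them."""

    records: list[RunRecord]
    config: dict

    def aggregate(self) -> dict[tuple[str, str], dict[str, float]]:
        """Best/Mean/Worst/Std per (function, algorithm) cell."""
        cells: dict[tuple[str, str], dict[str, float]] = {}
        for fn in self.config["functions"]:
            for algo in self.config["algorithms"]:
                vals = np.array([r.best_fitness for r in self.records
                                 if r.function == fn and r.algorithm == algo and r.error is None])
                if len(vals):
                    cells[(fn, algo)] = {
                        "Best": float(vals.min()),
                        "Mean": float(vals.mean()),
                        "Worst": float(vals.max()),
                        "Std": float(vals.std()),
                    }
        return cells

    def to_dict(self, include_traces: bool = False) -> dict:
        out = {"config": self.config, "results": []}
        for fn in self.config["functions"]:
            for algo in self.config["algorithms"]:
                runs = [
                    {"run": r.run, "seed": r.seed, "best": r.best_fitness,
                     **({"trace": r.trace.tolist()} if include_traces and r.trace is not None else {}),
                     **({"error": r.error} if r.error else {})}
                    for r in self.records if r.function == fn and r.algorithm == algo
                ]
                out["results"].append({"function": fn, "algo": algo, "runs": runs})
        return out

    def to_json(self, include_traces: bool = False) -> str:
        return json.dumps(self.to_dict(include_traces), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "RunReport":
        records = []
        for block in data["results"]:
            for r in block["runs"]:
                records.append(RunRecord(
                    block["function"], block["algo"], r["run"], r["seed"],
                    r.get("best", float("nan")), 0.0,
                    np.asarray(r["trace"]) if "trace" in r else None,
                    r.get("error"),
                ))
        return cls(records, data["config"])


def run_benchmark_matrix(
    algorithms: list[str],
    functions: list[str],
    runs: int = 30,
    master_seed: int = 0,
    population_size: int = 30,
    max_iterations: int = 500,
    keep_traces: bool = False,
) -> RunReport:
    """Execute the full seeded run matrix; a failed run is recorded with its
    seed and the matrix continues."""
    records: list[RunRecord] = []
    for fname in functions:
        fn = get_function(fname)
        for algo in algorithms:
            entry = get_optimizer(algo)
            for run in range(runs):
                seed = derive_seed(master_seed, entry.name, fn.name, run)
                t0 = time.perf_counter()
                try:
                    config = entry.config_factory(
                        bounds=fn.bounds,
                        population_size=population_size,
                        max_iterations=max_iterations,
                        seed=seed,
                    )
                    result = entry.optimize(fn, config)
                    rec = RunRecord(fn.name, entry.name, run, seed, result.best_fitness,
                                    time.perf_counter() - t0,
                                    result.trace if keep_traces else None)
                except Exception as exc:  # noqa: BLE001 - recorded, matrix continues
                    rec = RunRecord(fn.name, entry.name, run, seed, float("nan"),
                                    time.perf_counter() - t0, None, repr(exc))
                logger.info("function=%s algo=%s seed=%d best=%.6g wall=%.3fs",
                            rec.function, rec.algorithm, rec.seed, rec.best_fitness,
                            rec.wall_time)
                records.append(rec)
    config = {
        "algorithms": [get_optimizer(a).name for a in algorithms],
        "functions": [get_function(f).name for f in functions],
        "runs": runs,
        "master_seed": master_seed,
        "population_size": population_size,
        "max_iterations": max_iterations,
    }
    return RunReport(records, config)


def sci3(x: float) -> str:
    """Three-significant-digit scientific notation, e.g. ``8.88E-16``."""
    return f"{x:.2E}"


def format_table(report: RunReport, style: str = "tab5") -> str:
    """Render the aggregate matrix as text.

    ``tab5``: statistics-by-algorithm rows, one column per function, in
    X.XXE+YY notation. ``csv``: long-form rows. ``json``: the full report.
    """
    cells = report.aggregate()
    functions = report.config["functions"]
    algorithms = report.config["algorithms"]
    if style == "json":
        return report.to_json()
    if style == "csv":
        lines = ["statistic,algorithm," + ",".join(functions)]
        for stat in STATISTICS:
            for algo in algorithms:
                row = [repr(cells[(f, algo)][stat]) if (f, algo) in cells else ""
                       for f in functions]
                lines.append(f"{stat},{algo}," + ",".join(row))
        return "\n".join(lines) + "\n"
    if style == "tab5":
        width = 12
        header = f"{'Statistic':<10}{'Algorithm':<10}" + "".join(f"{f:>{width}}" for f in functions)
        lines = [header, "-" * len(header)]
        for stat in STATISTICS:
            for algo in algorithms:
                row = [sci3(cells[(f, algo)][stat]) if (f, algo) in cells else "—"
                       for f in functions]
                lines.append(f"{stat:<10}{algo:<10}" + "".join(f"{v:>{width}}" for v in row))
        return "\n".join(lines) + "\n"
    raise ValueError("style must be one of 'tab5', 'csv', 'json'")
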