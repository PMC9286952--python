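"""Optimizer plugin registry.

Third-party population optimizers can be benchmarked side-by-side with the
built-in ones by registering a ``(config_factory, optimize)`` pair. The
contract: ``config_factory(bounds=..., population_size=..., max_iterations=...,
seed=...)`` returns a config object, and ``optimize(objective, config)``
returns an :class:`~iaoadbn.aoa.OptimizerResult`.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

from . import aoa, iaoa

__all__ = ["OptimizerEntry", "register_optimizer", "get_optimizer", "list_optimizers"]


class OptimizerEntry(NamedTuple):
    name: str
    config_factory: Callable
    optimize: Callable


_OPTIMIZERS: dict[str, OptimizerEntry] = {}


def register_optimizer(name: str, config_factory: Callable, optimize: Callable) -> None:
    """Register an optimizer under ``name`` (case-insensitive)."""
    _OPTIMIZERS[name.lower()] = OptimizerEntry(name.lower(), config_factory, optimize)


def get_optimizer(name: str) -> OptimizerEntry:
    entry = _OPTIMIZERS.get(name.lower())
    if entry is None:
        raise KeyError(f"unknown optimizer {name!r}; registered: {', '.join(sorted(_OPTIMIZERS))}")
    return entry


def list_optimizers() -> list[str]:
    return sorted(_OPTIMIZERS)


register_optimizer("aoa", aoa.AoaConfig, aoa.optimize)
register_optimizer("iaoa", iaoa.IaoaConfig, iaoa.optimize)
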