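"""Local dependency-graph runner with persisted state and smart restart.

Each step carries a fingerprint — a stable hash of its resolved
parameters, the content digests of its declared input files, and the
fingerprints of its dependencies.  On resume, a step is skipped iff its
persisted state is ``done`` and its recorded fingerprint matches the
current one; because fingerprints chain through dependencies, editing one
step's parameters invalidates exactly that step and its downstream cone.
Failures halt dependents, but independent branches keep running.

Execution is local and in-process; the contract preserved from
scheduler-based pipeline frameworks is dependency ordering plus smart
restart, not job submission.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import networkx as nx


class ConfigError(ValueError):
    pass


class StateError(RuntimeError):
    pass


@dataclass
class Step:
    """One unit of work: a callable with params, declared inputs/outputs
    and dependencies on other steps (by name)."""

    name: str
    func: Callable[[dict], Any]
    params: dict = field(default_factory=dict)
    dependencies: list[str] = field(default_factory=list)
    inputs: list[Path] = field(default_factory=list)
    outputs: list[Path] = field(default_factory=list)


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stable_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=str)


@dataclass
class StepGraph:
    """Acyclic step collection with a deterministic topological order."""

    steps: dict[str, Step] = field(default_factory=dict)

    def add(self, step: Step) -> None:
        if step.name in self.steps:
            raise ConfigError(f"duplicate step name {step.name!r}")
        self.steps[step.name] = step

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.steps)
        for step in self.steps.values():
            for dep in step.dependencies:
                if dep not in self.steps:
                    raise ConfigError(f"step {step.name!r} depends on unknown {dep!r}")
                g.add_edge(dep, step.name)
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigError("step graph has a cycle")
        return g

    def order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    def fingerprint(self, name: str, dep_fingerprints: dict[str, str]) -> str:
        step = self.steps[name]
        h = hashlib.sha256()
        h.update(_stable_json(step.params).encode())
        for inp in sorted(map(str, step.inputs)):
            p = Path(inp)
            h.update(inp.encode())
            if p.exists():
                h.update(_digest_file(p).encode())
        for dep in sorted(step.dependencies):
            h.update(dep_fingerprints[dep].encode())
        return h.hexdigest()


@dataclass
class RunReport:
    executed: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    failed: list[str] = field(default_factory=list)
    blocked: list[str] = field(default_factory=list)
    results: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "executed": self.executed,
            "skipped": self.skipped,
            "failed": self.failed,
            "blocked": self.blocked,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def _state_path(state_dir: Path, name: str) -> Path:
    return state_dir / f"{name}.json"


def _load_state(state_dir: Path, name: str) -> Optional[dict]:
    p = _state_path(state_dir, name)
    if not p.exists():
        return None
    try:
        with open(p) as fh:
            rec = json.load(fh)
        if not isinstance(rec, dict) or "state" not in rec:
            raise ValueError("malformed record")
        return rec
    except (ValueError, OSError) as exc:
        raise StateError(
            f"state record for step {name!r} is corrupt ({exc}); "
            "refusing to resume — remove the state directory and run fresh"
        ) from exc


def _save_state(state_dir: Path, name: str, rec: dict) -> None:
    tmp = _state_path(state_dir, name).with_suffix(".tmp")
    with open(tmp, "w") as fh:
        json.dump(rec, fh)
    tmp.replace(_state_path(state_dir, name))


def execute(
    graph: StepGraph,
    state_dir,
    resume: bool = False,
    fail_on: Optional[set[str]] = None,
) -> RunReport:
    """Run the graph in dependency order with persisted per-step state.

    ``resume=False`` clears previous state.  ``fail_on`` forces named
    steps to fail (for testing restart semantics).  Returns the run
    report; step return values are collected in ``report.results``.
    """
    state_dir = Path(state_dir)
    state_dir.mkdir(parents=True, exist_ok=True)
    if not resume:
        for p in state_dir.glob("*.json"):
            p.unlink()

    report = RunReport()
    fingerprints: dict[str, str] = {}
    status: dict[str, str] = {}
    for name in graph.order():
        step = graph.steps[name]
        fp = graph.fingerprint(name, fingerprints)
        fingerprints[name] = fp
        if any(status.get(dep) in ("failed", "blocked") for dep in step.dependencies):
            status[name] = "blocked"
            report.blocked.append(name)
            continue
        prior = _load_state(state_dir, name) if resume else None
        if prior and prior.get("state") == "done" and prior.get("fingerprint") == fp:
            status[name] = "done"
            report.skipped.append(name)
            continue
        rec = {"name": name, "fingerprint": fp, "state": "running",
               "started": time.time()}
        _save_state(state_dir, name, rec)
        try:
            if fail_on and name in fail_on:
                raise RuntimeError(f"step {name!r} forced to fail")
            result = step.func(step.params)
        except Exception as exc:
            rec.update(state="failed", error=str(exc), finished=time.time())
            _save_state(state_dir, name, rec)
            status[name] = "failed"
            report.failed.append(name)
            continue
        rec.update(state="done", finished=time.time())
        _save_state(state_dir, name, rec)
        status[name] = "done"
        report.executed.append(name)
        report.results[name] = result
    return report
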