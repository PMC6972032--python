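"""Declarative run configuration (YAML).

A run-config file can override the transition structure, covariate
masks, the analysis plan and generator settings, e.g.::

    structure:
      transitions: [A->B, A->C, B->D, C->A, C->D, D->B, A->E, B->E, C->E, D->E]
    plan:
      models: [individual, triple]
      strata: [overall]
      age_threshold: 65
      ci_level: 0.95
    generator:
      n_subjects: 1000
      dropout: 0.22

Omitted sections fall back to the packaged five-state defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .model import InputError, TransitionStructure
from .pipeline import AnalysisPlan
from .simulate import CohortConfig


def _parse_transition(s: str) -> tuple[str, str]:
    if "->" not in s:
        raise InputError(f"transition {s!r} must use the form 'A->B'")
    r, _, t = s.partition("->")
    return r.strip(), t.strip()


def structure_from_dict(d: dict | None) -> TransitionStructure:
    if not d or "transitions" not in d:
        return TransitionStructure()
    return TransitionStructure(tuple(_parse_transition(s) for s in d["transitions"]))


def plan_from_dict(d: dict | None) -> AnalysisPlan:
    if not d:
        return AnalysisPlan()
    known = {f.name for f in dataclasses.fields(AnalysisPlan)}
    unknown = set(d) - known
    if unknown:
        raise InputError(f"unknown plan keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return AnalysisPlan(**kwargs)


def generator_from_dict(d: dict | None) -> CohortConfig:
    if not d:
        return CohortConfig()
    known = {f.name for f in dataclasses.fields(CohortConfig)} - {"truth"}
    unknown = set(d) - known
    if unknown:
        raise InputError(f"unknown generator keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return CohortConfig(**kwargs)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        "structure": structure_from_dict(raw.get("structure")),
        "plan": plan_from_dict(raw.get("plan")),
        "generator": generator_from_dict(raw.get("generator")),
    }
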