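"""Configuration files, trajectory serialisation and scenario presets.

Configs are flat YAML or JSON mappings of model parameters, optionally with a
``classes`` list describing the initial population.  ``"inf"`` is accepted
for ``phi`` and ``beta_p``.  Unknown keys are rejected with an error naming
them.  Trajectory CSVs use a stable column order and fixed formatting so
identical runs diff clean.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import (
    AdultClass,
    ConfigurationError,
    INFINITE,
    MatingType,
    ModelParams,
    PopulationState,
    ReproductiveMode,
    two_type_state,
)
from .evolve import EventType, EvolutionRecord, EvolutionTrajectory

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "load_config",
    "load_classes_csv",
    "write_classes_csv",
    "write_trajectory",
    "read_trajectory",
    "provenance_block",
]

_CLASS_FIELDS = ("class_id", "mating_type", "mode", "m", "count")


@dataclass(frozen=True)
class ScenarioPreset:
    """A named parameterisation with its stock initial conditions."""

    name: str
    params: ModelParams
    initial_conditions: tuple[tuple[float, float], ...]
    expected_outcome: str


#: The two stock scenarios: zygote survival scale 1, fertilisation effort 100,
#: mutational step 0.02, and a parthenosporophyte survival scale either above
#: (disadvantage) or below (advantage) the zygotic one.
PRESETS: dict[str, ScenarioPreset] = {
    "partheno-disadvantage": ScenarioPreset(
        "partheno-disadvantage",
        ModelParams(beta_z=1.0, beta_p=1.3, phi=100.0, delta_m=0.02),
        ((2.0, 2.0), (1.0, 1.0), (1.5, 0.2)),
        "all starts evolve to strong anisogamy with minimal microgametes",
    ),
    "partheno-advantage": ScenarioPreset(
        "partheno-advantage",
        ModelParams(beta_z=1.0, beta_p=0.7, phi=100.0, delta_m=0.02),
        ((2.0, 2.0), (1.0, 1.0), (1.5, 0.2)),
        "outcome depends on the start: anisogamy, stable isogamy, or "
        "macrogamete extinction followed by progeny-size optimisation",
    ),
}


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def load_config(path: str | Path) -> tuple[ModelParams, PopulationState | None]:
    """Read a YAML/JSON config; returns params and, if ``classes`` or
    ``initial`` is given, the initial population state."""
    data = _load_mapping(path)
    classes_spec = data.pop("classes", None)
    initial = data.pop("initial", None)
    params = ModelParams.from_dict(data)
    state = None
    if classes_spec is not None:
        classes = []
        for i, spec in enumerate(classes_spec):
            unknown = sorted(set(spec) - set(_CLASS_FIELDS))
            if unknown:
                raise ConfigurationError(f"class entry {i}: unknown keys {unknown}")
            try:
                classes.append(
                    AdultClass(
                        str(spec["class_id"]),
                        MatingType(str(spec["mating_type"]).upper()),
                        ReproductiveMode(str(spec.get("mode", "SEXUAL")).upper()),
                        float(spec["m"]),
                        float(spec["count"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigurationError(f"class entry {i}: {exc}") from exc
        state = PopulationState(classes, params)
    elif initial is not None:
        try:
            mx, my = (float(v) for v in initial)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"initial must be [mx, my]: {initial!r}") from exc
        state = two_type_state(params, mx, my)
    return params, state


def load_classes_csv(path: str | Path, params: ModelParams) -> PopulationState:
    classes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CLASS_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            classes.append(
                AdultClass(
                    row["class_id"],
                    MatingType(row["mating_type"].upper()),
                    ReproductiveMode(row["mode"].upper()),
                    float(row["m"]),
                    float(row["count"]),
                )
            )
    return PopulationState(classes, params)


def write_classes_csv(state: PopulationState, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CLASS_FIELDS)
        for c in state.classes:
            writer.writerow(
                [c.class_id, c.mating_type.value, c.mode.value,
                 _fmt(c.m), _fmt(c.count)]
            )


def _fmt(value: float | None) -> str:
    # shortest round-trippable decimal: deterministic, diff-clean, and
    # read(write(t)) recovers the exact float
    if value is None:
        return ""
    return repr(float(value))


def write_trajectory(trajectory: EvolutionTrajectory, path: str | Path) -> None:
    """Write an evolution trajectory as CSV with stable columns
    (substitution_index, mx, my, R, event) and fixed precision, so that two
    runs with the same seed produce byte-identical files."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["substitution_index", "mx", "my", "R", "event"])
        for r in trajectory.records:
            writer.writerow(
                [r.substitution_index, _fmt(r.mx), _fmt(r.my), _fmt(r.R),
                 r.event.value]
            )


def read_trajectory(path: str | Path) -> list[EvolutionRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                EvolutionRecord(
                    int(row["substitution_index"]),
                    float(row["mx"]) if row["mx"] else None,
                    float(row["my"]) if row["my"] else None,
                    float(row["R"]),
                    EventType(row["event"]),
                )
            )
    return records


def provenance_block(params: ModelParams, seed: int | None = None, **extra) -> dict:
    """JSON-serialisable provenance: parameters, seed and package version."""
    from . import __version__

    block = {"params": params.to_dict(), "seed": seed, "version": __version__}
    block.update(extra)
    return block
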