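"""Motion models: a sports motion as a chain of sub-motions with shared boundary states.

A motion (e.g. a soccer kick) is modeled as an ordered sequence of
sub-motions (phases).  Each sub-motion is split into three states: a
*start* state, a multi-frame *performing* state, and an *end* state.
Transitions between sub-motions are assumed instantaneous, so boundary
states occupy exactly one sensor frame and the end state of sub-motion
``i`` is the same state as the start state of sub-motion ``i+1``.

A motion with ``N`` sub-motions therefore has ``2N + 1`` distinct states
(``N + 1`` single-frame boundary states interleaved with ``N`` performing
states).  The per-frame classifier additionally recognises a *none /
unknown* state (class index 0) covering everything outside the modeled
motion, for ``2N + 2`` classes in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SubMotion",
    "MotionModel",
    "ModelDefinitionError",
    "build_model",
    "load_model",
    "boundary_states",
    "state_pattern",
]

NONE_CLASS = 0


class ModelDefinitionError(ValueError):
    """Raised for structurally invalid motion-model definitions."""


@dataclass(frozen=True)
class SubMotion:
    """One phase of a motion: start boundary, performing interior, end boundary."""

    name: str
    start_label: str
    performing_label: str
    end_label: str

    def __post_init__(self) -> None:
        labels = (self.start_label, self.performing_label, self.end_label)
        if len(set(labels)) != 3:
            raise ModelDefinitionError(
                f"sub-motion {self.name!r}: the three state labels must be "
                f"distinct, got {labels}"
            )


@dataclass(frozen=True)
class MotionModel:
    """An ordered chain of sub-motions sharing single-frame boundary states.

    ``state_index`` maps every state label to its classifier class index:
    0 is reserved for the none/unknown state and the motion's own states
    are numbered 1, 2, ... in temporal order.
    """

    name: str
    sub_motions: tuple[SubMotion, ...]
    state_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sub_motions:
            raise ModelDefinitionError("a motion model needs at least one phase")
        for a, b in zip(self.sub_motions, self.sub_motions[1:]):
            if a.end_label != b.start_label:
                raise ModelDefinitionError(
                    f"boundary chain broken between phases {a.name!r} and "
                    f"{b.name!r}: {a.end_label!r} != {b.start_label!r}"
                )
        labels = self.state_labels()
        if len(set(labels)) != len(labels):
            raise ModelDefinitionError(f"duplicate state labels in {labels}")
        expected = {lab: i + 1 for i, lab in enumerate(labels)}
        if not self.state_index:
            object.__setattr__(self, "state_index", {"none": NONE_CLASS, **expected})
        else:
            got = {k: v for k, v in self.state_index.items() if k != "none"}
            if got != expected or self.state_index.get("none") != NONE_CLASS:
                raise ModelDefinitionError("state_index inconsistent with phase order")

    # -- derived structure -------------------------------------------------

    @property
    def n_phases(self) -> int:
        return len(self.sub_motions)

    @property
    def n_states(self) -> int:
        """Distinct motion states, excluding the none class (2N + 1)."""
        return 2 * self.n_phases + 1

    @property
    def n_classes(self) -> int:
        """Classifier classes, including the none class (2N + 2)."""
        return self.n_states + 1

    def state_labels(self) -> list[str]:
        """All state labels in temporal order, boundaries listed once."""
        out = [self.sub_motions[0].start_label]
        for sm in self.sub_motions:
            out.append(sm.performing_label)
            out.append(sm.end_label)
        return out

    def label_of(self, index: int) -> str:
        for lab, i in self.state_index.items():
            if i == index:
                return lab
        raise KeyError(index)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "phases": [
                {
                    "name": sm.name,
                    "start": sm.start_label,
                    "performing": sm.performing_label,
                    "end": sm.end_label,
                }
                for sm in self.sub_motions
            ],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)


def build_model(definition: dict) -> MotionModel:
    """Build a :class:`MotionModel` from a parsed config mapping.

    The mapping has a ``name`` and a ``phases`` list; each phase is a
    mapping with ``name``, ``start``, ``performing`` and ``end`` state
    labels.  Adjacent phases must chain (``end`` of one == ``start`` of
    the next).
    """
    if not isinstance(definition, dict) or "phases" not in definition:
        raise ModelDefinitionError("model definition must be a mapping with 'phases'")
    phases = definition["phases"]
    if not phases:
        raise ModelDefinitionError("empty phase list")
    subs = []
    for i, ph in enumerate(phases):
        try:
            subs.append(
                SubMotion(
                    name=str(ph.get("name", f"phase{i + 1}")),
                    start_label=str(ph["start"]),
                    performing_label=str(ph["performing"]),
                    end_label=str(ph["end"]),
                )
            )
        except KeyError as exc:
            raise ModelDefinitionError(f"phase {i}: missing key {exc}") from exc
    return MotionModel(name=str(definition.get("name", "motion")), sub_motions=tuple(subs))


def load_model(path: str | Path) -> MotionModel:
    """Load a motion model from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return build_model(data)


def boundary_states(model: MotionModel) -> list[int]:
    """Class indices of the N+1 boundary states, in temporal order.

    These are the states whose temporal indices the segmentation step
    localizes: the start of the first phase, each shared phase boundary,
    and the end of the last phase.
    """
    labels = [model.sub_motions[0].start_label] + [sm.end_label for sm in model.sub_motions]
    return [model.state_index[lab] for lab in labels]


def state_pattern(model: MotionModel) -> list[int]:
    """The full expected temporal class-index pattern of one motion instance.

    Length ``2N + 1``: start, performing, boundary, performing, ...,
    final end state, with each shared boundary appearing once.
    """
    return [model.state_index[lab] for lab in model.state_labels()]


def bundled_config_path(name: str) -> Path:
    """Path to a bundled example model config (``soccer_kick`` or ``two_hand_throw``)."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(p)
    return p
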