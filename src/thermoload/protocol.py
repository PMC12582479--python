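"""Experimental protocol description and per-modality measurement grids.

The session alternates between two climate-chamber rooms: a preparation
block, a pre-exposure block in room A, seven 21-minute blocks alternating
room B and room A (starting and ending with B), and a post-exposure block
in room A.  Four conditions differ only in the room set-point temperatures
(control 26-26 up to the 15 degree step 21-36).

Each modality is observed on its own time grid:

* ``skin`` -- continuous 1 Hz recording averaged over 3 equal sub-ranges in
  each of A_pre/A_post and 4 equal sub-ranges in every intermediate block;
* ``hr``/``hf``/``lfhf`` -- one value per 5-minute rest block;
* ``vas`` -- one value per questionnaire block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

SECTION_LABELS = ("prep", "A_pre", "B", "A", "A_post")
MODALITIES = ("vas", "skin", "hr", "hf", "lfhf")

#: canonical condition labels, control first
CONDITIONS = ("T_26-26", "T_26-31", "T_26-36", "T_21-36")
#: short keys used for the per-condition state components
CONDITION_KEYS = {"T_26-26": "a", "T_26-31": "b", "T_26-36": "c", "T_21-36": "d"}

REST_MINUTES = 5.0
QUESTIONNAIRE_MINUTES = 1.0


@dataclass(frozen=True)
class Section:
    """One protocol block: a label, a duration in minutes and the room."""

    label: str
    duration: float
    room: str  # "A", "B" or "none"

    def __post_init__(self) -> None:
        if self.label not in SECTION_LABELS:
            raise ValueError(f"unknown section label {self.label!r}")
        if self.duration <= 0:
            raise ValueError("section duration must be positive")
        if self.room not in ("A", "B", "none"):
            raise ValueError(f"unknown room {self.room!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Machine description of one experimental session.

    Parameters
    ----------
    sections
        Ordered blocks; must begin with ``prep`` and end with ``A_post``,
        with B/A blocks strictly alternating in between (B first, B last).
    condition_temperatures
        Condition label -> (room A set-point, room B set-point) in deg C.
    rest_plan
        Section label -> number of 5-minute rest blocks in that section.
    questionnaire_plan
        Section label -> number of questionnaire blocks in that section.
    """

    sections: tuple[Section, ...]
    condition_temperatures: dict[str, tuple[float, float]]
    rest_plan: dict[str, int] = field(default_factory=dict)
    questionnaire_plan: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("protocol needs at least one section")
        if self.sections[0].label != "prep":
            raise ValueError("protocol must begin with prep")
        if self.sections[-1].label != "A_post":
            raise ValueError("protocol must end with A_post")
        inner = [s for s in self.sections if s.label in ("A", "B")]
        if inner:
            expected = ["B" if i % 2 == 0 else "A" for i in range(len(inner))]
            if [s.label for s in inner] != expected or inner[-1].label != "B":
                raise ValueError("B and A sections must alternate, first and last B")
        if len(self.condition_temperatures) != 4:
            raise ValueError("exactly 4 conditions required")

    @property
    def n_b_visits(self) -> int:
        return sum(1 for s in self.sections if s.label == "B")

    def total_minutes(self) -> float:
        return float(sum(s.duration for s in self.sections))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sections": [asdict(s) for s in self.sections],
            "condition_temperatures": {
                k: list(v) for k, v in self.condition_temperatures.items()
            },
            "rest_plan": dict(self.rest_plan),
            "questionnaire_plan": dict(self.questionnaire_plan),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            sections=tuple(Section(**s) for s in d["sections"]),
            condition_temperatures={
                k: tuple(v) for k, v in d["condition_temperatures"].items()
            },
            rest_plan={k: int(v) for k, v in d.get("rest_plan", {}).items()},
            questionnaire_plan={
                k: int(v) for k, v in d.get("questionnaire_plan", {}).items()
            },
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class GridPoint:
    t: int  # 1-based time index
    mid_min: float  # wall-clock midpoint of the averaging window
    start_min: float
    end_min: float
    section: str
    room: str


@dataclass(frozen=True)
class MeasurementGrid:
    """Time grid of one modality: averaging windows and the seasonal period.

    ``period`` is the number of grid points contributed by one consecutive
    B+A room pair; it sets the summation length N of the Env recursion.
    """

    modality: str
    points: tuple[GridPoint, ...]
    period: int

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if [p.t for p in self.points] != list(range(1, len(self.points) + 1)):
            raise ValueError("grid indices must be consecutive from 1")
        mids = [p.mid_min for p in self.points]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("grid midpoints must be strictly increasing")
        if self.period < 2:
            raise ValueError("period must be >= 2")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "modality": self.modality,
                "t": [p.t for p in self.points],
                "minutes": [p.mid_min for p in self.points],
                "section": [p.section for p in self.points],
                "room": [p.room for p in self.points],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_protocol() -> ProtocolSpec:
    """The packaged session layout.

    6-min preparation, 14-min A_pre, seven alternating 21-min blocks
    (B, A, B, A, B, A, B: four B visits), 14-min A_post.  One rest block in
    each of A_pre/A_post and three per 21-min block (23 total); one
    questionnaire in prep (practice), one in each of A_pre/A_post and four
    per 21-min block (31 total).
    """
    inner = tuple(
        Section("B" if i % 2 == 0 else "A", 21.0, "B" if i % 2 == 0 else "A")
        for i in range(7)
    )
    sections = (
        Section("prep", 6.0, "A"),
        Section("A_pre", 14.0, "A"),
        *inner,
        Section("A_post", 14.0, "A"),
    )
    return ProtocolSpec(
        sections=sections,
        condition_temperatures={
            "T_26-26": (26.0, 26.0),
            "T_26-31": (26.0, 31.0),
            "T_26-36": (26.0, 36.0),
            "T_21-36": (21.0, 36.0),
        },
        rest_plan={"prep": 0, "A_pre": 1, "B": 3, "A": 3, "A_post": 1},
        questionnaire_plan={"prep": 1, "A_pre": 1, "B": 4, "A": 4, "A_post": 1},
    )


def _section_offsets(spec: ProtocolSpec) -> list[float]:
    offs, acc = [], 0.0
    for s in spec.sections:
        offs.append(acc)
        acc += s.duration
    return offs


def _block_windows(
    section: Section, start: float, n_blocks: int, block_minutes: float
) -> list[tuple[float, float]]:
    """Centre ``n_blocks`` blocks of ``block_minutes`` in equal slots."""
    if n_blocks <= 0:
        return []
    slot = section.duration / n_blocks
    width = min(block_minutes, slot)
    out = []
    for i in range(n_blocks):
        centre = start + (i + 0.5) * slot
        out.append((centre - width / 2.0, centre + width / 2.0))
    return out


def build_grid(spec: ProtocolSpec, modality: str) -> MeasurementGrid:
    """Construct the measurement grid of ``modality`` for ``spec``.

    Continuous modalities (``skin``) are averaged over 3 equal sub-ranges in
    A_pre/A_post and 4 in each intermediate section; ``hr``/``hf``/``lfhf``
    get one point per rest block, ``vas`` one per questionnaire block.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    offsets = _section_offsets(spec)
    points: list[GridPoint] = []
    per_section_counts: list[tuple[str, int]] = []
    for sec, start in zip(spec.sections, offsets):
        if modality == "skin":
            if sec.label in ("A_pre", "A_post"):
                n = 3
            elif sec.label in ("A", "B"):
                n = 4
            else:
                n = 0
            sub = sec.duration / n if n else 0.0
            windows = [(start + i * sub, start + (i + 1) * sub) for i in range(n)]
        elif modality in ("hr", "hf", "lfhf"):
            n = spec.rest_plan.get(sec.label, 0)
            windows = _block_windows(sec, start, n, REST_MINUTES)
        else:  # vas
            n = spec.questionnaire_plan.get(sec.label, 0)
            windows = _block_windows(sec, start, n, QUESTIONNAIRE_MINUTES)
        per_section_counts.append((sec.label, len(windows)))
        for lo, hi in windows:
            points.append(
                GridPoint(
                    t=len(points) + 1,
                    mid_min=(lo + hi) / 2.0,
                    start_min=lo,
                    end_min=hi,
                    section=sec.label,
                    room=sec.room,
                )
            )
    # points per consecutive B+A pair
    per_b = [c for lbl, c in per_section_counts if lbl == "B"]
    per_a = [c for lbl, c in per_section_counts if lbl == "A"]
    if per_b and per_a:
        period = per_b[0] + per_a[0]
    elif per_b:
        period = 2 * per_b[0]
    else:
        period = 2
    return MeasurementGrid(modality=modality, points=tuple(points), period=max(period, 2))
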