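"""Cohort data model, preprocessing, and CSV/JSON input-output.

A cohort indexes one univariate joint-angle trace (degrees) per
(participant-side, movement, angle) triple.  Recordings have variable
duration because every individual performs each movement exactly once, at
their own pace; before any network is learned all traces are brought to a
common length ``m_max`` (default 1500 samples) by spline resampling, so
that traces live in one vector space where Euclidean comparisons make
sense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import CompletenessError, InvalidInputError, SchemaError

DEFAULT_M_MAX = 1500

REGIONS = ("shoulder", "elbow", "wrist", "thorax", "lumbar")
GROUPS = ("stroke", "control")
SIDES = ("L", "R")

#: group/side token used by the filtering module and the CLI
GROUP_SIDE_TOKENS = ("strokeL", "strokeR", "ctrlL", "ctrlR")


@dataclass(frozen=True)
class JointAngle:
    """One anatomical angle channel (e.g. ``"Elbow Flexion LT, deg"``).

    ``display_rank`` fixes the body-ordered position used by the arc view:
    channels are always drawn shoulder-to-lumbar, never in storage order.
    """

    id: int
    name: str
    region: str
    display_rank: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SchemaError(f"unknown region {self.region!r} for angle {self.name!r}")


@dataclass(frozen=True)
class ParticipantSide:
    """One recorded body side of one individual.

    Stroke patients are recorded on the paretic side only; controls on both
    sides, so a control individual contributes two ParticipantSide records.
    ``fma_total`` is the upper-extremity Fugl-Meyer total (0-66) and
    ``fma_item`` maps movement index -> per-item score (0/1/2).
    """

    id: str
    group: str
    side: str
    fma_total: int | None = None
    fma_item: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group token {self.group!r}")
        if self.side not in SIDES:
            raise SchemaError(f"unknown side token {self.side!r}")

    @property
    def group_side(self) -> str:
        """Token in {strokeL, strokeR, ctrlL, ctrlR}."""
        prefix = "stroke" if self.group == "stroke" else "ctrl"
        return prefix + self.side


@dataclass
class TimeSeries:
    """One joint-angle trace in degrees.

    ``original_length`` records the duration (sample count) before any
    resampling; it survives preprocessing so that "Proportional" group
    summaries can recover the real time extent.
    """

    participant: str
    movement: int
    angle: int
    values: np.ndarray
    original_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class Cohort:
    """The full indexed collection of series plus metadata."""

    angles: list[JointAngle]
    movements: list[str]
    participants: list[ParticipantSide]
    series: dict[tuple[str, int, int], TimeSeries] = field(default_factory=dict)
    m_max: int = DEFAULT_M_MAX

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_movements(self) -> int:
        return len(self.movements)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def participant(self, pid: str) -> ParticipantSide:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def movement_series(self, pid: str, movement: int) -> list[TimeSeries]:
        """All angle traces of one recording, in angle-id order."""
        out = []
        for a in range(self.n_angles):
            key = (pid, movement, a)
            if key not in self.series:
                raise CompletenessError(f"missing series for triple {key}")
            out.append(self.series[key])
        return out

    def validate(self) -> None:
        """Check totality of the series map and angle-id contiguity."""
        ids = sorted(a.id for a in self.angles)
        if ids != list(range(self.n_angles)):
            raise SchemaError("angle ids must be unique and contiguous from 0")
        ranks = sorted(a.display_rank for a in self.angles)
        if ranks != list(range(self.n_angles)):
            raise SchemaError("display_rank must be a permutation of angle ids")
        for p in self.participants:
            for m in range(self.n_movements):
                for a in range(self.n_angles):
                    if (p.id, m, a) not in self.series:
                        raise CompletenessError(
                            f"missing series for triple ({p.id!r}, {m}, {a})"
                        )

    def resample_all(self) -> None:
        """Bring every stored series to length ``m_max`` in place."""
        for ts in self.series.values():
            if len(ts.values) != self.m_max:
                ts.values = resample_to_common_length(ts.values, self.m_max)


def resample_to_common_length(values, target_length: int) -> np.ndarray:
    """Resample a trace to ``target_length`` samples with an interpolating
    spline.

    The original sample positions are mapped affinely onto [0, 1]; a cubic
    interpolating spline (linear for inputs of length 2 or 3, where a cubic
    is under-determined) is evaluated on the uniform target grid.  Endpoints
    are preserved exactly and the operation is idempotent at the target
    length.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("resampling needs a 1-D series of length >= 2")
    if target_length < 2:
        raise InvalidInputError("target_length must be >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains non-finite values")
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, target_length)
    if x.size < 4:
        return np.interp(dst, src, x)
    return CubicSpline(src, x)(dst)


def count_series(cohort: Cohort) -> int:
    """Total number of stored series; equals N_P * N_M * N_A for a complete
    cohort."""
    expected = cohort.n_participants * cohort.n_movements * cohort.n_angles
    actual = len(cohort.series)
    if actual != expected:
        raise CompletenessError(
            f"cohort stores {actual} series but the index grid has {expected}"
        )
    return actual


# --------------------------------------------------------------------------
# on-disk layout:
#   <root>/cohort.json                 metadata (angles, movements, participants)
#   <root>/<participant-id>/M01.csv    one CSV per movement; header = angle
#                                      names, one column per angle, rows = time
# --------------------------------------------------------------------------


def _movement_filename(movement: int) -> str:
    return f"M{movement + 1:02d}.csv"


def save_cohort(cohort: Cohort, path) -> None:
    """Write a cohort directory (CSV per recording + one metadata JSON).

    Values are written at their current length; a cohort holding raw
    variable-duration traces round-trips through ``load_cohort(...,
    resample=False)`` losslessly.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    meta = {
        "m_max": cohort.m_max,
        "movements": list(cohort.movements),
        "angles": [
            {
                "id": a.id,
                "name": a.name,
                "region": a.region,
                "display_rank": a.display_rank,
            }
            for a in cohort.angles
        ],
        "participants": [
            {
                "id": p.id,
                "group": p.group,
                "side": p.side,
                "fma_total": p.fma_total,
                "fma_item": (
                    {str(k): v for k, v in p.fma_item.items()} if p.fma_item else None
                ),
            }
            for p in cohort.participants
        ],
    }
    (root / "cohort.json").write_text(json.dumps(meta, indent=1))
    names = [a.name for a in sorted(cohort.angles, key=lambda a: a.id)]
    for p in cohort.participants:
        pdir = root / p.id
        pdir.mkdir(exist_ok=True)
        for m in range(cohort.n_movements):
            cols = {}
            for a in range(cohort.n_angles):
                ts = cohort.series[(p.id, m, a)]
                cols[names[a]] = ts.values
            lengths = {len(v) for v in cols.values()}
            if len(lengths) != 1:
                raise InvalidInputError(
                    f"angles of recording ({p.id!r}, {m}) have unequal lengths"
                )
            pd.DataFrame(cols).to_csv(pdir / _movement_filename(m), index=False)


def load_cohort(path, resample: bool = True) -> Cohort:
    """Read a cohort directory.

    With ``resample=True`` (the default) every series whose stored length
    differs from ``m_max`` is spline-resampled on load, so the returned
    cohort is ready for network learning; ``original_length`` keeps the
    stored duration.
    """
    root = Path(path)
    meta_path = root / "cohort.json"
    if not meta_path.exists():
        raise SchemaError(f"no cohort.json under {root}")
    meta = json.loads(meta_path.read_text())
    try:
        angles = [
            JointAngle(a["id"], a["name"], a["region"], a["display_rank"])
            for a in meta["angles"]
        ]
        movements = list(meta["movements"])
        participants = [
            ParticipantSide(
                p["id"],
                p["group"],
                p["side"],
                p.get("fma_total"),
                (
                    {int(k): v for k, v in p["fma_item"].items()}
                    if p.get("fma_item")
                    else None
                ),
            )
            for p in meta["participants"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed cohort.json: {exc}") from exc
    cohort = Cohort(angles, movements, participants, m_max=meta.get("m_max", DEFAULT_M_MAX))
    name_to_id = {a.name: a.id for a in angles}
    for p in participants:
        for m in range(cohort.n_movements):
            csv_path = root / p.id / _movement_filename(m)
            if not csv_path.exists():
                raise CompletenessError(
                    f"missing recording file for ({p.id!r}, movement {m})"
                )
            frame = pd.read_csv(csv_path)
            for a in angles:
                if a.name not in frame.columns:
                    raise CompletenessError(
                        f"missing series for triple ({p.id!r}, {m}, {a.id})"
                    )
                raw = frame[a.name].to_numpy(dtype=float)
                values = raw
                if resample and raw.size != cohort.m_max:
                    values = resample_to_common_length(raw, cohort.m_max)
                cohort.series[(p.id, m, a.id)] = TimeSeries(
                    p.id, m, a.id, values, original_length=int(raw.size)
                )
    cohort.validate()
    return cohort
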