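"""Synthetic cohorts with planted synchronization structure.

The generator emulates the statistical shape of wearable joint-angle
recordings: smooth low-frequency excursions of 10-90 degrees, one
variable-duration execution per (participant-side, movement), occasional
motionless channels (all-zero or constant), and pairs of channels coupled
through shared latent curves.  Couplings are declared per group (or per
individual, for planting outliers) and may differ between stroke and
control groups, which is exactly the structure the network-learning
pipeline is meant to recover; the emitted ground truth makes recovery
testable.

Latent curves are drawn once per (group, movement, coupled component), so
coupled channels agree within an individual *and* follow a common
group-level shape across individuals; uncoupled channels are independent
per individual.  Group differences are therefore encoded purely through
the coupling structure, never through amplitude conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Cohort, JointAngle, ParticipantSide, TimeSeries
from .errors import ConfigError

GROUP_KEYS = ("stroke", "control")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    ``couplings`` maps "stroke"/"control" (or a participant id, for
    planted outliers) to a list of ((angle_i, angle_j), movement) pairs.
    ``null_channels`` / ``constant_channels`` map group -> list of entries,
    each an angle id (motionless in every movement) or an (angle, movement)
    tuple (motionless in that movement only).  Defaults reproduce a
    full study-scale cohort: 28 left- and 23 right-paretic stroke sides, 18
    control individuals recorded on both sides, 13 movements, 20 angles.
    """

    n_stroke_L: int = 28
    n_stroke_R: int = 23
    n_ctrl: int = 18  # per side; controls are recorded on both sides
    n_movements: int = 13
    n_angles: int = 20
    couplings: dict = field(
        default_factory=lambda: {
            "stroke": [((1, 2), 0)],
            "control": [((0, 1), 0)],
        }
    )
    noise_sd: float = 1.0
    null_channels: dict = field(default_factory=dict)
    constant_channels: dict = field(default_factory=dict)
    duration_range: tuple[int, int] = (600, 1500)
    seed: int = 0
    m_max: int = 1500
    amplitude_range: tuple[float, float] = (10.0, 90.0)
    angle_names: tuple | None = None
    angle_regions: tuple | None = None
    angle_display_order: tuple | None = None


@dataclass
class GroundTruth:
    """What was planted, per recording and per participant."""

    planted: dict[tuple[str, int], set[tuple[int, int]]] = field(default_factory=dict)
    null_channels: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    constant_channels: dict[str, set[tuple[int, int]]] = field(default_factory=dict)


_CANONICAL_ARM = (
    ("Shoulder Flexion", "shoulder"),
    ("Shoulder Rotation", "shoulder"),
    ("Shoulder Abduction", "shoulder"),
    ("Shoulder Total Flexion", "shoulder"),
    ("Elbow Flexion", "elbow"),
    ("Wrist Flexion", "wrist"),
    ("Forearm Pronation", "wrist"),
)
_CANONICAL_TRUNK = (
    ("Thoracic Flexion", "thorax"),
    ("Thoracic Axial", "thorax"),
    ("Thoracic Lateral", "thorax"),
    ("Lumbar Flexion", "lumbar"),
    ("Lumbar Axial", "lumbar"),
    ("Lumbar Lateral", "lumbar"),
)


def default_angles(n: int) -> list[JointAngle]:
    """Illustrative angle list.

    For n = 20 this is seven arm angles per side plus six trunk angles;
    other sizes fall back to generic channel names spread across regions.
    The display order follows body location: shoulder, elbow, wrist,
    thorax, lumbar.
    """
    if n == 20:
        entries = (
            [(f"{nm} LT, deg", rg) for nm, rg in _CANONICAL_ARM]
            + [(f"{nm} RT, deg", rg) for nm, rg in _CANONICAL_ARM]
            + [(f"{nm}, deg", rg) for nm, rg in _CANONICAL_TRUNK]
        )
    else:
        regions = ("shoulder", "elbow", "wrist", "thorax", "lumbar")
        entries = [
            (f"Channel {i + 1}, deg", regions[(i * len(regions)) // n]) for i in range(n)
        ]
    return _angles_from_entries(entries, None)


def _angles_from_entries(entries, display_order) -> list[JointAngle]:
    region_rank = {"shoulder": 0, "elbow": 1, "wrist": 2, "thorax": 3, "lumbar": 4}
    if display_order is None:
        display_order = sorted(
            range(len(entries)), key=lambda i: (region_rank[entries[i][1]], i)
        )
    rank = {aid: pos for pos, aid in enumerate(display_order)}
    return [
        JointAngle(i, name, region, rank[i]) for i, (name, region) in enumerate(entries)
    ]


def _expand_channel_list(raw, n_movements) -> set[tuple[int, int]]:
    out = set()
    for entry in raw:
        if isinstance(entry, int):
            out.update((entry, m) for m in range(n_movements))
        else:
            a, m = entry
            if m is None:
                out.update((a, mm) for mm in range(n_movements))
            else:
                out.add((a, m))
    return out


def _components(pairs) -> list[set[int]]:
    parent: dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, set[int]] = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return [comps[r] for r in sorted(comps)]


class _CurveParams:
    """A smooth band-limited curve on [0, 1]: 2-4 sinusoids of at most 3
    cycles plus a linear drift, total amplitude 10-90 degrees.

    ``band`` restricts the sinusoid frequencies; latents of different
    coupled components are drawn from disjoint bands so that distinct
    latents decorrelate (all very-low-frequency smooth curves would
    otherwise be substantially correlated by chance).
    """

    def __init__(self, rng, amplitude_range, band=(0.25, 3.0)):
        n_sin = int(rng.integers(2, 5))
        amp_total = rng.uniform(*amplitude_range)
        w = rng.uniform(0.2, 1.0, n_sin)
        self.amps = amp_total * w / w.sum()
        self.cycles = rng.uniform(band[0], band[1], n_sin)
        self.phases = rng.uniform(0.0, 2 * np.pi, n_sin)
        self.drift = rng.uniform(-10.0, 10.0)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        y = self.drift * t
        for a, c, ph in zip(self.amps, self.cycles, self.phases):
            y = y + a * np.sin(2 * np.pi * c * t + ph)
        return y


def _validate(cfg: SyntheticConfig, nulls, consts, participants) -> None:
    lo, hi = cfg.duration_range
    if not (2 <= lo <= hi <= cfg.m_max):
        raise ConfigError("duration_range must lie within [2, m_max]")
    group_of = {p.id: p.group for p in participants}
    for key, plist in cfg.couplings.items():
        if key in GROUP_KEYS:
            groups = [key]
        elif key in group_of:
            groups = [group_of[key]]
        else:
            raise ConfigError(f"couplings key {key!r} is neither a group nor a participant")
        for (a, b), m in plist:
            if not (0 <= m < cfg.n_movements):
                raise ConfigError(f"coupling references unknown movement {m}")
            if a == b or not all(0 <= x < cfg.n_angles for x in (a, b)):
                raise ConfigError(f"coupling references invalid angle pair ({a}, {b})")
            for g in groups:
                for x in (a, b):
                    if (x, m) in nulls.get(g, set()):
                        raise ConfigError(
                            f"coupling ({a}, {b}) on movement {m} references "
                            f"null channel {x} of group {g!r}"
                        )
                    if (x, m) in consts.get(g, set()):
                        raise ConfigError(
                            f"coupling ({a}, {b}) on movement {m} references "
                            f"constant channel {x} of group {g!r}"
                        )


def generate_cohort(cfg: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort (series at their original variable durations) plus
    ground truth.  Fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    participants = []
    k = 0
    for _ in range(cfg.n_stroke_L):
        k += 1
        participants.append(("stroke_%d" % k, "stroke", "L"))
    for _ in range(cfg.n_stroke_R):
        k += 1
        participants.append(("stroke_%d" % k, "stroke", "R"))
    for i in range(cfg.n_ctrl):
        participants.append(("ctrl_%d_L" % (i + 1), "control", "L"))
    for i in range(cfg.n_ctrl):
        participants.append(("ctrl_%d_R" % (i + 1), "control", "R"))

    ps = []
    for pid, group, side in participants:
        if group == "stroke":
            total = int(rng.integers(8, 66))
            items = {m: int(rng.integers(0, 3)) for m in range(cfg.n_movements)}
        else:
            total = int(rng.integers(62, 67))
            items = {m: 2 for m in range(cfg.n_movements)}
        ps.append(ParticipantSide(pid, group, side, total, items))

    nulls = {g: _expand_channel_list(cfg.null_channels.get(g, ()), cfg.n_movements) for g in GROUP_KEYS}
    consts = {g: _expand_channel_list(cfg.constant_channels.get(g, ()), cfg.n_movements) for g in GROUP_KEYS}
    _validate(cfg, nulls, consts, ps)

    if cfg.angle_names is not None:
        regions = cfg.angle_regions or ("shoulder",) * cfg.n_angles
        angles = _angles_from_entries(
            list(zip(cfg.angle_names, regions)), cfg.angle_display_order
        )
    else:
        angles = default_angles(cfg.n_angles)
    movements = [f"M{m + 1}" for m in range(cfg.n_movements)]

    # group-level latents: one curve per (group, movement, coupled
    # component).  Each component draws from its own frequency band and
    # the curves of one (group, movement) are Gram-Schmidt
    # decorrelated on the master grid, so that distinct latents have
    # (near-)zero cross-correlation by construction - random smooth
    # low-frequency curves would otherwise correlate substantially by
    # chance, blurring the planted coupling structure.
    bands = ((0.25, 0.75), (0.8, 1.3), (1.35, 1.85), (1.9, 2.4), (2.45, 2.95))
    t_master = np.linspace(0.0, 1.0, cfg.m_max)

    def _latent_curve(band, basis):
        raw = _CurveParams(rng, cfg.amplitude_range, band=band)(t_master)
        centered = raw - raw.mean()
        norm = np.linalg.norm(centered)
        for e in basis:
            centered = centered - (centered @ e) * e
        residual = np.linalg.norm(centered)
        if residual > 1e-12 and norm > 0:
            centered = centered * (norm / residual)
            basis.append(centered / norm)
        return centered + raw.mean()

    group_pairs: dict[str, dict[int, list]] = {g: {} for g in GROUP_KEYS}
    for g in GROUP_KEYS:
        for (pair, m) in cfg.couplings.get(g, ()):
            group_pairs[g].setdefault(m, []).append(pair)
    group_latents: dict[str, dict[int, dict[frozenset, np.ndarray]]] = {}
    latent_basis: dict[tuple[str, int], list[np.ndarray]] = {}
    for g in GROUP_KEYS:
        group_latents[g] = {}
        for m in range(cfg.n_movements):
            basis: list[np.ndarray] = []
            comps = _components(group_pairs[g].get(m, []))
            group_latents[g][m] = {
                frozenset(comp): _latent_curve(bands[k % len(bands)], basis)
                for k, comp in enumerate(comps)
            }
            latent_basis[(g, m)] = basis

    extra_pairs: dict[str, dict[int, list]] = {}
    for key, plist in cfg.couplings.items():
        if key in GROUP_KEYS:
            continue
        extra_pairs[key] = {}
        for (pair, m) in plist:
            extra_pairs[key].setdefault(m, []).append(pair)

    cohort = Cohort(angles, movements, ps, m_max=cfg.m_max)
    truth = GroundTruth()
    lo, hi = cfg.duration_range

    for p in ps:
        truth.null_channels[p.id] = set(nulls[p.group])
        truth.constant_channels[p.id] = set(consts[p.group])
        for m in range(cfg.n_movements):
            duration = int(rng.integers(lo, hi + 1))
            t = np.linspace(0.0, 1.0, duration)
            scale = rng.uniform(0.9, 1.1)

            # components of the participant's full coupling set; components
            # touched by participant-specific (outlier) pairs get a fresh
            # latent so the outlier's channels genuinely merge
            g_pairs = group_pairs[p.group].get(m, [])
            e_pairs = extra_pairs.get(p.id, {}).get(m, [])
            extra_angles = {a for pair in e_pairs for a in pair}
            member_of: dict[int, np.ndarray] = {}
            for comp in _components(g_pairs + e_pairs):
                if comp & extra_angles:
                    basis = list(latent_basis[(p.group, m)])
                    curve = _latent_curve((0.25, 3.0), basis)
                else:
                    curve = group_latents[p.group][m][frozenset(comp)]
                for a in comp:
                    member_of[a] = curve

            planted = {
                tuple(sorted(pair))
                for key in (p.group, p.id)
                for (pair, mm) in cfg.couplings.get(key, ())
                if mm == m
            }
            truth.planted[(p.id, m)] = planted

            for a in range(cfg.n_angles):
                if (a, m) in nulls[p.group]:
                    values = np.zeros(duration)
                elif (a, m) in consts[p.group]:
                    values = np.full(duration, rng.uniform(-30.0, 30.0))
                else:
                    curve = member_of.get(a)
                    if curve is None:
                        values = scale * _CurveParams(rng, cfg.amplitude_range)(t)
                    else:
                        values = scale * np.interp(t, t_master, curve)
                    if cfg.noise_sd > 0:
                        values = values + rng.normal(0.0, cfg.noise_sd, duration)
                cohort.series[(p.id, m, a)] = TimeSeries(
                    p.id, m, a, values, original_length=duration
                )
    cohort.validate()
    return cohort, truth


def preset_case_study(name: str) -> SyntheticConfig:
    """Named configurations mirroring the two analysis scenarios.

    "flexor-synergy-like": one movement, both groups fully paired but with
    different pairings (group-specific latents), plus one stroke individual
    ("stroke_7") with an extra truncal coupling - exercises group
    separation in projections and outlier spotting.

    "shoulder-flexion-like": two movements; controls keep shoulder
    abduction, shoulder flexion and elbow flexion motionless (null) while
    stroke individuals synchronize abduction with flexion (movement 1) and
    abduction with elbow flexion (movement 2) - the Differences filter
    recovers exactly these two stroke-only pairs and no control-only pair.
    """
    if name == "flexor-synergy-like":
        names = (
            "Shoulder Flexion LT, deg",
            "Elbow Flexion LT, deg",
            "Shoulder Abduction LT, deg",
            "Shoulder Rotation LT, deg",
            "Wrist Flexion LT, deg",
            "Forearm Pronation LT, deg",
            "Shoulder Total Flexion LT, deg",
            "Thoracic Flexion, deg",
            "Lumbar Flexion, deg",
            "Thoracic Lateral, deg",
            "Wrist Deviation LT, deg",
        )
        regions = (
            "shoulder", "elbow", "shoulder", "shoulder", "wrist",
            "wrist", "shoulder", "thorax", "lumbar", "thorax", "wrist",
        )
        return SyntheticConfig(
            n_stroke_L=7,
            n_stroke_R=0,
            n_ctrl=5,
            n_movements=1,
            n_angles=11,
            couplings={
                "stroke": [((0, 1), 0), ((2, 3), 0), ((4, 5), 0), ((6, 7), 0), ((8, 9), 0)],
                "control": [((0, 2), 0), ((1, 3), 0), ((4, 6), 0), ((5, 7), 0), ((8, 9), 0)],
                "stroke_7": [((7, 8), 0)],
            },
            noise_sd=1.0,
            null_channels={"stroke": [10], "control": [10]},
            amplitude_range=(20.0, 90.0),
            angle_names=names,
            angle_regions=regions,
            seed=20,
        )
    if name == "shoulder-flexion-like":
        names = (
            "Shoulder Abduction LT, deg",
            "Shoulder Flexion LT, deg",
            "Elbow Flexion LT, deg",
            "Shoulder Rotation LT, deg",
            "Shoulder Total Flexion LT, deg",
            "Wrist Flexion LT, deg",
            "Forearm Pronation LT, deg",
            "Thoracic Flexion, deg",
            "Lumbar Flexion, deg",
        )
        regions = (
            "shoulder", "shoulder", "elbow", "shoulder", "shoulder",
            "wrist", "wrist", "thorax", "lumbar",
        )
        backbone = [((1, 2), 0), ((3, 4), 0), ((5, 6), 0), ((7, 8), 0)]
        return SyntheticConfig(
            n_stroke_L=6,
            n_stroke_R=0,
            n_ctrl=5,
            n_movements=1,
            n_angles=9,
            couplings={
                # normal synergies shared by everyone; abduction intrudes
                # into the flexion/elbow synergy only after stroke
                "stroke": [((0, 1), 0), ((0, 2), 0)] + backbone,
                "control": list(backbone),
            },
            noise_sd=1.0,
            constant_channels={"control": [0]},
            amplitude_range=(20.0, 90.0),
            angle_names=names,
            angle_regions=regions,
            seed=21,
        )
    raise ConfigError(f"unknown preset {name!r}")
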