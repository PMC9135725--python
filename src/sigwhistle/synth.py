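"""Synthetic whistle-study generator.

Simulates the kind of dataset a multi-site signature-whistle survey yields:
per-site repertoires of stereotyped contour prototypes (one per simulated
emitter identity), bout-structured emission schedules that satisfy or violate
the SIGID temporal criterion, one-off variant whistles, additive site-level
shifts on the acoustic parameters, identity-level random intercepts with
per-emission residual noise, and (optionally) rendered audio.

Every study carries ground-truth labels, and :func:`expected_labels`
re-derives them from the emission schedule alone, independently of any
classifier, so downstream stages can be tested against a known answer.

Contour family
--------------
Prototypes are piecewise-quadratic frequency trajectories.  Each contour
starts at its minimum frequency and ends at its maximum, rising and falling
through an even number of slope sign changes (0, 2 or 4 inflection points),
so minimum and start frequency coincide, as do maximum and end frequency.
This mirrors the predominantly rising contour types reported for
Mediterranean bottlenose dolphins and keeps all seven acoustic parameters
available in closed form for oracle tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from sigwhistle.contours import WhistleContour, shape_distance, shape_vector

log = logging.getLogger(__name__)

#: The seven acoustic parameters measured on each signature-whistle contour.
PARAM_NAMES = ("min_freq", "max_freq", "start_freq", "end_freq",
               "freq_range", "n_inflections", "duration")

#: Factors whose levels may shift the acoustic parameters.
FACTOR_NAMES = ("region", "site", "seabottom", "demography")


class ConfigurationError(ValueError):
    """An effect or session configuration refers to unknown levels."""


class GenerationError(RuntimeError):
    """A requested schedule cannot be realised (e.g. session too short)."""


# ---------------------------------------------------------------------------
# contour prototypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One quadratic frequency segment.

    Frequency over the segment is ``f(u) = f_start + (f_end - f_start) * u
    + curvature * u * (1 - u)`` with ``u = t / duration``.  With
    ``|curvature| < |f_end - f_start|`` the segment is strictly monotone, so
    slope sign changes happen only at segment boundaries.
    """

    duration: float
    f_start: float
    f_end: float
    curvature: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.f_start <= 0 or self.f_end <= 0:
            raise ValueError("segment frequencies must be positive")

    def frequency(self, u: np.ndarray) -> np.ndarray:
        rise = self.f_end - self.f_start
        return self.f_start + rise * u + self.curvature * u * (1.0 - u)

    def slope_signs(self) -> tuple[int, int]:
        """Sign of df/dt at the segment start and end."""
        rise = self.f_end - self.f_start
        return (int(np.sign(rise + self.curvature)), int(np.sign(rise - self.curvature)))

    def extrema(self) -> tuple[float, float]:
        """Exact (min, max) frequency over the segment."""
        rise = self.f_end - self.f_start
        cand = [self.f_start, self.f_end]
        if self.curvature != 0.0:
            u_star = (rise / self.curvature + 1.0) / 2.0
            if 0.0 < u_star < 1.0:
                cand.append(float(self.frequency(np.array([u_star]))[0]))
        return (min(cand), max(cand))


@dataclass(frozen=True)
class ContourPrototype:
    """A stereotyped whistle type: the template one identity emits.

    ``n_loops`` repetitions of the segment sequence, separated by
    ``inter_loop_gap`` seconds of silence, form one whistle unit.
    """

    identity: str
    segments: tuple[Segment, ...]
    n_loops: int = 1
    inter_loop_gap: float = 0.15

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("prototype needs at least one segment")
        if self.n_loops < 1:
            raise ValueError("n_loops must be >= 1")
        if self.inter_loop_gap < 0:
            raise ValueError("inter_loop_gap must be >= 0")

    @property
    def loop_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def total_duration(self) -> float:
        return self.n_loops * self.loop_duration + (self.n_loops - 1) * self.inter_loop_gap

    @property
    def max_frequency(self) -> float:
        return max(s.extrema()[1] for s in self.segments)

    @property
    def max_sweep_rate(self) -> float:
        """Largest |df/dt| over the contour, Hz/s (attained at segment ends)."""
        rates = []
        for s in self.segments:
            rise = s.f_end - s.f_start
            rates.append(max(abs(rise + s.curvature), abs(rise - s.curvature))
                         / s.duration)
        return max(rates)

    @property
    def min_frequency(self) -> float:
        return min(s.extrema()[0] for s in self.segments)

    def loop_frequency(self, t: np.ndarray) -> np.ndarray:
        """Frequency trajectory of a single loop at times ``t`` (0 .. loop_duration)."""
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        t0 = 0.0
        for seg in self.segments:
            mask = (t >= t0) & (t <= t0 + seg.duration)
            out[mask] = seg.frequency((t[mask] - t0) / seg.duration)
            t0 += seg.duration
        return out

    def sample_loops(self, dt: float = 0.005) -> list[tuple[np.ndarray, np.ndarray]]:
        """Sample each loop at step ``dt``: list of (times within unit, freqs)."""
        ld = self.loop_duration
        tl = np.arange(0.0, ld, dt)
        if tl[-1] < ld:
            tl = np.append(tl, ld)
        fl = self.loop_frequency(tl)
        out = []
        for k in range(self.n_loops):
            offset = k * (ld + self.inter_loop_gap)
            out.append((tl + offset, fl.copy()))
        return out

    def analytic_features(self) -> dict[str, float]:
        """The seven acoustic parameters of one whistle unit, in closed form.

        Inflection points are slope sign changes within loops (the silent
        inter-loop gaps contribute none), summed over loops.
        """
        lo = min(s.extrema()[0] for s in self.segments)
        hi = max(s.extrema()[1] for s in self.segments)
        signs: list[int] = []
        for seg in self.segments:
            signs.extend(s for s in seg.slope_signs() if s != 0)
        flips = sum(1 for a, b in zip(signs, signs[1:]) if a * b < 0)
        return {
            "min_freq": lo,
            "max_freq": hi,
            "start_freq": self.segments[0].f_start,
            "end_freq": self.segments[-1].f_end,
            "freq_range": hi - lo,
            "n_inflections": float(flips * self.n_loops),
            "duration": self.total_duration,
        }


# ---------------------------------------------------------------------------
# effect configuration and study container
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Additive effect structure imposed on the seven acoustic parameters.

    ``shifts[factor][level][param]`` is an additive shift (Hz, s or count)
    applied to every identity whose site carries that factor level.
    ``id_sd[param]`` is the identity-level random-intercept SD and
    ``resid_sd[param]`` the per-emission residual SD.  Shifts on
    ``start_freq`` act through the contour floor (as ``min_freq`` does);
    shifts on ``end_freq`` / ``freq_range`` act through the ceiling (as
    ``max_freq``), because start/end coincide with the extrema in this
    contour family.

    Residual noise is realised per emission as a whole-contour frequency
    offset (SD ``resid_sd['min_freq']``) and a duration rescaling
    (SD ``resid_sd['duration']`` seconds).
    """

    shifts: dict = field(default_factory=dict)
    id_sd: dict = field(default_factory=dict)
    resid_sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for factor, levels in self.shifts.items():
            if factor not in FACTOR_NAMES:
                raise ConfigurationError(f"unknown factor {factor!r}")
            for level, params in levels.items():
                for p in params:
                    if p not in PARAM_NAMES:
                        raise ConfigurationError(f"unknown parameter {p!r} for level {level!r}")
        for d in (self.id_sd, self.resid_sd):
            for p, v in d.items():
                if p not in PARAM_NAMES:
                    raise ConfigurationError(f"unknown parameter {p!r}")
                if v < 0:
                    raise ConfigurationError(f"SD for {p!r} must be >= 0")

    def validate_levels(self, site_profiles: pd.DataFrame) -> None:
        for factor, levels in self.shifts.items():
            if factor == "site":
                known = set(site_profiles.index)
            else:
                known = set(site_profiles[factor].unique())
            for level in levels:
                if level not in known:
                    raise ConfigurationError(
                        f"effect level {level!r} not a level of factor {factor!r}")

    def shift_for(self, profile: pd.Series, param: str) -> float:
        total = 0.0
        for factor, levels in self.shifts.items():
            level = profile.name if factor == "site" else profile[factor]
            total += float(levels.get(level, {}).get(param, 0.0))
        return total


@dataclass
class Emission:
    """One scheduled whistle unit (all loops) of one identity."""

    session_id: str
    identity: str
    t_start: float
    prototype: ContourPrototype
    kind: str  # "sw" | "rewt" | "sparse" | "variant"

    @property
    def t_end(self) -> float:
        return self.t_start + self.prototype.total_duration


@dataclass
class SyntheticStudy:
    """A generated multi-site study: site table, prototypes, effect config."""

    site_profiles: pd.DataFrame
    prototypes: dict[str, ContourPrototype]
    identity_site: dict[str, str]
    effects: EffectConfig
    seed: int

    def identities_at(self, site: str) -> list[str]:
        return [i for i, s in self.identity_site.items() if s == site]

    def to_json(self) -> str:
        """Serialise the study (used for byte-identity determinism checks)."""

        def proto(p: ContourPrototype) -> dict:
            return {"identity": p.identity,
                    "segments": [asdict(s) for s in p.segments],
                    "n_loops": p.n_loops, "inter_loop_gap": p.inter_loop_gap}

        payload = {
            "seed": self.seed,
            "sites": self.site_profiles.reset_index().to_dict(orient="list"),
            "identity_site": self.identity_site,
            "prototypes": {k: proto(v) for k, v in sorted(self.prototypes.items())},
            "effects": {"shifts": self.effects.shifts, "id_sd": self.effects.id_sd,
                        "resid_sd": self.effects.resid_sd},
        }
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# default site metadata (six Mediterranean study sites)
# ---------------------------------------------------------------------------

def default_site_profiles() -> pd.DataFrame:
    """Site-metadata table for the six simulated Mediterranean sites.

    Columns follow the published survey design: region (proxy of genetic
    structure), sea-bottom cluster (H1-H3), demography cluster (P1-P4),
    EUNIS-style habitat presence indicators, depth, mark-recapture population
    size with CI, group size range, residency pattern and connectivity.
    """
    rows = [
        # site, region, H, P, posidonia, infral_sand, circal_coarse, muddy_detritic,
        # terrigenous_mud, open_sea_detritic, bathyal_mud, infral_mud, depth,
        # pop_mean, pop_lo, pop_hi, grp_mean, grp_lo, grp_hi, residency, connection
        ("PC", "WEST", "H1", "P4", 1, 1, 1, 0, 0, 0, 0, 0, 150, 223, 152, 385, 16, 1, 55, "transient", "yes"),
        ("AL", "WEST", "H2", "P2", 1, 0, 1, 1, 0, 0, 0, 0, 115, 76, 61, 118, 7, 1, 17, "resident", "yes"),
        ("FI", "WEST", "H2", "P4", 0, 0, 1, 1, 1, 0, 0, 0, 100, 529, 456, 614, 15, 1, 65, "transient", "yes"),
        ("LA", "SOUTH", "H1", "P1", 1, 1, 1, 0, 0, 0, 0, 0, 110, 249, 162, 449, 4, 1, 20, "transient", "no"),
        ("GC", "EAST", "H3", "P2", 0, 0, 0, 0, 1, 1, 1, 0, 500, 38, 32, 46, 8, 1, 28, "resident", "yes"),
        ("CL", "EAST", "H2", "P3", 0, 0, 1, 0, 1, 0, 0, 1, 70, 184, 152, 250, 22, 2, 46, "resident", "no"),
    ]
    cols = ["site", "region", "seabottom", "demography",
            "hab_posidonia", "hab_infralittoral_sand", "hab_circalittoral_coarse",
            "hab_muddy_detritic", "hab_terrigenous_mud", "hab_open_sea_detritic",
            "hab_bathyal_mud", "hab_infralittoral_mud", "depth_max_m",
            "pop_size_mean", "pop_size_lo", "pop_size_hi",
            "group_size_mean", "group_size_min", "group_size_max",
            "residency", "connection"]
    return pd.DataFrame(rows, columns=cols).set_index("site")


# ---------------------------------------------------------------------------
# repertoire generation
# ---------------------------------------------------------------------------

# Baseline distributions of the generative parameters (Hz / s / counts).
BASE_F_MIN = (5500.0, 700.0)
BASE_F_MAX = (13500.0, 900.0)
BASE_DURATION = (0.9, 0.18)
INFLECTION_CHOICES = (0, 2, 4)
INFLECTION_PROBS = (0.30, 0.50, 0.20)
MIN_SEPARATION_HZ = 2000.0   # enforced gap between contour floor and ceiling
SHAPE_REJECT_MARGIN = 0.45   # minimum shape distance between distinct prototypes
MAX_SWEEP_RATE_HZ_S = 80000.0  # realism cap on |df/dt|; keeps ridges traceable


def _draw_prototype(identity: str, f_min: float, f_max: float, duration: float,
                    n_infl: int, n_loops: int, inter_loop_gap: float,
                    rng: np.random.Generator) -> ContourPrototype:
    """Build a piecewise-quadratic contour with exactly ``n_infl`` inflections.

    The contour rises from ``f_min`` to ``f_max`` through ``n_infl + 1``
    alternating monotone runs; each run is split into two quadratic segments
    at a random interior level, which gives a rich shape space (fast/slow
    rises, chevrons, multi-humped contours) while keeping the extrema and the
    inflection count analytic.
    """
    frange = f_max - f_min
    n_runs = n_infl + 1
    # run endpoint levels: start at floor, end at ceiling, interior
    # extremes alternate peak / trough strictly inside (f_min, f_max)
    levels = [f_min]
    for j in range(1, n_runs):
        if j % 2 == 1:   # interior peak
            levels.append(f_min + frange * rng.uniform(0.55, 0.90))
        else:            # interior trough
            levels.append(f_min + frange * rng.uniform(0.12, 0.45))
    levels.append(f_max)
    # free random timing gives the shape variety (slow-fast-slow, plateaux,
    # step-like rises); a per-segment duration floor tied to the target sweep
    # rate keeps every slope physiological and traceable
    target_rate = 0.8 * MAX_SWEEP_RATE_HZ_S
    run_fracs = rng.dirichlet(np.full(n_runs, 5.0))
    spec: list[tuple[float, float, float]] = []  # (duration, f_a, f_b)
    for j in range(n_runs):
        a, b = levels[j], levels[j + 1]
        run_dur = duration * run_fracs[j]
        # split the monotone run into three segments at two random interior
        # levels and times, so even uninflected contours are individually
        # distinctive
        u = np.sort(rng.uniform(0.05, 0.95, size=2))
        knots = [a, a + (b - a) * u[0], a + (b - a) * u[1], b]
        tfracs = rng.dirichlet(np.full(3, 2.0))
        for (fa, fb, frac) in zip(knots[:-1], knots[1:], tfracs):
            # the 1.7 factor leaves room for the curvature term in the slope
            dur = max(run_dur * frac, 1.7 * abs(fb - fa) / target_rate, 1e-4)
            spec.append((dur, fa, fb))
    # duration floors can only lengthen the contour; keep them (rescaling
    # back down would reintroduce the steep slopes the floors prevent)
    segments = []
    for dur, fa, fb in spec:
        rise = fb - fa
        curv = rng.uniform(-0.7, 0.7) * abs(rise)
        segments.append(Segment(dur, fa, fb, curv))
    return ContourPrototype(identity, tuple(segments), n_loops, inter_loop_gap)


def _prototype_shape(p: ContourPrototype) -> tuple[np.ndarray, np.ndarray]:
    t, f = p.sample_loops(dt=0.005)[0]
    return t, f


def _prototype_shape_vec(p: ContourPrototype, n: int = 64) -> np.ndarray:
    t, f = p.sample_loops(dt=0.005)[0]
    return shape_vector(t, f, n)


def _vec_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def make_repertoire(site_profiles: pd.DataFrame, sw_per_site: int,
                    effects: EffectConfig | None = None, seed: int = 0,
                    n_loops_range: tuple[int, int] = (1, 3),
                    shape_margin: float = SHAPE_REJECT_MARGIN,
                    max_tries: int = 3000) -> SyntheticStudy:
    """Generate one distinct signature-whistle prototype per simulated identity.

    Prototype parameter means are shifted per :class:`EffectConfig`; an
    identity-level random intercept is added on top.  Candidate prototypes
    whose shape lies within ``shape_margin`` of an already-accepted prototype
    are redrawn, so identities are mutually distinguishable by the catalogue
    matcher (signature whistles are individually distinctive by definition).
    """
    if sw_per_site < 1:
        raise ValueError("sw_per_site must be >= 1")
    effects = effects or EffectConfig()
    effects.validate_levels(site_profiles)
    rng = np.random.default_rng(seed)
    prototypes: dict[str, ContourPrototype] = {}
    identity_site: dict[str, str] = {}
    accepted_shapes: list[np.ndarray] = []

    for site, profile in site_profiles.iterrows():
        d_fmin = (effects.shift_for(profile, "min_freq")
                  + effects.shift_for(profile, "start_freq"))
        d_fmax = (effects.shift_for(profile, "max_freq")
                  + effects.shift_for(profile, "end_freq")
                  + effects.shift_for(profile, "freq_range"))
        d_dur = effects.shift_for(profile, "duration")
        d_infl = effects.shift_for(profile, "n_inflections")
        for k in range(sw_per_site):
            identity = f"{site}-SW{k + 1:02d}"
            sd_extra = {p: effects.id_sd.get(p, 0.0) for p in PARAM_NAMES}
            for _ in range(max_tries):
                f_min = rng.normal(BASE_F_MIN[0] + d_fmin,
                                   np.hypot(BASE_F_MIN[1], sd_extra["min_freq"]))
                f_max = rng.normal(BASE_F_MAX[0] + d_fmin + d_fmax,
                                   np.hypot(BASE_F_MAX[1], sd_extra["max_freq"]))
                duration = rng.normal(BASE_DURATION[0] + d_dur,
                                      np.hypot(BASE_DURATION[1], sd_extra["duration"]))
                f_min = max(f_min, 1500.0)
                f_max = max(f_max, f_min + MIN_SEPARATION_HZ)
                duration = max(duration, 0.3)
                base_infl = rng.choice(INFLECTION_CHOICES, p=INFLECTION_PROBS)
                n_infl = int(base_infl + 2 * round((d_infl + rng.normal(0.0, sd_extra["n_inflections"])) / 2.0))
                n_infl = max(0, n_infl)
                n_loops = int(rng.integers(n_loops_range[0], n_loops_range[1] + 1))
                gap = rng.uniform(0.08, 0.22)
                cand = _draw_prototype(identity, f_min, f_max, duration,
                                       n_infl, n_loops, gap, rng)
                if cand.max_sweep_rate > MAX_SWEEP_RATE_HZ_S:
                    continue
                shape = _prototype_shape_vec(cand)
                if all(_vec_dist(shape, s) >= shape_margin for s in accepted_shapes):
                    prototypes[identity] = cand
                    identity_site[identity] = site
                    accepted_shapes.append(shape)
                    break
            else:
                raise GenerationError(
                    f"could not draw a distinct prototype for {identity} "
                    f"after {max_tries} tries (shape_margin={shape_margin})")
    return SyntheticStudy(site_profiles, prototypes, identity_site, effects, seed)


# ---------------------------------------------------------------------------
# session scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmitterSpec:
    """How one identity behaves in a session.

    Patterns
    --------
    ``"sw"``
        >= 4 units with inter-unit gaps of 1.5-8 s: satisfies both the
        repeated-element rule (two within 0.25-10 s) and the SIGID bout
        criterion (>= 4 units, >= 75% within 1-10 s of another).
    ``"rewt"``
        Repeated but not signature: with <= 3 units, gaps of 1.5-8 s
        (fails the "minimum of four"); with >= 4 units, sub-second gaps of
        0.3-0.8 s (repeated within 0.25-10 s but 0% within 1-10 s).
    ``"sparse"``
        Units >= 25 s apart: fails the repeated-element rule entirely.
    """

    identity: str
    pattern: str = "sw"
    n_units: int | None = None

    def resolved_units(self) -> int:
        if self.n_units is not None:
            return self.n_units
        return {"sw": 5, "rewt": 2, "sparse": 4}[self.pattern]


@dataclass(frozen=True)
class SessionConfig:
    duration: float = 600.0
    emitters: tuple[EmitterSpec, ...] = ()
    n_variant_whistles: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("session duration must be positive")


_GAPS = {"sw": (1.5, 8.0), "rewt_few": (1.5, 8.0), "rewt_dense": (0.3, 0.8),
         "sparse": (25.0, 40.0)}
_BLOCK_BUFFER = (12.0, 16.0)   # silence between emitter blocks, > 10 s


def sample_session(study: SyntheticStudy, config: SessionConfig, seed: int,
                   session_id: str = "S1") -> list[Emission]:
    """Schedule timed whistle emissions for one recording session.

    Emitter blocks are laid out sequentially with > 10 s of separation, so
    one identity's bout structure cannot alter another's classification.
    Raises :class:`GenerationError` when the requested schedule cannot fit
    into ``config.duration``.
    """
    rng = np.random.default_rng(seed)
    emissions: list[Emission] = []
    t = 0.0
    for spec in config.emitters:
        if spec.identity not in study.prototypes:
            raise ConfigurationError(f"unknown identity {spec.identity!r} in session config")
        proto = study.prototypes[spec.identity]
        n = spec.resolved_units()
        if spec.pattern == "sw":
            if n < 4:
                raise ConfigurationError("'sw' pattern needs n_units >= 4")
            gaps = _GAPS["sw"]
        elif spec.pattern == "rewt":
            gaps = _GAPS["rewt_few"] if n <= 3 else _GAPS["rewt_dense"]
            if n < 2:
                raise ConfigurationError("'rewt' pattern needs n_units >= 2")
        elif spec.pattern == "sparse":
            gaps = _GAPS["sparse"]
        else:
            raise ConfigurationError(f"unknown emission pattern {spec.pattern!r}")
        for k in range(n):
            emissions.append(Emission(session_id, spec.identity, t, proto, spec.pattern))
            t += proto.total_duration
            if k < n - 1:
                t += rng.uniform(*gaps)
        t += rng.uniform(*_BLOCK_BUFFER)
    # one-off variant whistles, each a unique throwaway type
    for k in range(config.n_variant_whistles):
        label = f"{session_id}-VAR{k + 1:02d}"
        for _ in range(500):
            f_min = rng.normal(*BASE_F_MIN)
            f_max = rng.normal(*BASE_F_MAX)
            f_min = max(f_min, 1500.0)
            f_max = max(f_max, f_min + MIN_SEPARATION_HZ)
            dur = max(rng.normal(*BASE_DURATION), 0.3)
            n_infl = int(rng.choice(INFLECTION_CHOICES, p=INFLECTION_PROBS))
            cand = _draw_prototype(label, f_min, f_max, dur, n_infl, 1, 0.15, rng)
            if cand.max_sweep_rate > MAX_SWEEP_RATE_HZ_S:
                continue
            others = ([_prototype_shape_vec(p) for p in study.prototypes.values()]
                      + [_prototype_shape_vec(e.prototype) for e in emissions
                         if e.kind == "variant"])
            cand_vec = _prototype_shape_vec(cand)
            if all(_vec_dist(cand_vec, s) >= SHAPE_REJECT_MARGIN for s in others):
                break
        else:
            raise GenerationError(f"could not draw a distinct variant whistle {label}")
        emissions.append(Emission(session_id, label, t, cand, "variant"))
        t += cand.total_duration + rng.uniform(*_BLOCK_BUFFER)
    if emissions and emissions[-1].t_end > config.duration:
        raise GenerationError(
            f"schedule needs {emissions[-1].t_end:.1f} s but session "
            f"duration is {config.duration:.1f} s")
    return emissions


def expected_labels(emissions: list[Emission]) -> dict[str, str]:
    """Independently re-derive SW / REWT / OW truth labels from a schedule.

    Applies the classification rules directly to the scheduled unit times
    (no contour matching involved): a whistle type is a repeated element
    (REWT) if two of its units fall within 0.25-10 s (end to start) in one
    session; it is a signature whistle (SW) if in some session it has at
    least four units of which at least 75% lie within 1-10 s of another.
    """
    by_key: dict[tuple[str, str], list[Emission]] = {}
    for e in emissions:
        by_key.setdefault((e.session_id, e.identity), []).append(e)
    rewt: set[str] = set()
    sw: set[str] = set()
    for (_, identity), ems in by_key.items():
        ems = sorted(ems, key=lambda e: e.t_start)
        n = len(ems)
        gaps = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(n):
                if i != j:
                    a, b = (ems[i], ems[j]) if ems[i].t_start <= ems[j].t_start else (ems[j], ems[i])
                    gaps[i, j] = max(b.t_start - a.t_end, 0.0)
        if n >= 2 and np.any((gaps >= 0.25) & (gaps <= 10.0)):
            rewt.add(identity)
        if n >= 4:
            nearest = gaps.min(axis=1)
            frac = np.mean((nearest >= 1.0) & (nearest <= 10.0))
            if frac >= 0.75:
                sw.add(identity)
    labels: dict[str, str] = {}
    for e in emissions:
        if e.identity in sw and e.identity in rewt:
            labels[e.identity] = "SW"
        elif e.identity in rewt:
            labels[e.identity] = "REWT"
        else:
            labels[e.identity] = "OW"
    return labels


def truth_table(emissions: list[Emission]) -> pd.DataFrame:
    """Emission truth table: session_id, identity, t_start, t_end, label."""
    labels = expected_labels(emissions)
    rows = [(e.session_id, e.identity, e.t_start, e.t_end,
             e.prototype.n_loops, labels[e.identity]) for e in emissions]
    return pd.DataFrame(rows, columns=["session_id", "identity", "t_start",
                                       "t_end", "n_loops", "label"])


# ---------------------------------------------------------------------------
# event-level realisation and audio rendering
# ---------------------------------------------------------------------------

def emission_contours(emissions: list[Emission], effects: EffectConfig | None = None,
                      seed: int = 0, dt: float = 0.005,
                      sample_jitter_hz: float = 0.0) -> list[WhistleContour]:
    """Realise scheduled emissions as event-level contours (one per loop).

    Per-emission residuals (whole-contour frequency offset, duration
    rescaling) follow ``effects.resid_sd``; ``sample_jitter_hz`` adds white
    per-sample frequency roughness emulating measurement noise.
    """
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    off_sd = float(effects.resid_sd.get("min_freq", 0.0))
    dur_sd = float(effects.resid_sd.get("duration", 0.0))
    out: list[WhistleContour] = []
    for e in emissions:
        f_off = rng.normal(0.0, off_sd) if off_sd > 0 else 0.0
        scale = 1.0
        if dur_sd > 0:
            scale = max(1.0 + rng.normal(0.0, dur_sd) / e.prototype.total_duration, 0.5)
        for t_loop, f_loop in e.prototype.sample_loops(dt):
            f = f_loop + f_off
            if sample_jitter_hz > 0:
                f = f + rng.normal(0.0, sample_jitter_hz, size=f.shape)
            f = np.maximum(f, 100.0)
            out.append(WhistleContour(e.session_id, e.t_start + t_loop * scale, f,
                                      grade=3, snr=np.inf, identity=e.identity))
    out.sort(key=lambda c: c.t_start)
    return out


def render_audio(emissions: list[Emission], sample_rate: int = 96000,
                 snr_db: float = 25.0, seed: int = 0,
                 amplitude: float = 0.3,
                 band: tuple[float, float] = (2000.0, 22000.0)) -> np.ndarray:
    """Render a session schedule to a waveform.

    Each loop becomes a frequency-modulated tone following its prototype
    trajectory (5 ms cosine on/off ramps); white Gaussian noise is added so
    that 20*log10(tonal RMS / broadband noise RMS within ``band``) equals
    ``snr_db``.  ``snr_db = -inf`` renders noise only.  Amplitude is bounded
    in [-1, 1].
    """
    nyquist = sample_rate / 2.0
    for e in emissions:
        if e.prototype.max_frequency >= nyquist:
            raise ValueError(
                f"prototype {e.prototype.identity!r} reaches "
                f"{e.prototype.max_frequency:.0f} Hz, >= Nyquist {nyquist:.0f} Hz")
    rng = np.random.default_rng(seed)
    duration = (max(e.t_end for e in emissions) + 1.0) if emissions else 1.0
    n = int(np.ceil(duration * sample_rate))
    wave = np.zeros(n)
    tonal = np.isfinite(snr_db)
    if tonal:
        for e in emissions:
            ld = e.prototype.loop_duration
            m = int(round(ld * sample_rate))
            tt = np.arange(m) / sample_rate
            f_inst = e.prototype.loop_frequency(tt)
            phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
            tone = amplitude * np.sin(phase)
            ramp = min(int(0.005 * sample_rate), m // 4)
            if ramp > 0:
                env = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
                tone[:ramp] *= env
                tone[-ramp:] *= env[::-1]
            for k in range(e.prototype.n_loops):
                start = int(round((e.t_start + k * (ld + e.prototype.inter_loop_gap))
                                  * sample_rate))
                stop = min(start + m, n)
                wave[start:stop] += tone[:stop - start]
    # white noise scaled to the requested in-band SNR
    tone_rms = amplitude / np.sqrt(2.0)
    band_frac = (min(band[1], nyquist) - band[0]) / nyquist
    if np.isfinite(snr_db):
        noise_band_rms = tone_rms / (10.0 ** (snr_db / 20.0))
        sigma = noise_band_rms / np.sqrt(band_frac)
    else:
        sigma = 0.01  # noise-only sentinel: fixed low-level background
    wave = wave + rng.normal(0.0, sigma, size=n)
    peak = np.max(np.abs(wave))
    if peak > 1.0:
        wave = wave / (peak * 1.01)
    return wave


def write_wav(path, wave: np.ndarray, sample_rate: int = 96000) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    data = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, sample_rate, (data * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# blocked feature table (for ordination / PCA structure checks)
# ---------------------------------------------------------------------------

def make_blocked_feature_table(n: int, seed: int = 0,
                               r: tuple[float, float, float] = (0.90, 0.85, 0.55)
                               ) -> pd.DataFrame:
    """Seven-parameter table with three independent correlated blocks.

    Mirrors the loading pattern seen in field data: {max_freq, end_freq}
    share the strongest latent factor, {min_freq, start_freq} a second, and
    {duration, n_inflections, freq_range} a weaker third (freq_range loading
    negatively), so the correlation-matrix eigenvalues order the blocks as
    the first, second and third principal component and leave the remaining
    four eigenvalues below 1.  ``r`` gives the per-block loadings.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 3))
    block = {"max_freq": 0, "end_freq": 0, "min_freq": 1, "start_freq": 1,
             "duration": 2, "n_inflections": 2, "freq_range": 2}
    sign = {p: (-1.0 if p == "freq_range" else 1.0) for p in PARAM_NAMES}
    scale = {"min_freq": 700, "max_freq": 900, "start_freq": 700, "end_freq": 900,
             "freq_range": 1500, "n_inflections": 1.2, "duration": 0.2}
    mean = {"min_freq": 5500, "max_freq": 13500, "start_freq": 5500, "end_freq": 13500,
            "freq_range": 8000, "n_inflections": 2.0, "duration": 0.9}
    cols = {}
    for j, p in enumerate(PARAM_NAMES):
        b = block[p]
        load = r[b]
        x = sign[p] * load * z[:, b] + rng.normal(size=n) * np.sqrt(1 - load * load)
        cols[p] = mean[p] + scale[p] * x
    return pd.DataFrame(cols, columns=list(PARAM_NAMES))
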