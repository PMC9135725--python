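"""Loop merging, contour matching, REWT cataloguing and SIGID classification.

The unit of analysis is the whistle unit: any single- or multi-loop whistle,
with loops (repetitions of the same element) separated by silent intervals
of strictly less than 250 ms.  Classification then proceeds in two passes,
mirroring catalogue-based field workflows:

1. Repeated element whistle types (REWT): a whistle type whose units occur
   at least twice within 0.25-10 s (end of one unit to start of the next)
   during a recording session.  All other types are variant "other
   whistles" (OW).
2. SIGID bout criterion: a REWT is a signature whistle (SW) if, in some
   session, at least four of its units occur and at least 75% of them lie
   within 1-10 s of at least one other.  Each SW receives a unique SW-ID,
   inherited by every matching unit study-wide.

Visual contour matching is replaced by a deterministic shape distance
(time-resampled, z-normalised RMS by default; DTW pluggable) with a
calibrated match threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigwhistle.contours import WhistleContour, shape_distance

log = logging.getLogger(__name__)

LOOP_GAP_S = 0.250           # loops closer than this belong to one unit (strict <)
REWT_WINDOW_S = (0.25, 10.0)  # closed interval, end-of-unit to start-of-next
SIGID_WINDOW_S = (1.0, 10.0)  # closed interval
SIGID_MIN_UNITS = 4
SIGID_MIN_FRACTION = 0.75     # compared with >= (3/4 qualifies)


@dataclass
class MatchParams:
    """Contour matching configuration."""

    resample_n: int = 64
    metric: str = "znorm_rms"
    threshold: float = 0.22

    def __post_init__(self) -> None:
        if self.resample_n < 8:
            raise ValueError("resample_n must be >= 8")
        if self.threshold <= 0:
            raise ValueError("match threshold must be positive")


@dataclass
class WhistleUnit:
    """A loop-merged whistle: the unit of analysis."""

    session_id: str
    contours: tuple[WhistleContour, ...]

    def __post_init__(self) -> None:
        if not self.contours:
            raise ValueError("a unit needs at least one contour")

    @property
    def t_start(self) -> float:
        return self.contours[0].t_start

    @property
    def t_end(self) -> float:
        return self.contours[-1].t_end

    @property
    def n_loops(self) -> int:
        return len(self.contours)

    @property
    def identity(self) -> str | None:
        return self.contours[0].identity

    def merged_samples(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (times, freqs) over all member loops."""
        t = np.concatenate([c.times for c in self.contours])
        f = np.concatenate([c.freqs for c in self.contours])
        return t, f

    def shape(self) -> tuple[np.ndarray, np.ndarray]:
        """Representative shape: the first (typically central-pattern) loop."""
        c = self.contours[0]
        return c.times, c.freqs

    def shape_vector(self, params: "MatchParams") -> np.ndarray:
        """Resampled, z-normalised shape vector (cached per parameterisation)."""
        key = (params.resample_n, params.metric)
        cache = getattr(self, "_shape_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_shape_cache", cache)
        if key not in cache:
            from sigwhistle.contours import resample_shape, znorm

            t, f = self.shape()
            cache[key] = znorm(resample_shape(t, f, params.resample_n))
        return cache[key]


@dataclass
class CatalogEntry:
    label: str
    prototype: WhistleUnit               # first unit assigned to the type
    status: str = "OW"                   # "OW" | "REWT" | "SW"
    sw_id: str | None = None
    unit_ids: list[int] = field(default_factory=list)
    session_ids: list[str] = field(default_factory=list)


@dataclass
class SignatureCatalog:
    """All whistle types of a study with their classification status."""

    entries: list[CatalogEntry]
    params: MatchParams
    assignments: pd.DataFrame  # one row per unit: unit_id, session_id, label, status, sw_id

    def entry(self, label: str) -> CatalogEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def sw_ids(self) -> list[str]:
        return [e.sw_id for e in self.entries if e.status == "SW"]


def merge_loops(contours: list[WhistleContour],
                gap_threshold: float = LOOP_GAP_S) -> list[WhistleUnit]:
    """Merge consecutive same-session contours separated by < ``gap_threshold``.

    The 250 ms default reflects the typical inter-loop interval; the
    comparison is strict, so a gap of exactly 250 ms separates two units.
    Overlapping contours are merged with a warning.  Idempotent and
    independent of input order (contours are sorted internally).
    """
    by_session: dict[str, list[WhistleContour]] = {}
    for c in contours:
        by_session.setdefault(c.session_id, []).append(c)
    units: list[WhistleUnit] = []
    for session_id in sorted(by_session):
        cs = sorted(by_session[session_id], key=lambda c: c.t_start)
        group: list[WhistleContour] = []
        for c in cs:
            if group and c.t_start - group[-1].t_end < gap_threshold:
                if c.t_start < group[-1].t_end:
                    log.warning("session %s: overlapping contours at t=%.3f merged",
                                session_id, c.t_start)
                group.append(c)
            else:
                if group:
                    units.append(WhistleUnit(session_id, tuple(group)))
                group = [c]
        if group:
            units.append(WhistleUnit(session_id, tuple(group)))
    units.sort(key=lambda u: (u.session_id, u.t_start))
    return units


def contour_distance(a: WhistleContour, b: WhistleContour,
                     params: MatchParams | None = None) -> float:
    """Shape distance between two contours (symmetric, shift-invariant)."""
    params = params or MatchParams()
    return shape_distance(a, b, n=params.resample_n, metric=params.metric)


def _unit_distance(a: WhistleUnit, b: WhistleUnit, params: MatchParams) -> float:
    if params.metric == "znorm_rms":
        xa, xb = a.shape_vector(params), b.shape_vector(params)
        return float(np.sqrt(np.mean((xa - xb) ** 2)))
    return shape_distance(a.shape(), b.shape(), n=params.resample_n,
                          metric=params.metric)


def unit_gap(a: WhistleUnit, b: WhistleUnit) -> float:
    """Non-negative end-to-start silent interval between two units."""
    if a.t_start <= b.t_start:
        return max(b.t_start - a.t_end, 0.0)
    return max(a.t_start - b.t_end, 0.0)


def build_rewt_catalog(units: list[WhistleUnit],
                       params: MatchParams | None = None) -> SignatureCatalog:
    """Group units into whistle types and mark repeated element types.

    Two passes: a first pass grows the catalogue greedily (a unit joins the
    nearest type within the match threshold, else founds a new type), then a
    second pass re-inspects every unit against the completed catalogue, so
    early units can move to a type founded later.  Ties break towards the
    earliest-created entry.  A type is REWT iff, in at least one session, two
    of its units have an end-to-start gap within 0.25-10 s; otherwise its
    units are variant whistles (OW).
    """
    params = params or MatchParams()
    units = sorted(units, key=lambda u: (u.session_id, u.t_start))
    entries: list[CatalogEntry] = []
    # pass 1: grow the catalogue
    for u in units:
        best, best_d = None, np.inf
        for e in entries:
            d = _unit_distance(u, e.prototype, params)
            if d < best_d:   # strict <: ties keep the earliest entry
                best, best_d = e, d
        if best is None or best_d > params.threshold:
            entries.append(CatalogEntry(label=f"W{len(entries) + 1:03d}", prototype=u))
    # pass 2: assign every unit to its nearest catalogued type
    assign: list[int] = []
    for u in units:
        dists = [_unit_distance(u, e.prototype, params) for e in entries]
        assign.append(int(np.argmin(dists)))
    for ei, e in enumerate(entries):
        e.unit_ids = [i for i, a in enumerate(assign) if a == ei]
        e.session_ids = sorted({units[i].session_id for i in e.unit_ids})
    # REWT rule, scoped per recording session
    for e in entries:
        e.status = "OW"
        for session_id in e.session_ids:
            us = [units[i] for i in e.unit_ids if units[i].session_id == session_id]
            if _has_pair_in_window(us, REWT_WINDOW_S):
                e.status = "REWT"
                break
    table = pd.DataFrame({
        "unit_id": range(len(units)),
        "session_id": [u.session_id for u in units],
        "t_start": [u.t_start for u in units],
        "t_end": [u.t_end for u in units],
        "n_loops": [u.n_loops for u in units],
        "label": [entries[a].label for a in assign],
        "status": [entries[a].status for a in assign],
        "sw_id": [None] * len(units),
    })
    return SignatureCatalog(entries, params, table)


def _has_pair_in_window(us: list[WhistleUnit], window: tuple[float, float]) -> bool:
    for i in range(len(us)):
        for j in range(i + 1, len(us)):
            g = unit_gap(us[i], us[j])
            if window[0] <= g <= window[1]:
                return True
    return False


def _sigid_holds(us: list[WhistleUnit]) -> bool:
    """The bout criterion for one type in one session."""
    n = len(us)
    if n < SIGID_MIN_UNITS:
        return False
    nearest = []
    for i in range(n):
        gaps = [unit_gap(us[i], us[j]) for j in range(n) if j != i]
        nearest.append(min(gaps))
    ok = sum(1 for g in nearest if SIGID_WINDOW_S[0] <= g <= SIGID_WINDOW_S[1])
    return ok / n >= SIGID_MIN_FRACTION


def classify_signature(catalog: SignatureCatalog,
                       units: list[WhistleUnit]) -> SignatureCatalog:
    """Apply the SIGID criterion to a REWT catalogue and assign SW-IDs.

    The criterion is evaluated per recording session; once a type qualifies
    in any session, all of its units study-wide inherit the SW-ID.
    """
    units = sorted(units, key=lambda u: (u.session_id, u.t_start))
    n_sw = 0
    for e in catalog.entries:
        if e.status != "REWT":
            continue
        for session_id in e.session_ids:
            us = [units[i] for i in e.unit_ids if units[i].session_id == session_id]
            if _sigid_holds(us):
                n_sw += 1
                e.status = "SW"
                e.sw_id = f"SW{n_sw:02d}"
                break
    table = catalog.assignments
    label_status = {e.label: e.status for e in catalog.entries}
    label_swid = {e.label: e.sw_id for e in catalog.entries}
    table["status"] = table["label"].map(label_status)
    table["sw_id"] = table["label"].map(label_swid)
    return catalog


def catalog_to_json(catalog: SignatureCatalog) -> str:
    import json

    payload = [{"label": e.label, "status": e.status, "sw_id": e.sw_id,
                "unit_ids": e.unit_ids, "session_ids": e.session_ids}
               for e in catalog.entries]
    return json.dumps(payload, indent=2)
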