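"""Measurement of the seven acoustic parameters of a whistle unit.

Parameters: minimum frequency, maximum frequency, start frequency, end
frequency, frequency range (max - min), number of inflection points (slope
sign changes of the contour) and duration.  Multi-loop units are measured
over the whole unit: frequency extrema across all loops, duration from the
start of the first loop to the end of the last (silent inter-loop gaps
included), inflection points counted within loops and summed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from sigwhistle.sigid import SignatureCatalog, WhistleUnit

PARAM_COLUMNS = ["min_freq", "max_freq", "start_freq", "end_freq",
                 "freq_range", "n_inflections", "duration"]


@dataclass(frozen=True)
class FeatureVector:
    """The seven acoustic parameters of one signature-whistle contour."""

    min_freq: float
    max_freq: float
    start_freq: float
    end_freq: float
    freq_range: float
    n_inflections: int
    duration: float
    sw_id: str | None = None
    site: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.min_freq <= self.start_freq <= self.max_freq
                and self.min_freq <= self.end_freq <= self.max_freq):
            raise ValueError("start/end frequencies must lie within [min, max]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_inflections < 0:
            raise ValueError("inflection count must be >= 0")


def count_inflections(freqs: np.ndarray, smoothing_window: int = 5) -> int:
    """Count slope sign changes of a (smoothed) frequency trajectory.

    The contour is smoothed with a centred moving average before
    differencing, because ridge quantisation creates spurious one-bin
    flips; zero-slope runs are ignored (a plateau between two rises is not
    an inflection).  Invariant to a uniform frequency offset.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size < 3:
        raise ValueError("need at least three samples to count inflections")
    w = min(smoothing_window, f.size)
    if w > 1:
        f = np.convolve(f, np.ones(w) / w, mode="valid")
    d = np.diff(f)
    signs = np.sign(d)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.sum(signs[:-1] * signs[1:] < 0))


def measure_features(unit: WhistleUnit, smoothing_window: int = 5,
                     per_loop: bool = False) -> FeatureVector | list[FeatureVector]:
    """Measure the seven parameters of a whistle unit.

    With ``per_loop=True`` each member loop is measured separately instead
    (occasionally useful for introductory/terminal-loop comparisons).
    """
    if per_loop:
        return [measure_features(WhistleUnit(unit.session_id, (c,)),
                                 smoothing_window) for c in unit.contours]
    t, f = unit.merged_samples()
    if f.size < 2:
        raise ValueError("degenerate unit: fewer than two contour samples")
    infl = sum(count_inflections(c.freqs, smoothing_window)
               for c in unit.contours if c.freqs.size >= 3)
    return FeatureVector(
        min_freq=float(f.min()),
        max_freq=float(f.max()),
        start_freq=float(f[0]),
        end_freq=float(f[-1]),
        freq_range=float(f.max() - f.min()),
        n_inflections=int(infl),
        duration=unit.t_end - unit.t_start,
        session_id=unit.session_id,
    )


def feature_table(units: list[WhistleUnit], catalog: SignatureCatalog,
                  site_of_session: dict[str, str] | None = None,
                  smoothing_window: int = 5) -> pd.DataFrame:
    """One row per signature-whistle contour: the analysis table for statistics.

    Only units assigned to SW types enter the table (variant and merely
    repeated whistles are not signature material).
    """
    units = sorted(units, key=lambda u: (u.session_id, u.t_start))
    table = catalog.assignments
    rows = []
    for _, rec in table[table["status"] == "SW"].iterrows():
        u = units[int(rec["unit_id"])]
        fv = measure_features(u, smoothing_window)
        d = asdict(fv)
        d["sw_id"] = rec["sw_id"]
        d["session_id"] = u.session_id
        d["site"] = (site_of_session or {}).get(u.session_id)
        rows.append(d)
    cols = ["sw_id", "site", "session_id"] + PARAM_COLUMNS
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
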