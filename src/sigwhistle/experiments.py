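"""Validation experiments: oracle sweeps, recovery suites and power studies.

These routines exercise the pipeline against independent oracles and known
ground truth at desk scale: brute-force enumeration of the classification
rules, schedule-truth recovery, exhaustive and null-calibration checks of
ANOSIM, mixed-model parameter recovery, and end-to-end detection of a
configured site effect.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigwhistle import sigid, stats, synth
from sigwhistle.contours import WhistleContour
from sigwhistle.features import feature_table
from sigwhistle.sigid import (MatchParams, WhistleUnit, build_rewt_catalog,
                              classify_signature, merge_loops)


# ---------------------------------------------------------------------------
# brute-force SIGID oracle
# ---------------------------------------------------------------------------

def brute_force_status(units: list[WhistleUnit], type_of: list[int],
                       rewt_window: tuple[float, float] = (0.25, 10.0),
                       sigid_window: tuple[float, float] = (1.0, 10.0),
                       min_units: int = 4, min_fraction: float = 0.75) -> list[str]:
    """Classification status per unit by direct enumeration.

    Independent of the catalogue implementation: given the true type index
    of each unit, enumerate every unit pair and gap window explicitly.
    """
    statuses = ["OW"] * len(units)
    keys = {(units[i].session_id, type_of[i]) for i in range(len(units))}
    type_status: dict[int, str] = {}
    for session_id, t in keys:
        idx = [i for i in range(len(units))
               if units[i].session_id == session_id and type_of[i] == t]
        ivs = [(units[i].t_start, units[i].t_end) for i in idx]
        rewt = False
        for (s1, e1), (s2, e2) in itertools.combinations(ivs, 2):
            if s1 <= s2:
                g = max(s2 - e1, 0.0)
            else:
                g = max(s1 - e2, 0.0)
            if rewt_window[0] <= g <= rewt_window[1]:
                rewt = True
        sw = False
        if len(ivs) >= min_units:
            n_ok = 0
            for a in range(len(ivs)):
                gaps = []
                for b in range(len(ivs)):
                    if a == b:
                        continue
                    (s1, e1), (s2, e2) = ivs[a], ivs[b]
                    gaps.append(max(s2 - e1, 0.0) if s1 <= s2 else max(s1 - e2, 0.0))
                if gaps and sigid_window[0] <= min(gaps) <= sigid_window[1]:
                    n_ok += 1
            if n_ok / len(ivs) >= min_fraction:
                sw = True
        if sw:
            type_status[t] = "SW"
        elif rewt and type_status.get(t) != "SW":
            type_status[t] = "REWT"
        elif t not in type_status:
            type_status[t] = "OW"
    for i in range(len(units)):
        statuses[i] = type_status[type_of[i]]
    return statuses


def _random_session_units(rng: np.random.Generator, shapes: list[tuple],
                          session_id: str, max_units: int = 20) -> tuple[list[WhistleUnit], list[int]]:
    """Random unit layout over a few whistle types with exact (noise-free) shapes."""
    n_units = int(rng.integers(2, max_units + 1))
    n_types = int(rng.integers(1, min(4, len(shapes)) + 1))
    type_of = rng.integers(0, n_types, size=n_units).tolist()
    # gaps straddle every rule boundary, but stay >= 0.26 s so loop merging
    # never fuses two scheduled units
    gap_bins = [(0.26, 0.9), (0.9, 1.1), (1.1, 9.0), (9.0, 11.0), (11.0, 30.0)]
    t = 0.0
    units = []
    for k in range(n_units):
        tt, ff = shapes[type_of[k]]
        contour = WhistleContour(session_id, tt + t, ff)
        units.append(WhistleUnit(session_id, (contour,)))
        lo, hi = gap_bins[int(rng.integers(0, len(gap_bins)))]
        t += (tt[-1] - tt[0]) + rng.uniform(lo, hi)
    return units, type_of


def sigid_oracle_sweep(n_sessions: int = 1000, seed: int = 0,
                       max_units: int = 20) -> int:
    """Compare catalogue classification with brute force; return disagreements.

    Each random session lays 2-20 noise-free units of 1-4 distinct whistle
    types with gaps straddling the 0.25 s, 1 s and 10 s rule boundaries.
    """
    rng = np.random.default_rng(seed)
    profiles = synth.default_site_profiles().iloc[:1]
    study = synth.make_repertoire(profiles, 4, seed=seed + 1,
                                  n_loops_range=(1, 1))
    shapes = [p.sample_loops(0.005)[0] for p in study.prototypes.values()]
    params = MatchParams()
    disagreements = 0
    for s in range(n_sessions):
        units, type_of = _random_session_units(rng, shapes, f"S{s}", max_units)
        catalog = classify_signature(build_rewt_catalog(units, params), units)
        got = list(catalog.assignments.sort_values("unit_id")["status"])
        expected = brute_force_status(units, type_of)
        if got != expected:
            disagreements += 1
    return disagreements


# ---------------------------------------------------------------------------
# schedule-truth recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    n_sessions: int
    label_accuracy: float       # per-unit SW/REWT/OW label accuracy
    sw_id_accuracy: float       # fraction of SW units assigned to the correct type
    exact: bool


def recovery_suite(n_sessions: int = 100, seed: int = 0,
                   freq_offset_sd: float = 0.0, duration_sd: float = 0.0,
                   sample_jitter_hz: float = 0.0) -> RecoveryResult:
    """Classify simulated sessions and score against schedule truth.

    With all noise terms zero the classification must be exact.  The jitter
    configuration used for robustness checks is a 150 Hz per-emission
    frequency offset, 0.04 s duration jitter and 60 Hz per-sample roughness.
    """
    rng = np.random.default_rng(seed)
    profiles = synth.default_site_profiles()
    effects = synth.EffectConfig(resid_sd={"min_freq": freq_offset_sd,
                                           "duration": duration_sd})
    study = synth.make_repertoire(profiles, 3, effects, seed=seed)
    params = MatchParams()
    n_correct_label = n_units_total = 0
    n_sw_correct = n_sw_total = 0
    exact = True
    sites = list(profiles.index)
    for s in range(n_sessions):
        site = sites[s % len(sites)]
        ids = study.identities_at(site)
        emitters = (synth.EmitterSpec(ids[0], "sw", 4 + s % 3),
                    synth.EmitterSpec(ids[1], "rewt", 2 + s % 2),
                    synth.EmitterSpec(ids[2], "sparse"))
        cfg = synth.SessionConfig(duration=900.0, emitters=emitters,
                                  n_variant_whistles=1)
        session_id = f"{site}-S{s}"
        ems = synth.sample_session(study, cfg, seed=int(rng.integers(2 ** 31)),
                                   session_id=session_id)
        truth = synth.expected_labels(ems)
        contours = synth.emission_contours(ems, effects,
                                           seed=int(rng.integers(2 ** 31)),
                                           sample_jitter_hz=sample_jitter_hz)
        units = merge_loops(contours)
        catalog = classify_signature(build_rewt_catalog(units, params), units)
        truth_sw = {i for i, lab in truth.items() if lab == "SW"}
        # majority catalogue label per true SW identity = its expected SW type
        for u, (_, rec) in zip(units, catalog.assignments.iterrows()):
            ident = u.identity
            n_units_total += 1
            if rec["status"] == truth[ident]:
                n_correct_label += 1
            else:
                exact = False
        sw_units = [(u, rec) for u, (_, rec) in
                    zip(units, catalog.assignments.iterrows())
                    if u.identity in truth_sw]
        type_of_ident: dict[str, str] = {}
        for u, rec in sw_units:
            type_of_ident.setdefault(u.identity, rec["label"])
        for u, rec in sw_units:
            n_sw_total += 1
            if rec["label"] == type_of_ident[u.identity] and rec["status"] == "SW":
                n_sw_correct += 1
    return RecoveryResult(n_sessions,
                          n_correct_label / n_units_total,
                          n_sw_correct / n_sw_total if n_sw_total else float("nan"),
                          exact)


# ---------------------------------------------------------------------------
# ANOSIM calibration
# ---------------------------------------------------------------------------

def anosim_type1_rate(n_datasets: int = 1000, n_per_group: int = 8,
                      n_groups: int = 2, n_perm: int = 199, seed: int = 0,
                      alpha: float = 0.05) -> float:
    """Empirical type-I error of the permutation test under a label-free null."""
    rng = np.random.default_rng(seed)
    n = n_per_group * n_groups
    labels = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    rejections = 0
    for i in range(n_datasets):
        x = rng.normal(size=(n, 4)) ** 2  # arbitrary null data, no group structure
        table = pd.DataFrame(x, index=[f"s{j}" for j in range(n)])
        dm = stats.bray_curtis(table, fourth_root=True)
        res = stats.anosim(dm, labels, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_datasets


# ---------------------------------------------------------------------------
# mixed-model parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class GlmmRecovery:
    mean_effect: float
    bias: float
    mean_intercept_sd: float
    mean_residual_sd: float
    n_replicates: int


def glmm_recovery(n_replicates: int = 200, n_groups: int = 150,
                  obs_per_group: int = 12, effect: float = 0.5,
                  intercept_sd: float = 1.0, residual_sd: float = 0.5,
                  seed: int = 0) -> GlmmRecovery:
    """Fit the random-intercept model on data with known parameters."""
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(n_groups), obs_per_group)
    fac = np.where(ids % 2 == 0, "A", "B")
    estimates, re_sds, res_sds = [], [], []
    for _ in range(n_replicates):
        b = rng.normal(0.0, intercept_sd, n_groups)[ids]
        y = effect * (fac == "B") + b + rng.normal(0.0, residual_sd, ids.size)
        df = pd.DataFrame({"y": y, "fac": fac, "sw_id": ids})
        res = stats.fit_glmm(df, "y", "fac")
        estimates.append(res.fixed_effects.loc["B", "Value"])
        re_sds.append(res.random_intercept_sd)
        res_sds.append(res.residual_sd)
    return GlmmRecovery(float(np.mean(estimates)), float(np.mean(estimates) - effect),
                        float(np.mean(re_sds)), float(np.mean(res_sds)), n_replicates)


def glmm_null_rejection_rate(n_replicates: int = 800, n_groups: int = 150,
                             obs_per_group: int = 12, intercept_sd: float = 1.0,
                             residual_sd: float = 0.5, seed: int = 0,
                             alpha: float = 0.05) -> float:
    """Rejection rate of the level-effect t-test when the true effect is zero."""
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(n_groups), obs_per_group)
    fac = np.where(ids % 2 == 0, "A", "B")
    rejections = 0
    for _ in range(n_replicates):
        b = rng.normal(0.0, intercept_sd, n_groups)[ids]
        y = b + rng.normal(0.0, residual_sd, ids.size)
        df = pd.DataFrame({"y": y, "fac": fac, "sw_id": ids})
        res = stats.fit_glmm(df, "y", "fac")
        if res.fixed_effects.loc["B", "p-value"] < alpha:
            rejections += 1
    return rejections / n_replicates


# ---------------------------------------------------------------------------
# end-to-end determinant detection
# ---------------------------------------------------------------------------

def _one_detection_replicate(shift_hz: float, sw_per_site: int, seed: int,
                             target_site: str = "LA") -> float:
    """Run simulate -> classify -> features -> PCA -> GLMM for one replicate.

    Returns the p-value of the target site's coefficient on the component
    aligned with minimum/start frequency.
    """
    profiles = synth.default_site_profiles()
    effects = synth.EffectConfig(
        shifts={"site": {target_site: {"min_freq": shift_hz}}} if shift_hz else {},
        resid_sd={"min_freq": 150.0, "duration": 0.03})
    study = synth.make_repertoire(profiles, sw_per_site, effects, seed=seed,
                                  n_loops_range=(1, 2))
    rng = np.random.default_rng(seed + 1)
    contours = []
    site_of_session = {}
    for site in profiles.index:
        ids = study.identities_at(site)
        session_id = f"{site}-R1"
        site_of_session[session_id] = site
        emitters = tuple(synth.EmitterSpec(i, "sw", 4) for i in ids)
        cfg = synth.SessionConfig(duration=3000.0, emitters=emitters)
        ems = synth.sample_session(study, cfg, seed=int(rng.integers(2 ** 31)),
                                   session_id=session_id)
        contours.extend(synth.emission_contours(
            ems, effects, seed=int(rng.integers(2 ** 31)), sample_jitter_hz=20.0))
    units = merge_loops(contours)
    catalog = classify_signature(build_rewt_catalog(units), units)
    features = feature_table(units, catalog, site_of_session)
    pca = stats.pca_reduce(features, kaiser=True)
    pc = stats.dominant_component(pca, ["min_freq", "start_freq"])
    scores = pca.scores[[pc]].copy()
    scores["sw_id"] = features["sw_id"].to_numpy()
    scores["site"] = features["site"].to_numpy()
    levels = [s for s in profiles.index if s != target_site]
    res = stats.fit_glmm(scores, pc, "site",
                         level_order=[levels[0]] + sorted(levels[1:] + [target_site]))
    return float(res.fixed_effects.loc[target_site, "p-value"])


def detection_experiment(n_replicates: int = 50, shift_hz: float = 700.0,
                         sw_per_site: int = 30, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Fraction of replicates in which the site effect is detected.

    ``shift_hz = 700`` equals one between-identity SD of the minimum/start
    frequency, applied to a single site; ``shift_hz = 0`` measures the
    false-positive rate of the same test under the null generator.
    """
    hits = 0
    for r in range(n_replicates):
        p = _one_detection_replicate(shift_hz, sw_per_site, seed + 1000 * r)
        if p < alpha:
            hits += 1
    return hits / n_replicates
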