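"""Multi-session repeatability experiments and CoV analysis.

Orchestrates the full pipeline (simulate -> reconstruct -> quantify) over a
scans-per-day x days design and computes the repeatability metrics of a
quantitative sodium MRI QA protocol:

* intra-day CoV: coefficient of variation of a vial's estimated
  concentration over the repeated scans of one day (reported per vial as the
  mean over days);
* inter-day CoV: CoV over the first scan of each day.

CoV = 100 * sample SD (n-1 denominator) / mean.  Values above 50% are
rendered as ">50.0" in formatted tables (raw values are preserved in the
machine-readable output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import acquisition as acq
from . import quantify, recon
from .config import RunConfig
from .phantom import build_phantom

__all__ = [
    "SessionResult",
    "RepeatabilityReport",
    "coefficient_of_variation",
    "format_cov",
    "run_session",
    "run_design",
    "repeatability_report",
    "fa_calibration",
]


@dataclass
class SessionResult:
    """Output of one simulated imaging session (one averaged acquisition)."""

    session_id: str
    day: int
    scan: int
    concentrations: dict[str, float]   # label -> estimated mM
    snr: float
    seed: int
    flip_angle: float
    noise_sigma: float
    amplitude_scale: float = 1.0
    shift_applied: tuple[int, int, int] = (0, 0, 0)
    calibration: quantify.CalibrationFit | None = None


@dataclass
class RepeatabilityReport:
    """Per-vial concentration summary and intra-/inter-day CoV tables."""

    summary: pd.DataFrame      # label, mean_mM, sd_mM, n_sessions
    intra_day: pd.DataFrame    # label, cov_percent (mean over days), n per day
    inter_day: pd.DataFrame    # label, cov_percent, n
    sessions: list[SessionResult] = field(default_factory=list)

    def formatted(self) -> pd.DataFrame:
        """Human-readable table with the >50% formatting rule applied."""
        out = self.summary[["label"]].copy()
        intra = self.intra_day.set_index("label")["cov_percent"]
        inter = self.inter_day.set_index("label")["cov_percent"]
        out["intra_day_cov"] = [format_cov(intra[l]) for l in out["label"]]
        out["inter_day_cov"] = [format_cov(inter[l]) for l in out["label"]]
        return out


def coefficient_of_variation(values) -> float:
    """CoV in percent: 100 * sample SD / mean.

    Requires n >= 2.  A zero mean makes the CoV undefined and returns NaN
    (flagged); a negative mean yields a negative CoV, which callers should
    treat as a flag that the estimate itself is unphysical.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CoV needs at least two values")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * values.std(ddof=1) / mean)


def format_cov(cov: float) -> str:
    """Render a CoV for reporting; values above 50% print as '>50.0'."""
    if math.isnan(cov):
        return "undefined"
    if cov > 50.0:
        return ">50.0"
    return f"{cov:.2f}"


def _session_seed(base_seed: int, day: int, scan: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(day, scan))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _day_amplitude_scale(config: RunConfig, day: int) -> float:
    """Deterministic per-day global intensity drift in +/- drift_percent."""
    if config.drift_percent == 0:
        return 1.0
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(9999, day))
    u = np.random.default_rng(ss).uniform(-1.0, 1.0)
    return float(1.0 + config.drift_percent / 100.0 * u)


class _PipelineCache:
    """Amortizes phantom rasterization and the noiseless forward model
    across sessions that share a configuration."""

    def __init__(self) -> None:
        self.phantom = None
        self.trajectory = None
        self.noiseless: dict[float, np.ndarray] = {}

    def prepare(self, config: RunConfig, flip_angle: float | None = None):
        fa = config.acq.flip_angle if flip_angle is None else flip_angle
        if self.phantom is None:
            self.phantom = build_phantom(config.phantom)
            self.trajectory = acq.build_trajectory(config.acq)
        if fa not in self.noiseless:
            params = replace(config.acq, flip_angle=fa)
            self.noiseless[fa] = acq.simulate_noiseless(
                self.phantom, self.trajectory, params,
                n_segments=config.recon.n_segments)
        return self.phantom, self.trajectory, self.noiseless[fa]


def run_session(config: RunConfig, seed: int, day: int = 0, scan: int = 0,
                flip_angle: float | None = None,
                reference_image: recon.ReconImage | None = None,
                cache: _PipelineCache | None = None) -> SessionResult:
    """One end-to-end simulated session: acquire, average, reconstruct,
    align (if a reference is given), calibrate, and quantify.

    Deterministic: the same config and seed give a bit-identical result.
    """
    cache = cache or _PipelineCache()
    phantom, trajectory, noiseless = cache.prepare(config, flip_angle)
    fa = config.acq.flip_angle if flip_angle is None else flip_angle
    params = replace(config.acq, flip_angle=fa)
    amplitude = _day_amplitude_scale(config, day)

    dataset = acq.simulate_kspace(
        phantom, trajectory, params, seed=seed,
        noise_sigma=config.noise_sigma, noiseless=noiseless,
        amplitude_scale=amplitude,
        session_id=f"day{day}_scan{scan}_seed{seed}")
    image = recon.grid_reconstruct(dataset, config.recon)

    shift = (0, 0, 0)
    if reference_image is not None:
        result = recon.align_translation(image, reference_image)
        image, shift = result.aligned, result.shift

    rois = quantify.place_rois(phantom, image)
    table = quantify.roi_statistics(image, rois)
    snr = quantify.measure_snr(image, rois)
    known = {f"L_{c:g}": c for c in config.calibration_concentrations}
    fit = quantify.fit_calibration(table, known)
    cmap = quantify.concentration_map(image, fit)
    estimates = quantify.estimate_vial_concentrations(cmap, rois)
    concentrations = dict(zip(estimates["label"], estimates["estimated_mM"]))

    return SessionResult(
        session_id=dataset.session_id, day=day, scan=scan,
        concentrations=concentrations, snr=snr, seed=seed, flip_angle=fa,
        noise_sigma=config.noise_sigma, amplitude_scale=amplitude,
        shift_applied=shift, calibration=fit)


def run_design(config: RunConfig,
               session_seeds: list[int] | None = None) -> list[SessionResult]:
    """Run the full days x scans-per-day design.

    Session seeds default to a deterministic derivation from ``config.seed``;
    an explicit flat list (ordered day-major) may be supplied instead.
    """
    cache = _PipelineCache()
    sessions = []
    reference = None
    i = 0
    for day in range(config.n_days):
        for scan in range(config.scans_per_day):
            if session_seeds is not None:
                seed = session_seeds[i]
            else:
                seed = _session_seed(config.seed, day, scan)
            result = run_session(config, seed, day=day, scan=scan,
                                 reference_image=reference, cache=cache)
            sessions.append(result)
            i += 1
    return sessions


def repeatability_report(sessions: list[SessionResult],
                         scans_per_day: int | None = None) -> RepeatabilityReport:
    """CoV tables from a completed session set (pure function; never
    re-runs simulations).

    Intra-day CoV per vial is the mean over days of the within-day CoV over
    scans; inter-day CoV is the CoV over the first scan of each day.
    Raises when the design is incomplete (a day missing scans).
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    days = sorted({s.day for s in sessions})
    by_day = {d: sorted([s for s in sessions if s.day == d],
                        key=lambda s: s.scan) for d in days}
    counts = {d: len(v) for d, v in by_day.items()}
    if scans_per_day is None:
        scans_per_day = max(counts.values())
    gaps = [d for d, c in counts.items() if c != scans_per_day]
    if gaps:
        raise ValueError(
            f"incomplete design: days {gaps} do not have {scans_per_day} scans")

    labels = list(sessions[0].concentrations)
    all_values = {l: np.array([s.concentrations[l] for s in sessions])
                  for l in labels}

    summary = pd.DataFrame({
        "label": labels,
        "mean_mM": [all_values[l].mean() for l in labels],
        "sd_mM": [all_values[l].std(ddof=1) for l in labels],
        "n_sessions": len(sessions),
    })

    intra_rows = []
    for l in labels:
        covs = [coefficient_of_variation(
            [s.concentrations[l] for s in by_day[d]]) for d in days]
        intra_rows.append({"label": l,
                           "cov_percent": float(np.mean(covs)),
                           "n_per_day": scans_per_day,
                           "n_days": len(days)})
    intra = pd.DataFrame(intra_rows)

    inter_rows = []
    firsts = [by_day[d][0] for d in days]
    for l in labels:
        inter_rows.append({"label": l,
                           "cov_percent": coefficient_of_variation(
                               [s.concentrations[l] for s in firsts]),
                           "n": len(firsts)})
    inter = pd.DataFrame(inter_rows)

    return RepeatabilityReport(summary=summary, intra_day=intra,
                               inter_day=inter, sessions=list(sessions))


def fa_calibration(config: RunConfig,
                   flip_angles=(10.0, 20.0, 30.0, 40.0, 50.0),
                   seed: int | None = None) -> tuple[pd.DataFrame, float]:
    """Flip-angle sweep: one session per FA at a fixed seed; returns the
    per-FA SNR table and the FA with the highest SNR.

    The same seed (hence the same noise realization) is used for every FA so
    the SNR ordering reflects the steady-state signal amplitude alone.
    """
    flip_angles = list(flip_angles)
    if not flip_angles:
        raise ValueError("need at least one flip angle")
    seed = config.seed if seed is None else seed
    cache = _PipelineCache()
    rows = []
    for fa in flip_angles:
        result = run_session(config, seed, flip_angle=fa, cache=cache)
        rows.append({"flip_angle": fa, "snr": result.snr,
                     "signal_mM_L77": result.concentrations.get("L_77")})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["snr"].idxmax(), "flip_angle"])
    return table, best
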