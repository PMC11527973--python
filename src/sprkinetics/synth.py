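"""Synthetic sensorgram generation with known ground truth.

Raw Biacore exports for fibril--small-molecule screens are essentially
never published, so this module emulates the acquisition: a dilution
series of 5-8 analyte concentrations injected in duplicate over an
immobilized-fibril surface ("full kinetics"), or up to five consecutive
injections followed by a single 10-minute dissociation ("single-cycle
kinetics", used when dissociation is too slow to regenerate the surface).
Gaussian instrument noise, slow baseline drift from fibril dissociation,
bulk refractive-index boxes and two artifact modes (signal jumps, signal
decrease during injection) can be layered on top of the exact forward
model.

The bundled preset bank carries one ground-truth two-component kinetic
model per fibril/analyte interaction of the source screen (amyloid-beta42,
K18-tau, full-length 2N4R-tau and alpha-synuclein fibrils versus LCO dyes,
lansoprazole and methylene blue); it is the only place where published
rate constants are transcribed, so recovery scoring never consults
anything but the emitted ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import (
    ASSOCIATION,
    BindingComponent,
    InjectionSchedule,
    KineticModel,
    Sensorgram,
    simulate_response,
)

__all__ = [
    "NoiseModel",
    "DriftModel",
    "ArtifactSpec",
    "ScenarioPreset",
    "GroundTruth",
    "generate_dataset",
    "preset_bank",
    "get_preset",
    "recovery_experiment",
    "RecoverySummary",
]

#: association segments are auto-sized to reach >=95% of Req, capped here (s)
ASSOCIATION_CAP_S = 600.0
#: dissociation durations: full-kinetics cycles and the single-cycle terminal phase
DISSOCIATION_FULL_S = 600.0
DISSOCIATION_SINGLE_CYCLE_S = 600.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian instrument noise (RU)."""

    sigma_RU: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_RU < 0:
            raise ValueError("sigma_RU must be >= 0")


@dataclass(frozen=True)
class DriftModel:
    """Slow downward baseline drift from dissociation of the fibrils.

    ``exponential``: baseline(t) = -amplitude * (1 - exp(-rate * t)),
    rate in s^-1.  ``linear``: baseline(t) = -rate * t (RU/s), clipped at
    -amplitude.  Both are monotone non-increasing and bounded by amplitude.
    """

    kind: Literal["exponential", "linear"] = "exponential"
    rate: float = 1e-4
    amplitude_RU: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_RU < 0:
            raise ValueError("amplitude_RU must be >= 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    def baseline(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            return -self.amplitude_RU * (1.0 - np.exp(-self.rate * t))
        if self.kind == "linear":
            return np.maximum(-self.rate * t, -self.amplitude_RU)
        raise ValueError(f"unknown drift kind {self.kind!r}")


@dataclass(frozen=True)
class ArtifactSpec:
    """Instrument artifact: a step ``jump`` of ``magnitude_RU`` at
    ``time_s``, or an ``injection_decrease`` (multiplicative exponential
    decay with ``decay_rate`` s^-1) over the association segment containing
    ``time_s``."""

    kind: Literal["jump", "injection_decrease"]
    time_s: float
    magnitude_RU: float = 0.0
    decay_rate: float = 0.0


def apply_artifact(
    response: np.ndarray,
    time_s: np.ndarray,
    schedule: InjectionSchedule,
    artifact: ArtifactSpec,
) -> np.ndarray:
    if not schedule.start_s <= artifact.time_s <= schedule.end_s:
        raise ValueError("artifact time outside schedule span")
    out = np.array(response, dtype=float)
    if artifact.kind == "jump":
        out[time_s >= artifact.time_s] += artifact.magnitude_RU
        return out
    if artifact.kind == "injection_decrease":
        seg = schedule.segments[
            int(schedule.segment_index(np.array([artifact.time_s]))[0])
        ]
        if seg.kind != ASSOCIATION:
            raise ValueError("injection_decrease artifact must target an injection")
        mask = (time_s >= seg.start_s) & (time_s < seg.end_s)
        out[mask] *= np.exp(-artifact.decay_rate * (time_s[mask] - seg.start_s))
        return out
    raise ValueError(f"unknown artifact kind {artifact.kind!r}")


def remove_artifact(
    response: np.ndarray,
    time_s: np.ndarray,
    schedule: InjectionSchedule,
    artifact: ArtifactSpec,
) -> np.ndarray:
    """Exact inverse of :func:`apply_artifact` for the ``jump`` mode."""
    if artifact.kind != "jump":
        raise ValueError("only jump artifacts are removable exactly")
    inverse = ArtifactSpec("jump", artifact.time_s, -artifact.magnitude_RU)
    return apply_artifact(response, time_s, schedule, inverse)


@dataclass(frozen=True)
class ScenarioPreset:
    """Named ground-truth scenario: kinetic model + acquisition design.

    Concentrations follow the usual screening rule of spanning roughly
    KD/10 to 10*KD (geometric series) around the slowest-dissociating
    component's KD.
    """

    name: str
    fibril: str
    ligand: str
    model: KineticModel
    surface: str = ""
    surface_density_RU: float = 1.0
    schedule_builder: Literal["full_kinetics", "single_cycle"] = "full_kinetics"
    n_concentrations: int = 5
    duplicates: int = 2
    sampling_rate_hz: float = 10.0
    #: equilibrium constants as printed in the source screen's kinetics
    #: table (M), per canonical component; reports always recompute KD from
    #: the rate constants instead of trusting these
    published_KD_M: tuple[float, ...] = ()
    flagged: bool = False
    #: canonical index of the component whose published KD disagrees with
    #: kd/ka (None when the transcription is consistent)
    flagged_component: int | None = None
    flag_note: str = ""

    def __post_init__(self) -> None:
        if not 5 <= self.n_concentrations <= 8:
            raise ValueError("n_concentrations must be within 5-8")
        if self.duplicates < 1:
            raise ValueError("duplicates must be >= 1")

    @property
    def reference_KD(self) -> float:
        """KD of component 1 (canonical slowest-kd component)."""
        return self.model.components[0].KD

    def concentration_series(self) -> np.ndarray:
        """Geometric dilution series KD/10 ... 10*KD of component 1."""
        kd = self.reference_KD
        n = self.n_concentrations
        if self.schedule_builder == "single_cycle":
            n = min(n, 5)
        return np.geomspace(kd / 10.0, kd * 10.0, n)


@dataclass(frozen=True)
class GroundTruth:
    """Generating model and provenance emitted alongside every dataset."""

    preset_name: str
    model: KineticModel
    seed: int
    sigma_RU: float
    t_assoc_s: float
    association_capped: bool
    concentrations_M: tuple[float, ...]


def _association_duration(model: KineticModel, c_med: float) -> tuple[float, bool]:
    """Duration for every component to reach >=95% of its Req at the median
    concentration: max_i ln(20)/(ka_i*c_med + kd_i), capped."""
    t95 = max(math.log(20.0) / (c.ka * c_med + c.kd) for c in model.components)
    if t95 > ASSOCIATION_CAP_S:
        return ASSOCIATION_CAP_S, True
    return t95, False


def generate_dataset(
    preset: ScenarioPreset,
    noise: NoiseModel,
    drift: DriftModel | None = None,
    artifacts: Sequence[ArtifactSpec] | None = None,
) -> tuple[list[Sensorgram], GroundTruth]:
    """Simulate a concentration series for ``preset`` and return the curves
    together with the exact generating model for recovery scoring.

    Deterministic for a fixed ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    concs = preset.concentration_series()
    c_med = float(np.median(concs))
    t_assoc, capped = _association_duration(preset.model, c_med)
    dt = 1.0 / preset.sampling_rate_hz
    curves: list[Sensorgram] = []

    if preset.schedule_builder == "single_cycle":
        schedule = InjectionSchedule.single_cycle(
            sorted(concs), t_assoc, DISSOCIATION_SINGLE_CYCLE_S
        )
        for rep in range(preset.duplicates):
            t = np.arange(schedule.start_s, schedule.end_s, dt)
            r = simulate_response(preset.model, schedule, t)
            r = _decorate(r, t, schedule, drift, artifacts, noise, rng)
            curves.append(
                Sensorgram(
                    t,
                    r,
                    schedule,
                    curve_id=f"{preset.name}/sc/rep{rep}",
                    concentration_M=None,
                    sampling_rate_hz=preset.sampling_rate_hz,
                )
            )
    else:
        for ci, conc in enumerate(concs):
            schedule = InjectionSchedule.full_kinetics(
                float(conc), t_assoc, DISSOCIATION_FULL_S
            )
            for rep in range(preset.duplicates):
                t = np.arange(schedule.start_s, schedule.end_s, dt)
                r = simulate_response(preset.model, schedule, t)
                r = _decorate(r, t, schedule, drift, artifacts, noise, rng)
                curves.append(
                    Sensorgram(
                        t,
                        r,
                        schedule,
                        curve_id=f"{preset.name}/c{ci}/rep{rep}",
                        concentration_M=float(conc),
                        sampling_rate_hz=preset.sampling_rate_hz,
                    )
                )

    truth = GroundTruth(
        preset_name=preset.name,
        model=preset.model,
        seed=noise.seed,
        sigma_RU=noise.sigma_RU,
        t_assoc_s=t_assoc,
        association_capped=capped,
        concentrations_M=tuple(float(c) for c in concs),
    )
    return curves, truth


def _decorate(r, t, schedule, drift, artifacts, noise, rng):
    if drift is not None:
        r = r + drift.baseline(t)
    for art in artifacts or ():
        r = apply_artifact(r, t, schedule, art)
    if noise.sigma_RU > 0:
        r = r + rng.normal(0.0, noise.sigma_RU, size=t.shape)
    return r


# ---------------------------------------------------------------------------
# preset bank
# ---------------------------------------------------------------------------

# Ground-truth kinetics per interaction (two site classes each), canonical
# order ascending kd: (ka / M^-1 s^-1, kd / s^-1, rmax / RU, published KD / M).
_BANK_SPEC = [
    # name, fibril, ligand, surface, density, comp1, comp2, flagged, note
    ("asyn_hs169", "aSyn", "HS-169", "CMD200M", 2940.0,
     (2.88e5, 2.54e-3, 16.3, 8.8e-9), (1.45e5, 4.18e-2, 45.4, 2.89e-7),
     False, ""),
    ("asyn_hs84", "aSyn", "HS-84", "CMD200M", 3400.0,
     (1.161e4, 5.45e-6, 22.5, 4.78e-10), (1.115e6, 6.02e-2, 42.2, 5.40e-8),
     False, ""),
    ("asyn_hftaa", "aSyn", "h-FTAA", "CMD200M", 3400.0,
     (1.62e5, 2.86e-3, 2.8, 1.77e-8), (1.11e5, 5.82e-2, 19.3, 5.23e-7),
     False, ""),
    ("asyn_qftaa", "aSyn", "q-FTAA", "CM5", 2940.0,
     (9.07e5, 1.52e-2, 26.7, 1.67e-7), (1.53e3, 7.05e-4, 60.9, 4.61e-7),
     True,
     "published KD of the fast component (1.67e-7 M) disagrees with kd/ka "
     "(1.68e-8 M), a likely exponent typo; KD is always recomputed from rates"),
    ("asyn_mb", "aSyn", "methylene blue", "CMD200M", 3400.0,
     (4.72e5, 8.34e-1, 39.0, 1.77e-6), (4.57e2, 1.71e-2, 107.0, 3.75e-5),
     False, ""),
    ("k18_hs84", "K18-tau", "HS-84", "CMD200M", 8280.0,
     (4.89e3, 2.21e-3, 35.3, 4.52e-7), (3.59e6, 6.33e0, 33.4, 1.76e-6),
     False, ""),
    ("k18_qftaa", "K18-tau", "q-FTAA", "CMD200M", 8280.0,
     (4.89e2, 3.14e-3, 47.9, 6.419e-6), (2.798e3, 5.85e-2, 32.1, 2.092e-5),
     False, ""),
    ("k18_hftaa", "K18-tau", "h-FTAA", "HC1500M", 9010.0,
     (5.32e1, 1.49e-4, 5968.0, 2.81e-6), (2.70e2, 3.02e-2, 900.0, 1.12e-4),
     False, ""),
    ("tau2n4r_hs169", "2N4R-tau", "HS-169", "ZC150D", 2900.0,
     (6.78e1, 1.64e-5, 2216.0, 2.41e-7), (1.12e4, 8.09e-3, 67.6, 7.23e-7),
     False, ""),
    ("tau2n4r_lansoprazole", "2N4R-tau", "lansoprazole", "ZC150D", 2900.0,
     (1.15e2, 1.74e-4, 2682.0, 1.51e-6), (5.03e3, 4.26e-2, 93.6, 8.47e-6),
     False, ""),
    ("abeta42_hs169", "Abeta42", "HS-169", "ZC150D", 1770.0,
     (1.20e2, 1.67e-5, 641.0, 1.39e-7), (5.79e2, 1.05e-2, 367.3, 1.82e-5),
     False, ""),
    ("abeta42_lansoprazole", "Abeta42", "lansoprazole", "ZC150D", 1770.0,
     (9.47e2, 1.63e-4, 383.0, 1.72e-7), (3.49e3, 3.81e-2, 98.9, 1.09e-5),
     False, ""),
]

#: interactions whose slowest component dissociates slower than this run as
#: single-cycle titrations (no regeneration possible between cycles)
_SINGLE_CYCLE_KD_MAX = 1e-4


def preset_bank() -> list[ScenarioPreset]:
    """The 12 bundled fibril/analyte scenarios with ground-truth kinetics."""
    bank = []
    for name, fibril, ligand, surface, density, c1, c2, flagged, note in _BANK_SPEC:
        # the published table lists components in no fixed order; sort each
        # (component, published KD) pair into canonical ascending-kd order
        rows = sorted((c1, c2), key=lambda r: r[1])
        model = KineticModel(tuple(BindingComponent(*r[:3]) for r in rows))
        published = tuple(r[3] for r in rows)
        flagged_component = None
        if flagged:
            flagged_component = max(
                range(len(rows)),
                key=lambda i: abs(model.components[i].KD / published[i] - 1.0),
            )
        slow = model.components[0].kd < _SINGLE_CYCLE_KD_MAX
        bank.append(
            ScenarioPreset(
                name=name,
                fibril=fibril,
                ligand=ligand,
                model=model,
                surface=surface,
                surface_density_RU=density,
                schedule_builder="single_cycle" if slow else "full_kinetics",
                published_KD_M=published,
                flagged=flagged,
                flagged_component=flagged_component,
                flag_note=note,
            )
        )
    return bank


def get_preset(name: str) -> ScenarioPreset:
    for p in preset_bank():
        if p.name == name:
            return p
    raise KeyError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------


@dataclass
class RecoverySummary:
    """Median/IQR relative errors of recovered rate constants per component."""

    preset_name: str
    n_replicates: int
    n_failed: int
    median_rel_err: dict  # {"ka": [per component], "kd": [...], "KD": [...]}
    iqr_rel_err: dict
    per_replicate_rel_err: dict  # same keys -> array (replicate, component)


def recovery_experiment(
    preset: ScenarioPreset,
    noise: NoiseModel,
    n_replicates: int,
    seed: int,
    fit_options=None,
) -> RecoverySummary:
    """Generate -> fit (at the generating order) -> compare, replicated.

    Scores only against the ground truth emitted by :func:`generate_dataset`;
    deterministic for a fixed seed.
    """
    from .fitting import FitOptions, FitProblem, global_fit

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    options = fit_options or FitOptions()
    rng = np.random.default_rng(seed)
    rel = {k: [] for k in ("ka", "kd", "KD")}
    n_failed = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        curves, truth = generate_dataset(
            preset, NoiseModel(noise.sigma_RU, seed=rep_seed)
        )
        problem = FitProblem(curves=curves, model_order=truth.model.order)
        try:
            result = global_fit(problem, options)
        except Exception:
            n_failed += 1
            continue
        if not result.converged:
            n_failed += 1
            continue
        fit_c = result.model.components
        true_c = truth.model.components
        rel["ka"].append([abs(f.ka / t.ka - 1) for f, t in zip(fit_c, true_c)])
        rel["kd"].append([abs(f.kd / t.kd - 1) for f, t in zip(fit_c, true_c)])
        rel["KD"].append([abs(f.KD / t.KD - 1) for f, t in zip(fit_c, true_c)])
    per_rep = {k: np.array(v) for k, v in rel.items()}
    med = {
        k: (np.median(v, axis=0).tolist() if v.size else [])
        for k, v in per_rep.items()
    }
    iqr = {
        k: (
            (np.percentile(v, 75, axis=0) - np.percentile(v, 25, axis=0)).tolist()
            if v.size
            else []
        )
        for k, v in per_rep.items()
    }
    return RecoverySummary(
        preset_name=preset.name,
        n_replicates=n_replicates,
        n_failed=n_failed,
        median_rel_err=med,
        iqr_rel_err=iqr,
        per_replicate_rel_err=per_rep,
    )
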