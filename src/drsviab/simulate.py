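"""Synthetic permittivity datasets emulating the porcine ischemia/reperfusion study.

The generator is anchored on the nine fitted tissue conditions (control,
1-6 h ischemia, and ischemia followed by reperfusion) whose double Cole-Cole
parameters were extracted from the in-vivo measurements, and on the probe
setup's stated measurement uncertainty: 1.7 % relative below 5 GHz, 3.5 %
from 5 GHz upward.  Condition differences enter only through these anchor
parameter sets; there is no biophysical simulation of edema or metabolite
transport.

Randomness is fully seeded: subject-level parameter perturbations and
per-measurement noise draw from independent streams keyed by
(seed, subject, case, hour, replicate), so adding subjects never perturbs
existing records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .colecole import (
    DEFAULT_ALPHA1,
    DEFAULT_ALPHA2,
    DEFAULT_EPS_INF,
    ColeColeParams,
    evaluate_model,
)
from .dataset import LabeledDataset, viability_label
from .spectra import FrequencyGrid, PermittivitySpectrum, SpecimenMeta, default_grid

__all__ = [
    "StateLibrary",
    "NoiseModel",
    "ExperimentDesign",
    "build_state_library",
    "params_at_time",
    "simulate_spectrum",
    "simulate_dataset",
    "TABLE_ANCHORS",
]

#: Fitted (delta_eps1, delta_eps2, tau1 [ps], tau2 [ps]) per tissue condition.
TABLE_ANCHORS: dict[str, tuple[float, float, float, float]] = {
    "Control": (20.21, 44.81, 825.30, 8.46),
    "I-1h": (19.48, 56.49, 675.20, 7.06),
    "I-4h": (18.99, 56.93, 655.82, 6.89),
    "I-5h": (15.48, 57.95, 574.18, 6.90),
    "I-6h": (15.08, 58.08, 529.70, 7.21),
    "I-3h-R-1h": (13.07, 44.32, 594.73, 8.69),
    "I-3h-R-3h": (13.70, 42.45, 724.48, 8.95),
    "I-4h-R-1h": (12.90, 43.41, 741.75, 8.94),
    "I-4h-R-3h": (21.12, 41.65, 1222.23, 8.95),
}


@dataclass(frozen=True)
class StateLibrary:
    """Map from tissue-condition label to Cole-Cole parameters."""

    entries: dict[str, ColeColeParams]

    def __post_init__(self):
        missing = set(TABLE_ANCHORS) - set(self.entries)
        if missing:
            raise ValueError(f"state library missing conditions: {sorted(missing)}")

    def __getitem__(self, label: str) -> ColeColeParams:
        return self.entries[label]


def build_state_library(overrides: dict[str, ColeColeParams] | None = None) -> StateLibrary:
    """Nine-condition library with the fitted strengths/times per condition.

    The in-vivo fits only report the two relaxation strengths and times; the
    remaining parameters default to eps_inf = 7.0 (the reported bound is
    "less than 10"), alpha1 = 0.10, alpha2 = 0.02.  ``overrides`` replaces
    whole entries.
    """
    entries = {
        label: ColeColeParams(
            eps_inf=DEFAULT_EPS_INF,
            delta_eps1=d1,
            delta_eps2=d2,
            tau1=t1 * 1e-12,
            tau2=t2 * 1e-12,
            alpha1=DEFAULT_ALPHA1,
            alpha2=DEFAULT_ALPHA2,
        )
        for label, (d1, d2, t1, t2) in TABLE_ANCHORS.items()
    }
    if overrides:
        for label, p in overrides.items():
            if not isinstance(p, ColeColeParams):
                raise TypeError("overrides must map labels to ColeColeParams")
            entries[label] = p
    return StateLibrary(entries)


#: Ischemia-branch anchors: elapsed ischemic hours -> condition label.
_ISCHEMIA_ANCHORS = [(1.0, "I-1h"), (4.0, "I-4h"), (5.0, "I-5h"), (6.0, "I-6h")]
#: Reperfusion-branch anchors per ischemic duration: reperfusion hours -> label.
_REPERFUSION_ANCHORS = {
    3.0: [(1.0, "I-3h-R-1h"), (3.0, "I-3h-R-3h")],
    4.0: [(1.0, "I-4h-R-1h"), (3.0, "I-4h-R-3h")],
}

_FIELDS = ("eps_inf", "delta_eps1", "delta_eps2", "tau1", "tau2", "alpha1", "alpha2")


def _interp_params(anchors, lib, t) -> ColeColeParams:
    """Per-parameter linear interpolation in elapsed time between anchors;
    clamped to the first/last anchor outside their span."""
    times = [a[0] for a in anchors]
    if t <= times[0]:
        return lib[anchors[0][1]]
    if t >= times[-1]:
        return lib[anchors[-1][1]]
    j = int(np.searchsorted(times, t))
    t0, l0 = anchors[j - 1]
    t1, l1 = anchors[j]
    if t == t0:
        return lib[l0]
    w = (t - t0) / (t1 - t0)
    p0, p1 = lib[l0], lib[l1]
    kw = {f: (1 - w) * getattr(p0, f) + w * getattr(p1, f) for f in _FIELDS}
    return ColeColeParams(**kw)


def params_at_time(
    lib: StateLibrary, phase: str, ischemia_h: float = 0.0, reperfusion_h: float = 0.0
) -> ColeColeParams:
    """Condition parameters at a given point of the 8-hour protocol.

    Anchored conditions are returned exactly; between anchors each of the
    seven parameters is interpolated linearly in elapsed time within the
    phase branch.  Reperfusion branches exist for 3 h and 4 h ischemic
    durations; other durations use the nearest branch (ties toward 3 h).
    """
    if ischemia_h < 0 or reperfusion_h < 0:
        raise ValueError("elapsed hours must be non-negative")
    if phase == "control":
        return lib["Control"]
    if phase == "ischemia":
        return _interp_params(_ISCHEMIA_ANCHORS, lib, ischemia_h)
    if phase == "reperfusion":
        branch_key = min(_REPERFUSION_ANCHORS, key=lambda k: (abs(k - ischemia_h), k))
        return _interp_params(_REPERFUSION_ANCHORS[branch_key], lib, reperfusion_h)
    raise ValueError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise with a band-dependent magnitude.

    eps' and eps'' are each scaled by (1 + z), z ~ N(0, sd) drawn
    independently per point, with sd = ``rel_sd_low`` below ``split_f`` and
    ``rel_sd_high`` at/above it.  ``subject_cv`` is the coefficient of
    variation of the per-subject lognormal parameter perturbation.
    """

    rel_sd_low: float = 0.017
    rel_sd_high: float = 0.035
    split_f: float = 5e9
    subject_cv: float = 0.05

    def __post_init__(self):
        for v in (self.rel_sd_low, self.rel_sd_high, self.subject_cv):
            if v < 0:
                raise ValueError("noise magnitudes must be non-negative")
        if self.split_f <= 0:
            raise ValueError("split frequency must be positive")

    def sd_per_point(self, f: np.ndarray) -> np.ndarray:
        return np.where(f < self.split_f, self.rel_sd_low, self.rel_sd_high)


def simulate_spectrum(
    p: ColeColeParams,
    grid: FrequencyGrid,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
    meta: SpecimenMeta | None = None,
) -> PermittivitySpectrum:
    """Forward-model spectrum with multiplicative band-dependent noise.

    Deterministic for a fixed rng state; eps'' is clipped at zero after
    noising.
    """
    eps = evaluate_model(p, grid)
    er, ei = eps.real.copy(), (-eps.imag).copy()
    if noise is not None and (noise.rel_sd_low > 0 or noise.rel_sd_high > 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        sd = noise.sd_per_point(grid.points)
        er = er * (1.0 + rng.normal(0.0, 1.0, size=len(grid)) * sd)
        ei = ei * (1.0 + rng.normal(0.0, 1.0, size=len(grid)) * sd)
        ei = np.clip(ei, 0.0, None)
        er = np.clip(er, np.finfo(float).tiny, None)
    return PermittivitySpectrum(grid, er, ei, meta)


# ---------------------------------------------------------------------------
# experiment schedule


@dataclass(frozen=True)
class CaseSchedule:
    """One protocol arm: hours of ischemia then reperfusion (8 h total)."""

    case_id: int
    ischemia_hours: int
    reperfusion_hours: int

    def phase_at(self, hour: int) -> tuple[str, float, float]:
        """(phase, ischemia_h, reperfusion_h) at measurement hour 1..8."""
        if self.case_id == 1:
            return ("control", 0.0, 0.0)
        if hour <= self.ischemia_hours:
            return ("ischemia", float(hour), 0.0)
        return ("reperfusion", float(self.ischemia_hours), float(hour - self.ischemia_hours))


DEFAULT_CASES = (
    CaseSchedule(1, 0, 0),   # control: 8 h normal perfusion
    CaseSchedule(2, 8, 0),   # 8 h warm full ischemia
    CaseSchedule(3, 3, 5),   # 3 h ischemia + 5 h reperfusion
    CaseSchedule(4, 4, 4),   # 4 h ischemia + 4 h reperfusion
)

#: Published per-phase measurement totals (control, ischemia, reperfusion).
DEFAULT_PHASE_TOTALS = {"control": 700, "ischemia": 1490, "reperfusion": 830}


@dataclass(frozen=True)
class ExperimentDesign:
    """Study layout: subjects, case schedules, replicates and phase totals.

    The published per-phase totals are explicit configuration rather than a
    product of the schedule, because they are not an exact multiple of
    subjects x hours x replicates; the generator pads or truncates replicates
    deterministically to hit them and records every adjustment in the
    dataset provenance log.
    """

    n_subjects: int = 8
    cases: tuple[CaseSchedule, ...] = DEFAULT_CASES
    reps_per_hour: int = 10
    hours: int = 8
    phase_totals: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_TOTALS)
    )

    def __post_init__(self):
        if self.n_subjects < 1 or self.reps_per_hour < 1 or self.hours < 1:
            raise ValueError("design counts must be positive")
        if any(v <= 0 for v in self.phase_totals.values()):
            raise ValueError("phase totals must be positive")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG stream keyed on (seed, *key)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def _perturbed_library(lib: StateLibrary, cv: float, seed: int, subject: int):
    """Per-subject multiplicative lognormal factors, one per parameter,
    shared across that subject's measurements."""
    if cv <= 0:
        return {}
    rng = _stream(seed, 101, subject)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma  # unit mean
    return {f: float(rng.lognormal(mu, sigma)) for f in _FIELDS}


def _apply_factors(p: ColeColeParams, factors: dict[str, float]) -> ColeColeParams:
    if not factors:
        return p
    kw = {f: getattr(p, f) * factors[f] for f in _FIELDS}
    # keep invariants under perturbation
    kw["eps_inf"] = max(kw["eps_inf"], 1.0)
    kw["alpha1"] = min(kw["alpha1"], 0.99)
    kw["alpha2"] = min(kw["alpha2"], 0.99)
    if kw["tau1"] <= kw["tau2"]:
        kw["tau1"], kw["tau2"] = kw["tau2"] * 1.001, kw["tau1"]
    return ColeColeParams(**kw)


def simulate_dataset(
    design: ExperimentDesign | None = None,
    lib: StateLibrary | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    grid: FrequencyGrid | None = None,
) -> LabeledDataset:
    """Simulate the full labeled experiment.

    Records are enumerated per (subject, case, hour, replicate) under the
    four-arm schedule; each phase is then padded (extra replicates cycling
    deterministically over that phase's slots) or truncated (highest
    replicate indices first) to hit ``design.phase_totals`` exactly.  The
    binary label is viable iff elapsed ischemic hours < 4; reperfusion
    records carry the ischemic duration that preceded reperfusion.
    """
    design = design or ExperimentDesign()
    lib = lib or build_state_library()
    noise = noise if noise is not None else NoiseModel()
    grid = grid or default_grid()
    provenance: list[str] = []

    # base slots per phase: (subject, case, hour)
    slots: dict[str, list[tuple[int, CaseSchedule, int]]] = {
        "control": [],
        "ischemia": [],
        "reperfusion": [],
    }
    for subj in range(design.n_subjects):
        for case in design.cases:
            for hour in range(1, design.hours + 1):
                phase, _, _ = case.phase_at(hour)
                slots[phase].append((subj, case, hour))

    records: list[tuple[int, CaseSchedule, int, int]] = []
    for phase, phase_slots in slots.items():
        target = design.phase_totals.get(phase, len(phase_slots) * design.reps_per_hour)
        base = [
            (subj, case, hour, rep)
            for (subj, case, hour) in phase_slots
            for rep in range(1, design.reps_per_hour + 1)
        ]
        if len(base) > target:
            base.sort(key=lambda r: (r[3], r[0], r[1].case_id, r[2]))
            base = sorted(base[:target], key=lambda r: (r[0], r[1].case_id, r[2], r[3]))
            provenance.append(
                f"phase {phase}: truncated {len(phase_slots) * design.reps_per_hour - target} "
                f"records (highest replicate indices) to reach total {target}"
            )
        elif len(base) < target:
            extra = target - len(base)
            add = []
            rep_offset = design.reps_per_hour
            i = 0
            while len(add) < extra:
                subj, case, hour = phase_slots[i % len(phase_slots)]
                add.append((subj, case, hour, rep_offset + 1 + i // len(phase_slots)))
                i += 1
            base = sorted(base + add, key=lambda r: (r[0], r[1].case_id, r[2], r[3]))
            provenance.append(
                f"phase {phase}: padded {extra} extra replicates (cycling over "
                f"subject/case/hour slots) to reach total {target}"
            )
        records.extend(base)

    subject_factors = {
        subj: _perturbed_library(lib, noise.subject_cv, seed, subj)
        for subj in range(design.n_subjects)
    }

    spectra, labels, groups = [], [], []
    # the CSV schema keys a spectrum by (subject, case, phase, hours,
    # replicate) and carries no measurement-hour column, so replicates are
    # renumbered uniquely within that key (control hours would otherwise
    # collide at ischemia_h = reperfusion_h = 0)
    group_counter: dict[tuple, int] = {}
    for subj, case, hour, rep in records:
        phase, isc_h, rep_h = case.phase_at(hour)
        p = params_at_time(lib, phase, isc_h, rep_h)
        p = _apply_factors(p, subject_factors[subj])
        gkey = (subj, case.case_id, phase, isc_h, rep_h)
        group_counter[gkey] = group_counter.get(gkey, 0) + 1
        meta = SpecimenMeta(
            subject_id=f"pig{subj + 1:02d}",
            case_id=case.case_id,
            phase=phase,
            ischemia_h=isc_h,
            reperfusion_h=rep_h,
            replicate=group_counter[gkey],
        )
        rng = _stream(seed, 202, subj, case.case_id, hour, rep)
        spectra.append(simulate_spectrum(p, grid, noise, rng, meta))
        labels.append(viability_label(isc_h))
        groups.append((meta.subject_id, case.case_id))

    return LabeledDataset(spectra, labels, groups, provenance)
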