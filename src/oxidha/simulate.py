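"""Synthetic SRM chromatograms with known ground truth.

The simulator produces the data the quantification pipeline consumes — one
time–intensity trace per transition — for calibration ladders, spiked
before/after-extraction recovery pairs and multi-day validation batches.
Peaks are exponentially modified Gaussians (EMG) at the expected retention
time of each transition; the integrated peak area is response_factor ×
concentration × recovery, scaled for qualitative transitions by the analyte's
qualitative/quantitative intensity ratio.  Baseline noise is additive
Gaussian (floored at zero counts) and area noise is multiplicative lognormal
with unit mean, so a stated CV is reproduced exactly in expectation.

Everything is deterministic given a seed: per-sample generators are spawned
from one :class:`numpy.random.SeedSequence`, so batches are reproducible
end-to-end and independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .srm import SRMMethod, SRMTransition, INTERNAL_STANDARDS

#: Default time grid: 0–10 min at 0.005 min spacing covers the printed
#: retention times (5.95–8.84 min) with margin and gives >=16 points across
#: a 4σ-wide peak at the default σ of 0.02 min.
DEFAULT_TIME_GRID = (0.0, 10.0, 0.005)

#: Default IS concentration in the injected extract (ng/µL): 10 µL of
#: 12.5 ng/µL standard brought to 100 µL of reconstituted extract.
DEFAULT_IS_CONCENTRATION = 1.25

#: Printed calibration ladders (ng/µL).
HPDOHE_LADDER = (10.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.1, 0.05, 0.025, 0.01)
HDOHE_LADDER = (
    4.0, 2.0, 1.0, 0.1, 0.05, 0.025, 0.01,
    0.005, 0.0025, 0.0012, 0.0006, 0.0003,
)

#: Default response factors (area counts·min per ng/µL).  Hydroperoxides are
#: detected roughly an order of magnitude less sensitively than hydroxides.
HDOHE_RESPONSE = 2.0e5
HPDOHE_RESPONSE = 2.0e4


@dataclass(frozen=True)
class PeakShape:
    """EMG peak: Gaussian core (σ) convolved with an exponential tail (τ).

    ``tailing_tau = 0`` degenerates to a pure Gaussian.  ``rt_apex`` is the
    center of the Gaussian component; with the default τ/σ ratio the true
    mode shifts by well under the retention-time matching tolerance.
    """

    rt_apex: float
    sigma: float = 0.02
    tailing_tau: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tailing_tau < 0:
            raise ValueError("tailing_tau must be >= 0")

    def profile(self, times: np.ndarray, area: float) -> np.ndarray:
        """Intensity profile integrating (over the real line) to ``area``."""
        if area == 0:
            return np.zeros_like(times)
        if self.tailing_tau == 0:
            pdf = stats.norm.pdf(times, loc=self.rt_apex, scale=self.sigma)
        else:
            k = self.tailing_tau / self.sigma
            pdf = stats.exponnorm.pdf(
                times, K=k, loc=self.rt_apex, scale=self.sigma
            )
        return area * pdf


@dataclass(frozen=True)
class SamplePlan:
    """Ground truth and noise model for one simulated injection.

    Concentrations are ng/µL in the injected extract.  ``response_factors``
    map analyte (and internal-standard) names to area per (ng/µL);
    ``qual_to_quant_ratio`` scales the qualitative transition's area;
    ``recovery_factor`` models extraction losses multiplicatively in [0, 1].
    """

    analyte_concentrations: Mapping[str, float]
    is_concentrations: Mapping[str, float] = field(
        default_factory=lambda: {
            name: DEFAULT_IS_CONCENTRATION for name in INTERNAL_STANDARDS
        }
    )
    response_factors: Mapping[str, float] = field(default_factory=dict)
    qual_to_quant_ratio: Mapping[str, float] | float = 0.5
    baseline_level: float = 0.0  # constant detector offset (counts)
    noise_sigma: float = 5.0
    area_cv: float = 0.0
    recovery_factor: Mapping[str, float] | float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in self.analyte_concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")
        if self.noise_sigma < 0 or self.area_cv < 0 or self.baseline_level < 0:
            raise ValueError("noise parameters must be >= 0")
        for r in self._as_map(self.recovery_factor).values():
            if not 0 <= r <= 1:
                raise ValueError("recovery_factor must lie in [0, 1]")

    @staticmethod
    def _as_map(value: Mapping[str, float] | float) -> Mapping[str, float]:
        return value if isinstance(value, Mapping) else {}

    def _lookup(
        self, value: Mapping[str, float] | float, analyte: str, default: float
    ) -> float:
        if isinstance(value, Mapping):
            return value.get(analyte, default)
        return value

    def response_factor(self, analyte: str) -> float:
        if analyte in self.response_factors:
            return self.response_factors[analyte]
        if analyte in INTERNAL_STANDARDS:
            return HDOHE_RESPONSE
        return HPDOHE_RESPONSE if "HpDoHE" in analyte else HDOHE_RESPONSE

    def true_area(self, transition: SRMTransition) -> float:
        """Noise-free expected peak area for one transition."""
        name = transition.analyte_id
        if transition.role == "internal_standard":
            conc = self.is_concentrations.get(name, 0.0)
            return self.response_factor(name) * conc
        conc = self.analyte_concentrations.get(name, 0.0)
        area = (
            self.response_factor(name)
            * conc
            * self._lookup(self.recovery_factor, name, 1.0)
        )
        if transition.role == "qualitative":
            area *= self._lookup(self.qual_to_quant_ratio, name, 0.5)
        return area


@dataclass(frozen=True)
class ChromatogramTrace:
    transition: SRMTransition
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self, sample_id: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": sample_id,
                "analyte_id": self.transition.analyte_id,
                "role": self.transition.role,
                "time_min": self.times,
                "intensity": self.intensities,
            }
        )


@dataclass(frozen=True)
class Sample:
    """One simulated injection: traces keyed by (analyte_id, role)."""

    sample_id: str
    plan: SamplePlan
    traces: Mapping[tuple[str, str], ChromatogramTrace]
    metadata: Mapping[str, float | int | str] = field(default_factory=dict)

    def trace(self, analyte_id: str, role: str) -> ChromatogramTrace:
        return self.traces[(analyte_id, role)]


def time_grid(
    grid: tuple[float, float, float] = DEFAULT_TIME_GRID,
) -> np.ndarray:
    start, stop, step = grid
    if step <= 0:
        raise ValueError("grid spacing must be positive")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def simulate_trace(
    plan: SamplePlan,
    transition: SRMTransition,
    shape: PeakShape | None = None,
    rng: np.random.Generator | int | None = None,
    grid: tuple[float, float, float] = DEFAULT_TIME_GRID,
) -> ChromatogramTrace:
    """Simulate one transition's chromatogram.

    An analyte absent from the plan (zero concentration) yields a blank
    trace containing only baseline noise.  Deterministic for a given
    generator state or integer seed.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(plan.seed if rng is None else rng)
    if shape is None:
        shape = PeakShape(rt_apex=transition.expected_rt)
    times = time_grid(grid)
    area = plan.true_area(transition)
    if area > 0 and plan.area_cv > 0:
        s = math.sqrt(math.log1p(plan.area_cv**2))
        area *= rng.lognormal(mean=-0.5 * s * s, sigma=s)
    signal = shape.profile(times, area) + plan.baseline_level
    if plan.noise_sigma > 0:
        signal = signal + rng.normal(0.0, plan.noise_sigma, size=times.shape)
    return ChromatogramTrace(transition, times, np.maximum(signal, 0.0))


def simulate_sample(
    plan: SamplePlan,
    method: SRMMethod,
    sample_id: str,
    rng: np.random.Generator | int | None = None,
    metadata: Mapping[str, float | int | str] | None = None,
    grid: tuple[float, float, float] = DEFAULT_TIME_GRID,
) -> Sample:
    """Simulate every transition of a method for one injection."""
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(plan.seed if rng is None else rng)
    traces = {
        (t.analyte_id, t.role): simulate_trace(plan, t, None, rng, grid)
        for t in method.transitions
    }
    return Sample(sample_id, plan, traces, dict(metadata or {}))


# --------------------------------------------------------------------------
# Study designs
# --------------------------------------------------------------------------

def calibration_series(
    method: SRMMethod,
    levels: Sequence[float],
    replicates: int = 5,
    template: SamplePlan | None = None,
    seed: int = 0,
) -> list[Sample]:
    """Calibration ladder: every analyte at each level, constant IS.

    One sample per (level, replicate); the default validation design uses
    8 levels × 5 replicates.  Level 0 produces analyte-free blanks usable
    for noise estimation.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if template is None:
        template = SamplePlan(analyte_concentrations={})
    analytes = method.analytes
    samples: list[Sample] = []
    children = np.random.SeedSequence(seed).spawn(len(levels) * replicates)
    i = 0
    for level in levels:
        for rep in range(1, replicates + 1):
            plan = replace(
                template,
                analyte_concentrations={a: level for a in analytes},
            )
            rng = np.random.default_rng(children[i])
            i += 1
            samples.append(
                simulate_sample(
                    plan,
                    method,
                    sample_id=f"cal_L{level:g}_R{rep}",
                    rng=rng,
                    metadata={"level": level, "replicate": rep},
                )
            )
    return samples


def recovery_scenario(
    plan: SamplePlan,
    method: SRMMethod,
    spike_level: float = 1.0,
    loss_factor: Mapping[str, float] | float = 1.0,
    seed: int = 0,
) -> tuple[Sample, Sample]:
    """Spiked before vs after extraction.

    The "before" sample applies ``loss_factor`` to the analyte response (the
    spike went through the extraction); the "after" sample does not.  The
    internal standards receive identical treatment in both, so the recovery
    read out by the pipeline equals the injected loss factor.
    """
    losses = (
        loss_factor
        if isinstance(loss_factor, Mapping)
        else {a: float(loss_factor) for a in method.analytes}
    )
    for name, lf in losses.items():
        if not 0 <= lf <= 1:
            raise ValueError(f"loss factor for {name} outside [0, 1]")
    concentrations = {a: spike_level for a in method.analytes}
    sq = np.random.SeedSequence(seed).spawn(2)
    before = simulate_sample(
        replace(
            plan,
            analyte_concentrations=concentrations,
            recovery_factor=dict(losses),
        ),
        method,
        "spiked_before",
        rng=np.random.default_rng(sq[0]),
        metadata={"spike": "before", "level": spike_level},
    )
    after = simulate_sample(
        replace(
            plan,
            analyte_concentrations=concentrations,
            recovery_factor=1.0,
        ),
        method,
        "spiked_after",
        rng=np.random.default_rng(sq[1]),
        metadata={"spike": "after", "level": spike_level},
    )
    return before, after


@dataclass(frozen=True)
class ValidationBatch:
    """Hierarchical noise design: days × replicates × concentration levels.

    ``area_scales[day, rep, level]`` holds the realized multiplicative effect
    (day effect × replicate noise) applied to analyte responses; the truth is
    recorded so parameter recovery can be checked.
    """

    levels: tuple[float, ...]
    day_effects: np.ndarray  # (days,)
    area_scales: np.ndarray  # (days, reps, levels)
    between_day_cv: float
    within_day_cv: float

    @property
    def days(self) -> int:
        return self.area_scales.shape[0]

    @property
    def replicates(self) -> int:
        return self.area_scales.shape[1]

    def measured_concentrations(self, level_index: int) -> np.ndarray:
        """Idealized measured concentrations (truth × area scale), (days, reps)."""
        return self.levels[level_index] * self.area_scales[:, :, level_index]


def _unit_mean_lognormal(
    rng: np.random.Generator, cv: float, size: tuple[int, ...] | int
) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def validation_design(
    days: int = 3,
    reps: int = 3,
    levels: Sequence[float] = (0.05, 0.5, 2.0),
    between_day_cv: float = 0.05,
    within_day_cv: float = 0.05,
    seed: int = 0,
) -> ValidationBatch:
    """Draw the multiplicative effects of a 3-day × 3-replicate validation.

    Day effects and replicate noise are unit-mean lognormal with the stated
    CVs; with both CVs zero every batch is identical.  The returned object
    can be combined with :func:`simulate_sample` (scaling response factors)
    or used directly at the area level for Monte-Carlo convergence checks.
    """
    if days < 1 or reps < 1 or not levels:
        raise ValueError("need >= 1 day, >= 1 replicate and >= 1 level")
    if between_day_cv < 0 or within_day_cv < 0:
        raise ValueError("CVs must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    day_effects = _unit_mean_lognormal(rng, between_day_cv, (days,))
    rep_noise = _unit_mean_lognormal(rng, within_day_cv, (days, reps, len(levels)))
    scales = day_effects[:, None, None] * rep_noise
    return ValidationBatch(
        tuple(float(l) for l in levels),
        day_effects,
        scales,
        between_day_cv,
        within_day_cv,
    )


# --------------------------------------------------------------------------
# Trace I/O
# --------------------------------------------------------------------------

def write_traces(samples: Iterable[Sample], path: str | Path) -> None:
    """Long-format CSV: sample_id, analyte_id, role, time_min, intensity."""
    frames = [
        trace.to_frame(sample.sample_id)
        for sample in samples
        for trace in sample.traces.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(
    path: str | Path, method: SRMMethod
) -> dict[str, dict[tuple[str, str], ChromatogramTrace]]:
    """Read a long-format trace CSV back into per-sample trace maps."""
    df = pd.read_csv(path)
    required = {"sample_id", "analyte_id", "role", "time_min", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace file must have columns {sorted(required)}")
    by_key: dict[str, dict[tuple[str, str], ChromatogramTrace]] = {}
    lookup = {(t.analyte_id, t.role): t for t in method.transitions}
    for (sample_id, analyte, role), grp in df.groupby(
        ["sample_id", "analyte_id", "role"], sort=False
    ):
        transition = lookup.get((analyte, role))
        if transition is None:
            raise ValueError(
                f"trace for unknown transition ({analyte}, {role})"
            )
        grp = grp.sort_values("time_min")
        by_key.setdefault(str(sample_id), {})[(analyte, role)] = (
            ChromatogramTrace(
                transition,
                grp["time_min"].to_numpy(float),
                grp["intensity"].to_numpy(float),
            )
        )
    return by_key
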