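"""Synthetic voltammetric sensor-array data with controllable structure.

Real electronic-tongue development measures pure analyte stocks with every
candidate electrode and later mixture designs with the selected array.
This module emulates those campaigns: each sensor is described by a
:class:`SensorResponseSpec` (cross-sensitivities, peak positions, baseline,
noise, drift), and a voltammogram is built as a baseline plus one Gaussian
anodic peak per analyte on the forward sweep, mirrored cathodic peaks on
the reverse sweep, Langmuir-type saturation, additive Gaussian noise, and
a linear drift in acquisition order.

The generator is deliberately phenomenological — it reproduces the
statistical structure the array-optimization method relies on
(differentiated cross-responses, redundancy, noise, drift), not the
electrochemical kinetics behind real cyclic voltammograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core_data import ArraySample, Dataset, PotentialProgram, ValidationError, Voltammogram

__all__ = [
    "AnalyteResponse",
    "SensorResponseSpec",
    "DesignSpec",
    "simulate_voltammogram",
    "default_array_specs",
    "tilted_factorial",
    "random_test_points",
    "simulate_selection_dataset",
    "simulate_mixture_dataset",
]

#: Default analytes: paracetamol, ascorbic acid, uric acid.
DEFAULT_ANALYTES = ("PA", "AA", "UA")

def _unit_norm(pattern: dict[str, float], target: float = 0.08) -> dict[str, float]:
    scale = target / float(np.linalg.norm(list(pattern.values())))
    return {k: v * scale for k, v in pattern.items()}


#: Default informative cross-sensitivity patterns (µA/µM).  The first
#: three follow published calibration slopes of ZnO-, Prussian blue- and
#: polypyrrole-modified composite electrodes toward PA/AA/UA; the fourth
#: is a flat (unselective) noble-metal-like pattern.  All are normalized
#: to a common slope-vector norm so every informative unit carries a
#: comparable share of the array's discriminating power — required for a
#: well-posed selection-recovery ground truth.
_INFORMATIVE_PATTERNS: list[tuple[str, dict[str, float]]] = [
    ("ZnO", _unit_norm({"PA": 0.0598, "AA": 0.0152, "UA": 0.0452})),
    ("PB", _unit_norm({"PA": 0.0629, "AA": 0.0261, "UA": 0.0499})),
    ("PPy", _unit_norm({"PA": 0.0857, "AA": 0.0304, "UA": 0.0668})),
    ("Pt", _unit_norm({"PA": 0.053, "AA": 0.029, "UA": 0.055})),
]

#: Nominal anodic peak potentials (V vs. reference) per analyte.
_PEAK_POTENTIALS = {"PA": 0.39, "AA": 0.01, "UA": 0.30}


@dataclass(frozen=True)
class AnalyteResponse:
    """One sensor's response parameters toward a single analyte."""

    sensitivity: float  # µA/µM (peak height per unit concentration)
    peak_potential_V: float
    peak_width_V: float = 0.15
    cathodic_rel: float = 0.5  # reverse-branch peak magnitude relative to anodic
    cathodic_shift_V: float = 0.06  # cathodic peak sits at E0 - shift

    def __post_init__(self) -> None:
        if self.sensitivity < 0:
            raise ValidationError(f"sensitivity must be >= 0, got {self.sensitivity}")
        if not self.peak_width_V > 0:
            raise ValidationError(f"peak_width_V must be > 0, got {self.peak_width_V}")


@dataclass(frozen=True)
class SensorResponseSpec:
    """Full response model of one sensor in the array.

    ``k_sat_uM`` is the Langmuir-type half-saturation constant: the peak
    amplitude for concentration ``c`` is ``sensitivity * c * K/(K + c)``;
    ``math.inf`` gives a strictly linear response.  ``drift_per_sample_uA``
    adds a constant current offset proportional to the sample's
    acquisition index, emulating slow sensor drift over a session.
    ``response_rel_sd`` is the relative standard deviation of the peak
    amplitude between repeated measurements (electrode surface state
    fluctuation) — it makes replicate scatter proportional to signal, as
    observed with real composite electrodes.
    """

    sensor_id: str
    responses: Mapping[str, AnalyteResponse]
    baseline_slope_uA_per_V: float = 1.0
    baseline_offset_uA: float = 0.0
    k_sat_uM: float = math.inf
    noise_sd_uA: float = 0.0
    drift_per_sample_uA: float = 0.0
    response_rel_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_uA < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd_uA}")
        if self.response_rel_sd < 0:
            raise ValidationError(
                f"response_rel_sd must be >= 0, got {self.response_rel_sd}"
            )
        if not self.k_sat_uM > 0:
            raise ValidationError(f"k_sat_uM must be > 0, got {self.k_sat_uM}")


@dataclass(frozen=True)
class DesignSpec:
    """Concentration-design specification for mixture experiments.

    Bounds default to the linear ranges established for the three model
    analytes: 0–500 µM for paracetamol and uric acid, 0–2000 µM for
    ascorbic acid.
    """

    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    low_uM: tuple[float, ...] = (0.0, 0.0, 0.0)
    high_uM: tuple[float, ...] = (500.0, 2000.0, 500.0)
    levels_per_factor: int = 3
    tilt_fraction: float = 0.15
    n_random_test: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.analytes) == len(self.low_uM) == len(self.high_uM)):
            raise ValidationError("analytes, low_uM and high_uM must align")
        for lo, hi in zip(self.low_uM, self.high_uM):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValidationError(f"invalid bounds ({lo}, {hi})")
        if self.levels_per_factor < 2:
            raise ValidationError("levels_per_factor must be >= 2")
        if not 0 <= self.tilt_fraction < 0.5:
            raise ValidationError("tilt_fraction must lie in [0, 0.5)")


def _gauss(E: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((E - center) / width) ** 2)


def simulate_voltammogram(
    spec: SensorResponseSpec,
    concentrations: Mapping[str, float],
    program: PotentialProgram,
    rng: np.random.Generator | None = None,
    sample_index: int = 0,
) -> Voltammogram:
    """Synthesize one sensor's cyclic voltammogram for given concentrations.

    The current is a linear baseline plus, per analyte, a Gaussian anodic
    peak on the forward branch and a mirrored (negative) cathodic peak on
    the reverse branch, with amplitude ``sensitivity * c * K/(K + c)``
    (linear when ``K`` is infinite), plus N(0, noise_sd) noise and
    ``drift_per_sample * sample_index``.
    """
    for analyte in spec.responses:
        if analyte not in concentrations:
            raise ValidationError(
                f"concentration for analyte {analyte!r} missing "
                f"(sensor {spec.sensor_id!r})"
            )
    for analyte, c in concentrations.items():
        if c < 0:
            raise ValidationError(f"negative concentration {c} for {analyte!r}")
    if (spec.noise_sd_uA > 0 or spec.response_rel_sd > 0) and rng is None:
        raise ValidationError("an rng is required when the spec is stochastic")

    E = program.potentials()
    fwd = program.forward_mask()
    current = spec.baseline_offset_uA + spec.baseline_slope_uA_per_V * E
    for analyte, resp in spec.responses.items():
        c = float(concentrations.get(analyte, 0.0))
        if math.isinf(spec.k_sat_uM):
            amp = resp.sensitivity * c
        else:
            amp = resp.sensitivity * c * spec.k_sat_uM / (spec.k_sat_uM + c)
        if spec.response_rel_sd > 0:
            amp *= 1.0 + rng.normal(0.0, spec.response_rel_sd)
        if amp == 0.0:
            continue
        anodic = amp * _gauss(E, resp.peak_potential_V, resp.peak_width_V)
        current = current + np.where(fwd, anodic, 0.0)
        if resp.cathodic_rel:
            cathodic = (
                resp.cathodic_rel
                * amp
                * _gauss(E, resp.peak_potential_V - resp.cathodic_shift_V, resp.peak_width_V)
            )
            current = current - np.where(fwd, 0.0, cathodic)
    if spec.noise_sd_uA > 0:
        current = current + rng.normal(0.0, spec.noise_sd_uA, size=E.size)
    if spec.drift_per_sample_uA:
        current = current + spec.drift_per_sample_uA * sample_index
    return Voltammogram(spec.sensor_id, E, current)


def default_array_specs(
    n_informative: int = 4,
    n_redundant: int = 2,
    n_noisy: int = 2,
    seed: int = 0,
    analytes: Sequence[str] = DEFAULT_ANALYTES,
) -> tuple[list[SensorResponseSpec], dict[str, str]]:
    """Build a seeded sensor array with known ground-truth roles.

    Informative sensors carry distinct cross-sensitivity patterns of
    comparable overall magnitude, differentiated mainly through their
    voltammetric profiles (per-sensor peak-position and width jitter),
    with moderate additive noise and negligible drift.  Redundant sensors
    are scaled copies of an informative one burdened with strong session
    drift; noisy sensors have near-zero sensitivities, large additive
    noise and strong drift.  Returns the spec list together with a
    ``sensor_id -> role`` map (``"informative" | "redundant" | "noisy"``)
    for selection-recovery experiments.
    """
    if n_informative < 1:
        raise ValidationError("need at least one informative sensor")
    if n_redundant < 0 or n_noisy < 0:
        raise ValidationError("sensor counts must be >= 0")
    rng = np.random.default_rng(seed)
    analytes = list(analytes)

    def jittered_responses(pattern: Mapping[str, float]) -> dict[str, AnalyteResponse]:
        out = {}
        for a in analytes:
            e0 = _PEAK_POTENTIALS.get(a, 0.2) + rng.uniform(-0.15, 0.15)
            width = 0.16 * (1.0 + rng.uniform(-0.15, 0.15))
            sens = float(pattern.get(a, 0.0)) * (1.0 + rng.uniform(-0.1, 0.1))
            out[a] = AnalyteResponse(
                sensitivity=sens,
                peak_potential_V=float(e0),
                peak_width_V=float(width),
            )
        return out

    specs: list[SensorResponseSpec] = []
    roles: dict[str, str] = {}
    informative: list[SensorResponseSpec] = []
    for i in range(n_informative):
        if i < len(_INFORMATIVE_PATTERNS) and set(analytes) == set(
            _INFORMATIVE_PATTERNS[i][1]
        ):
            name, pattern = _INFORMATIVE_PATTERNS[i]
        else:
            name = f"inf{i + 1}"
            pattern = _unit_norm({a: float(rng.uniform(0.2, 1.0)) for a in analytes})
        spec = SensorResponseSpec(
            sensor_id=name,
            responses=jittered_responses(pattern),
            baseline_slope_uA_per_V=float(rng.uniform(0.5, 2.0)),
            baseline_offset_uA=float(rng.uniform(-1.0, 1.0)),
            noise_sd_uA=0.2,
            drift_per_sample_uA=0.005,
        )
        specs.append(spec)
        informative.append(spec)
        roles[name] = "informative"

    for i in range(n_redundant):
        parent = informative[i % n_informative]
        responses = {
            a: replace(r, sensitivity=r.sensitivity * 0.7)
            for a, r in parent.responses.items()
        }
        name = f"red{i + 1}_{parent.sensor_id}"
        specs.append(
            SensorResponseSpec(
                sensor_id=name,
                responses=responses,
                baseline_slope_uA_per_V=parent.baseline_slope_uA_per_V,
                baseline_offset_uA=parent.baseline_offset_uA,
                noise_sd_uA=0.2,
                drift_per_sample_uA=0.5,
            )
        )
        roles[name] = "redundant"

    for i in range(n_noisy):
        name = f"noise{i + 1}"
        pattern = {a: float(rng.uniform(0.0, 0.001)) for a in analytes}
        specs.append(
            SensorResponseSpec(
                sensor_id=name,
                responses=jittered_responses(pattern),
                baseline_slope_uA_per_V=float(rng.uniform(0.5, 2.0)),
                baseline_offset_uA=float(rng.uniform(-1.0, 1.0)),
                noise_sd_uA=2.0,
                drift_per_sample_uA=0.5,
            )
        )
        roles[name] = "noisy"
    return specs, roles


# Irrational multipliers (fractional parts of square roots of primes) used
# to derive deterministic per-point tilt offsets in [-1, 1].
_TILT_IRRATIONALS = [math.sqrt(p) % 1.0 for p in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)]


def tilted_factorial(design: DesignSpec) -> np.ndarray:
    """Full-factorial concentration grid with deterministic per-point tilt.

    Base levels are equispaced on each factor's range; point ``p``'s level
    for factor ``f`` is then offset by ``tilt_fraction * spacing * u``
    where ``u = 2*frac((p+1)*alpha_f) - 1`` is an index-derived value in
    [-1, 1] (irrational rotation, so no two points share an exact level
    when ``tilt_fraction > 0``).  Outputs are clipped to the bounds.
    Returns an ``(levels**n_factors) x n_factors`` array in µM, columns in
    ``design.analytes`` order.
    """
    d = len(design.analytes)
    L = design.levels_per_factor
    lows = np.asarray(design.low_uM, dtype=float)
    highs = np.asarray(design.high_uM, dtype=float)
    spacing = (highs - lows) / (L - 1)

    # enumerate the grid with the last factor varying fastest
    idx = np.stack(
        np.meshgrid(*[np.arange(L)] * d, indexing="ij"), axis=-1
    ).reshape(-1, d)
    base = lows + idx * spacing
    if design.tilt_fraction > 0:
        p = np.arange(base.shape[0], dtype=float)[:, None]
        alpha = np.array(_TILT_IRRATIONALS[:d])[None, :]
        u = 2.0 * (((p + 1.0) * alpha) % 1.0) - 1.0
        base = base + design.tilt_fraction * spacing * u
    return np.clip(base, lows, highs)


def random_test_points(design: DesignSpec) -> np.ndarray:
    """Seeded i.i.d. uniform concentration vectors within the design bounds."""
    rng = np.random.default_rng(design.seed)
    lows = np.asarray(design.low_uM, dtype=float)
    highs = np.asarray(design.high_uM, dtype=float)
    return rng.uniform(lows, highs, size=(design.n_random_test, len(design.analytes)))


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_selection_dataset(
    specs: Sequence[SensorResponseSpec],
    program: PotentialProgram | None = None,
    analytes: Sequence[str] | None = None,
    stock_uM: float = 250.0,
    n_replicates: int = 5,
    include_buffer: bool = True,
    seed: int = 0,
) -> Dataset:
    """Replicate single-analyte stock measurements for array selection.

    Emulates measuring ``n_replicates`` replicate samples of one stock
    solution per analyte (plus buffer blanks) with every sensor.  Samples
    are ordered in interleaved acquisition rounds (one replicate of every
    class per round), so per-sample drift inflates within-class scatter
    the way session drift does in practice.
    """
    if not stock_uM > 0:
        raise ValidationError("stock_uM must be > 0")
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    program = program or PotentialProgram()
    if analytes is None:
        analytes = list(dict.fromkeys(a for s in specs for a in s.responses))
    classes = list(analytes) + (["buffer"] if include_buffer else [])
    rng = np.random.default_rng(seed)

    spec_analytes = {a for s in specs for a in s.responses}
    samples: list[ArraySample] = []
    acq_index = 0
    for rep in range(n_replicates):
        for label in classes:
            conc = {a: (stock_uM if a == label else 0.0) for a in analytes}
            full_conc = {**{a: 0.0 for a in spec_analytes}, **conc}
            vgrams = {
                spec.sensor_id: simulate_voltammogram(
                    spec, full_conc, program, rng=rng, sample_index=acq_index
                )
                for spec in specs
            }
            samples.append(
                ArraySample(
                    sample_id=f"{label}_r{rep + 1}",
                    class_label=label,
                    concentrations=conc,
                    voltammograms=vgrams,
                    replicate_index=rep + 1,
                )
            )
            acq_index += 1
    return Dataset(
        samples=samples,
        sensor_roster=[s.sensor_id for s in specs],
        analytes=list(analytes),
    )


def simulate_mixture_dataset(
    specs: Sequence[SensorResponseSpec],
    concentrations: np.ndarray,
    analytes: Sequence[str] | None = None,
    program: PotentialProgram | None = None,
    seed: int = 0,
    class_label: str = "mixture",
    id_prefix: str = "mix",
) -> Dataset:
    """Measure a list of mixture concentration vectors with the array.

    ``concentrations`` is an ``n_samples x n_analytes`` array in µM with
    columns in ``analytes`` order (defaulting to the union of the specs'
    analytes).
    """
    program = program or PotentialProgram()
    if analytes is None:
        analytes = list(dict.fromkeys(a for s in specs for a in s.responses))
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.ndim != 2 or concentrations.shape[1] != len(analytes):
        raise ValidationError(
            f"concentrations must be n_samples x {len(analytes)}, "
            f"got shape {concentrations.shape}"
        )
    rng = np.random.default_rng(seed)
    spec_analytes = {a for s in specs for a in s.responses}
    samples = []
    for i, row in enumerate(concentrations):
        conc = {a: float(c) for a, c in zip(analytes, row)}
        full_conc = {**{a: 0.0 for a in spec_analytes}, **conc}
        vgrams = {
            spec.sensor_id: simulate_voltammogram(
                spec, full_conc, program, rng=rng, sample_index=i
            )
            for spec in specs
        }
        samples.append(
            ArraySample(
                sample_id=f"{id_prefix}_{i + 1:03d}",
                class_label=class_label,
                concentrations=conc,
                voltammograms=vgrams,
                replicate_index=1,
            )
        )
    return Dataset(
        samples=samples,
        sensor_roster=[s.sensor_id for s in specs],
        analytes=list(analytes),
    )
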