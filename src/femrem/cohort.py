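"""Synthetic patient cohort generation for closed-loop testing.

Generates patient records (body weight, Pauwels angle, jittered femur
geometry, stem assignment) and synthetic "observed" per-zone remodeling
labels produced by a ground-truth mechanostat plus optional class-uniform
label noise.  Everything is a pure function of its seed.

Default distributions: body weight ~ Normal(70, 12) kg truncated to
[45, 110]; Pauwels angle ~ Normal(16, 3) clipped to [5, 30]; geometry
parameters jittered +-10% around the parametric defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .geometry import FemurParams, StemType
from .remodeling import RemodelingClass, ThresholdPair, classify_stimulus

__all__ = [
    "PatientRecord",
    "ObservedLabels",
    "generate_patient",
    "generate_cohort",
    "generate_observed_labels",
]

_JITTERED_FIELDS = (
    "shaft_length",
    "shaft_width",
    "cortical_thickness",
    "metaphysis_height",
    "neck_length",
    "neck_width",
    "trochanter_height",
    "calcar_flare",
)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    body_weight: float  # kg
    height: float  # cm
    pauwels_angle: float  # deg
    stem_type: StemType
    alignment_angle: float  # deg, 0 = neutral
    geometry_params: FemurParams
    rng_seed: int

    def __post_init__(self) -> None:
        if self.body_weight <= 0.0:
            raise InvalidParameterError("body_weight must be > 0")
        if not 5.0 <= self.pauwels_angle <= 30.0:
            raise InvalidParameterError("pauwels_angle must lie in [5, 30] deg")


@dataclass(frozen=True)
class ObservedLabels:
    labels: dict[int, RemodelingClass]

    def __post_init__(self) -> None:
        if set(self.labels) != set(range(1, 8)):
            raise InvalidParameterError("labels must cover zones 1..7 exactly once")


def generate_patient(
    seed: int,
    stem_type: StemType | str = StemType.MINIMA,
    *,
    weight_mean: float = 70.0,
    weight_sd: float = 12.0,
    weight_bounds: tuple[float, float] = (45.0, 110.0),
    pauwels_mean: float = 16.0,
    pauwels_sd: float = 3.0,
    geometry_jitter: float = 0.10,
    alignment_angle: float = 0.0,
) -> PatientRecord:
    """Draw one reproducible synthetic patient."""
    if seed < 0:
        raise InvalidParameterError("seed must be >= 0")
    if isinstance(stem_type, str):
        stem_type = StemType[stem_type.upper()]
    rng = np.random.default_rng(seed)

    lo, hi = weight_bounds
    weight = float(rng.normal(weight_mean, weight_sd))
    while not lo <= weight <= hi:  # truncation by redraw
        weight = float(rng.normal(weight_mean, weight_sd))
    pauwels = float(np.clip(rng.normal(pauwels_mean, pauwels_sd), 5.0, 30.0))
    height = float(np.clip(rng.normal(168.0, 9.0), 145.0, 200.0))

    base = FemurParams()
    jit = {
        name: getattr(base, name) * float(rng.uniform(1.0 - geometry_jitter, 1.0 + geometry_jitter))
        for name in _JITTERED_FIELDS
    }
    jit["ccd_angle"] = float(np.clip(rng.normal(130.0, 4.0), 120.0, 140.0))
    params = replace(base, **jit)

    return PatientRecord(
        patient_id=f"SYN-{seed:06d}",
        body_weight=weight,
        height=height,
        pauwels_angle=pauwels,
        stem_type=stem_type,
        alignment_angle=alignment_angle,
        geometry_params=params,
        rng_seed=seed,
    )


def generate_cohort(
    n: int,
    seed: int,
    stem_mix: dict[StemType, float] | None = None,
    **patient_kwargs,
) -> list[PatientRecord]:
    """Generate ``n`` patients with stems assigned per ``stem_mix``.

    The default mix is balanced across the three archetypes (exactly n/3
    each when n is divisible by 3, e.g. 5 per stem at n = 15).
    """
    if n < 1:
        raise InvalidParameterError("cohort size must be >= 1")
    if stem_mix is None:
        stem_mix = {st: 1.0 / 3.0 for st in StemType}
    total = sum(stem_mix.values())
    if total <= 0:
        raise InvalidParameterError("stem_mix must have positive mass")

    # largest-remainder allocation keeps the mix exact and deterministic
    types = sorted(stem_mix, key=lambda s: s.value)
    quotas = [n * stem_mix[t] / total for t in types]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(types)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1

    assignment: list[StemType] = []
    for t, c in zip(types, counts):
        assignment.extend([t] * c)

    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [
        generate_patient(int(s), stem, **patient_kwargs)
        for s, stem in zip(seeds, assignment)
    ]


def generate_observed_labels(
    zone_stimuli: dict[int, float],
    true_thresholds: ThresholdPair,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> ObservedLabels:
    """Label each zone by the forward mechanostat, then flip each label to a
    uniformly random *different* class with probability ``noise_rate``."""
    if not 0.0 <= noise_rate < 0.5:
        raise InvalidParameterError("noise_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    classes = list(RemodelingClass)
    labels: dict[int, RemodelingClass] = {}
    for zid in sorted(zone_stimuli):
        lab = classify_stimulus(zone_stimuli[zid], true_thresholds)
        if noise_rate > 0.0 and rng.random() < noise_rate:
            others = [c for c in classes if c is not lab]
            lab = others[int(rng.integers(len(others)))]
        labels[zid] = lab
    return ObservedLabels(labels=labels)
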