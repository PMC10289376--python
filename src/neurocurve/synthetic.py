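"""Synthetic neurite cohorts with controllable curvature structure.

Real post-mortem trace data for this kind of study are rarely shareable,
so every downstream stage is exercised against cohorts generated here.
Neurites are simulated as discrete 3D **worm-like chains**: the unit
tangent performs a random walk on the sphere so that its autocorrelation
decays as ``exp(-s / Lp)``, where ``Lp`` is the persistence length (μm).
For a chain built with node spacing ``h``, the per-step deflection angle
is Rayleigh-distributed with mode ``sqrt(h / Lp)``, which gives a
closed-form expected Menger curvature

    E[κ] = sqrt(π / (2 · h · Lp)),

monotone decreasing in ``Lp``.  The generator therefore works backwards:
each neurite draws a target curvature from its case's distribution and
is grown with ``Lp = π / (2 · h · κ²)``.

Cohort structure (all parameters on :class:`SyntheticCohortSpec`):

* **controls** — case mean curvature near ``control_mean_curvature``
  with small between-case spread; the across-neurite curvature SD
  declines linearly with age (the aging signature: older cases lose the
  high-curvature end of their distribution);
* **disease cases** — case mean and SD elevated by multiplicative
  factors, radii thinned, and a minority *tail component* of
  short-persistence neurites that produces the long-tailed curvature
  histograms without moving the bulk mode;
* **symptom score** — affine in the case's target mean curvature plus
  noise, truncated at zero; controls are exactly zero;
* **antipsychotic dose** — drawn independently of curvature for disease
  cases (so the dose regression is null by construction), absent for
  controls.

A single global seed expands into independent per-case substreams via
``numpy.random.SeedSequence`` spawn keys, so cohorts are reproducible
and adding cases does not perturb earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .model import CaseRecord, ConstituentKind, NeuriteTrace, SkeletonModel, SkeletonNode

__all__ = [
    "SyntheticCohortSpec",
    "CaseTruth",
    "persistence_for_curvature",
    "expected_curvature",
    "generate_neurite",
    "generate_cohort",
]


def persistence_for_curvature(kappa: float, step: float) -> float:
    """Persistence length (μm) giving expected Menger curvature *kappa*."""
    if kappa <= 0 or step <= 0:
        raise ValueError("kappa and step must be > 0")
    return math.pi / (2.0 * step * kappa * kappa)


def expected_curvature(persistence_length: float, step: float) -> float:
    """Closed-form expected Menger curvature of a chain at spacing *step*."""
    return math.sqrt(math.pi / (2.0 * step * persistence_length))


@dataclass
class SyntheticCohortSpec:
    """Generating parameters of a synthetic case-control cohort.

    Defaults emulate a cohort of eight cases per group with a ~60%
    elevation of mean neurite curvature in the disease group, an
    age-declining curvature SD in controls, modest radius thinning, and
    a long-tail mixture component confined to disease cases.
    """

    n_cases_per_group: int = 8
    neurites_per_case: int = 200
    # trace geometry
    trace_length_range: tuple[float, float] = (20.0, 60.0)  # μm, uniform
    step: float = 1.0                                       # μm node spacing
    # control curvature law
    control_mean_curvature: float = 0.36    # 1/μm, case-mean target
    between_case_mean_sd: float = 0.03      # 1/μm, case-to-case spread
    sd_intercept: float = 0.25              # 1/μm, curvature SD at age 0
    sd_age_slope: float = -0.002            # 1/μm per year (negative: aging)
    sd_floor: float = 0.02                  # 1/μm, lower clamp
    sd_case_jitter: float = 0.10            # lognormal sigma on case SD target
    age_range: tuple[float, float] = (25.0, 75.0)  # years, uniform
    # disease effects (multiplicative on the control law)
    disease_curvature_multiplier: float = 1.6
    disease_sd_multiplier: float = 1.6
    disease_radius_multiplier: float = 0.85
    # long-tail mixture (disease only)
    tail_fraction: float = 0.15
    tail_mean_curvature: float = 1.0        # 1/μm
    tail_sd_curvature: float = 0.15         # 1/μm
    # radii
    radius_mean: float = 0.6                # μm, control per-case mean
    radius_cv: float = 0.25                 # per-node lognormal CV
    between_case_radius_sd: float = 0.05    # μm
    # symptom model: score = max(0, slope*(kappa - ref) + noise), controls 0
    score_slope: float = 12.0               # per (1/μm)
    score_ref_curvature: float = 0.33       # 1/μm
    score_noise_sd: float = 2.0             # sets case-level structure-symptom r ~ 0.8
    # medication (disease only, independent of structure)
    cpz_log_mean: float = math.log(450.0)   # mg/day
    cpz_log_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases_per_group < 1:
            raise ValueError("n_cases_per_group must be ≥ 1")
        if self.neurites_per_case < 2:
            raise ValueError("neurites_per_case must be ≥ 2")
        positive = ["step", "control_mean_curvature", "between_case_mean_sd",
                    "sd_intercept", "sd_floor", "sd_case_jitter",
                    "disease_curvature_multiplier", "disease_sd_multiplier",
                    "disease_radius_multiplier", "tail_mean_curvature",
                    "tail_sd_curvature", "radius_mean", "radius_cv",
                    "between_case_radius_sd"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.tail_fraction < 1.0:
            raise ValueError("tail_fraction must be in [0, 1)")
        lo, hi = self.trace_length_range
        if not 0 < lo <= hi:
            raise ValueError("trace_length_range must satisfy 0 < lo <= hi")
        if lo < 3 * self.step:
            raise ValueError("shortest trace must be ≥ 3 steps")


@dataclass
class CaseTruth:
    """Generating parameters and expected summaries for one case."""

    case_id: str
    group: str
    age: float
    target_mean_curvature: float     # 1/μm, expectation of the case mean
    target_sd_curvature: float       # 1/μm, between-neurite spread target
    bulk_mean_curvature: float       # 1/μm, bulk mixture component mean
    tail_fraction: float
    radius_mean: float               # μm
    curvature_multiplier: float
    radius_multiplier: float
    hallucination_score: float
    cpz_dose: Optional[float]

    def as_dict(self) -> dict:
        return asdict(self)


def _unit_rows(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return _unit_rows(v)


def _grow_chains(
    persistence: np.ndarray,
    n_steps: np.ndarray,
    step: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Grow several worm-like chains at once (vectorized over chains).

    ``persistence[i]`` and ``n_steps[i]`` give chain i's persistence
    length and segment count; returns one (n_steps[i]+1, 3) coordinate
    array per chain.  Chains start at the origin with isotropic random
    initial tangents; positions advance by ``step`` along the current
    tangent, and after each step the tangent is rotated by a Rayleigh
    angle of scale ``sqrt(step/Lp)`` about a uniformly random
    perpendicular axis.
    """
    n = len(persistence)
    max_steps = int(n_steps.max())
    sigma = np.sqrt(step / persistence)
    tangents = _random_unit_vectors(n, rng)
    pos = np.zeros((n, 3))
    out = np.zeros((n, max_steps + 1, 3))
    for k in range(max_steps):
        pos = pos + step * tangents
        out[:, k + 1, :] = pos
        # Menger curvature of an equal-chord triplet with turning angle
        # theta is 2*sin(theta/2)/step, so drawing the *chord* variable
        # theta' ~ Rayleigh and turning by theta = 2*arcsin(theta'/2)
        # makes the realized point curvature exactly theta'/step:
        # unbiased for E[kappa] at any magnitude.  E[cos theta] = 1 -
        # step/Lp, matching the worm-like-chain decorrelation.
        chord = np.clip(rng.rayleigh(scale=sigma), 0.0, 2.0 - 1e-9)
        theta = 2.0 * np.arcsin(chord / 2.0)
        g = rng.normal(size=(n, 3))
        g -= np.sum(g * tangents, axis=1, keepdims=True) * tangents
        norms = np.linalg.norm(g, axis=1, keepdims=True)
        u = g / np.maximum(norms, 1e-300)
        tangents = tangents * np.cos(theta)[:, None] + u * np.sin(theta)[:, None]
        tangents = _unit_rows(tangents)
    return [out[i, : n_steps[i] + 1, :] for i in range(n)]


def _lognormal_radii(mean: float, cv: float, size, rng: np.random.Generator) -> np.ndarray:
    s2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - s2 / 2.0
    r = rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=size)
    return np.maximum(r, 0.01)  # keep radii representable at column precision


def generate_neurite(
    persistence_length: float,
    total_length: float,
    step: float,
    rng: np.random.Generator,
    radius_mean: float = 0.6,
    radius_cv: float = 0.25,
    trace_id: str = "T0000",
) -> NeuriteTrace:
    """Generate one worm-like-chain neurite trace.

    Requires ``persistence_length > 0`` and ``total_length ≥ 3·step``.
    Node spacing equals *step* exactly; per-node radii are lognormal
    with the given mean and coefficient of variation.
    """
    if persistence_length <= 0:
        raise ValueError("persistence_length must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if total_length < 3 * step:
        raise ValueError("total_length must be ≥ 3 * step")
    n_steps = int(round(total_length / step))
    coords = _grow_chains(np.array([persistence_length]),
                          np.array([n_steps]), step, rng)[0]
    radii = _lognormal_radii(radius_mean, radius_cv, len(coords), rng)
    nodes = [SkeletonNode(i + 1, *xyz, r)
             for i, (xyz, r) in enumerate(zip(coords.tolist(), radii.tolist()))]
    return NeuriteTrace(trace_id=trace_id, nodes=nodes, kind=ConstituentKind.NEURITE)


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(case_index,)))


def _draw_gamma(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)


def _case_truth(spec: SyntheticCohortSpec, case_id: str, group: str,
                rng: np.random.Generator) -> CaseTruth:
    age = rng.uniform(*spec.age_range)
    base_mean = rng.normal(spec.control_mean_curvature, spec.between_case_mean_sd)
    base_mean = max(base_mean, 0.05)
    base_sd = max(spec.sd_floor, spec.sd_intercept + spec.sd_age_slope * age)
    base_sd *= rng.lognormal(0.0, spec.sd_case_jitter)
    radius = max(0.05, rng.normal(spec.radius_mean, spec.between_case_radius_sd))

    if group == "schizophrenia":
        mult = spec.disease_curvature_multiplier
        target_mean = base_mean * mult
        target_sd = base_sd * spec.disease_sd_multiplier
        tail_frac = spec.tail_fraction
        radius *= spec.disease_radius_multiplier
        rmult = spec.disease_radius_multiplier
        # bulk component mean chosen so the mixture hits the case target
        bulk_mean = (target_mean - tail_frac * spec.tail_mean_curvature) / (1.0 - tail_frac)
        if bulk_mean <= 0.02:
            raise ValueError(
                "tail mixture incompatible with the target mean curvature "
                f"(bulk mean {bulk_mean:.3f} 1/μm)")
        score = max(0.0, spec.score_slope * (target_mean - spec.score_ref_curvature)
                    + rng.normal(0.0, spec.score_noise_sd))
        cpz: Optional[float] = float(rng.lognormal(spec.cpz_log_mean, spec.cpz_log_sd))
    else:
        mult, rmult = 1.0, 1.0
        target_mean, target_sd = base_mean, base_sd
        tail_frac, bulk_mean = 0.0, base_mean
        score, cpz = 0.0, None

    return CaseTruth(
        case_id=case_id, group=group, age=float(age),
        target_mean_curvature=float(target_mean),
        target_sd_curvature=float(target_sd),
        bulk_mean_curvature=float(bulk_mean),
        tail_fraction=float(tail_frac),
        radius_mean=float(radius),
        curvature_multiplier=float(mult),
        radius_multiplier=float(rmult),
        hallucination_score=float(round(score, 1)),
        cpz_dose=None if cpz is None else float(round(cpz)))


def _generate_case_model(spec: SyntheticCohortSpec, truth: CaseTruth,
                         rng: np.random.Generator) -> SkeletonModel:
    n = spec.neurites_per_case
    h = spec.step
    # per-neurite target curvature: gamma bulk + optional gaussian tail
    is_tail = rng.random(n) < truth.tail_fraction
    n_tail = int(is_tail.sum())
    kappa = np.empty(n)
    bulk_sd = max(truth.target_sd_curvature, 0.01)
    kappa[~is_tail] = _draw_gamma(truth.bulk_mean_curvature, bulk_sd,
                                  n - n_tail, rng)
    if n_tail:
        kappa[is_tail] = rng.normal(spec.tail_mean_curvature,
                                    spec.tail_sd_curvature, size=n_tail)
    kappa = np.clip(kappa, 0.02, None)
    persistence = np.pi / (2.0 * h * kappa ** 2)
    lengths = rng.uniform(*spec.trace_length_range, size=n)
    n_steps = np.round(lengths / h).astype(int)
    chains = _grow_chains(persistence, n_steps, h, rng)
    traces = []
    for i, coords in enumerate(chains):
        radii = _lognormal_radii(truth.radius_mean, spec.radius_cv,
                                 len(coords), rng)
        base = i * 1000
        nodes = [SkeletonNode(base + j + 1, *xyz, r)
                 for j, (xyz, r) in enumerate(zip(coords.tolist(), radii.tolist()))]
        traces.append(NeuriteTrace(trace_id=f"T{i:04d}", nodes=nodes,
                                   kind=ConstituentKind.NEURITE))
    return SkeletonModel(dataset_id=f"{truth.case_id}A", traces=traces)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[SkeletonModel], list[CaseRecord], dict[str, CaseTruth]]:
    """Generate one model + record per case, plus the generating truth.

    Case labels are ``S1..Sn`` (disease) and ``N1..Nn`` (controls); each
    case contributes one dataset labelled ``<case>A``.  The returned
    ``truth`` maps case id to its :class:`CaseTruth`, enabling
    parameter-recovery tests.  Identical spec + seed reproduce the
    cohort exactly.
    """
    spec.validate()
    models: list[SkeletonModel] = []
    records: list[CaseRecord] = []
    truth: dict[str, CaseTruth] = {}
    labels = ([(f"S{i+1}", "schizophrenia") for i in range(spec.n_cases_per_group)]
              + [(f"N{i+1}", "control") for i in range(spec.n_cases_per_group)])
    for idx, (case_id, group) in enumerate(labels):
        rng = _case_rng(spec.seed, idx)
        ct = _case_truth(spec, case_id, group, rng)
        models.append(_generate_case_model(spec, ct, rng))
        records.append(CaseRecord(
            case_id=case_id, group=group, age=ct.age,
            sex="M" if rng.random() < 0.5 else "F",
            hallucination_score=ct.hallucination_score,
            cpz_dose=ct.cpz_dose))
        truth[case_id] = ct
    return models, records, truth
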