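"""Core domain types for traced neuron skeletons.

A traced dataset is a :class:`SkeletonModel`: a flat list of unbranched
polylines (:class:`NeuriteTrace`), each an ordered chain of
:class:`SkeletonNode` carrying a 3D position and a local half-thickness
(radius).  Branching is represented by starting a new trace at the branch
point, so every trace is an independent open curve and carries exactly one
summary curvature value downstream.

All coordinates and radii are in micrometres (isotropic); curvatures
derived from them are in 1/μm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ConstituentKind",
    "SkeletonNode",
    "NeuriteTrace",
    "SkeletonModel",
    "CaseRecord",
    "Violation",
    "validate_model",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a model or trace breaks a structural invariant."""


class ConstituentKind(str, enum.Enum):
    """Role of a traced constituent within the tissue model."""

    NEURITE = "neurite"
    SOMA = "soma"
    OTHER = "other"


@dataclass(frozen=True)
class SkeletonNode:
    """One node of a traced polyline: position (μm) and local radius (μm)."""

    node_id: int
    x: float
    y: float
    z: float
    radius: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def is_finite(self) -> bool:
        return all(math.isfinite(v) for v in (self.x, self.y, self.z, self.radius))


@dataclass
class NeuriteTrace:
    """A single unbranched polyline of ≥ 2 non-coincident nodes.

    One neurite trace is the unit of analysis that yields one summary
    curvature value.  Branch points never occur inside a trace; a branch
    is encoded by duplicating the junction node into each child trace.
    """

    trace_id: str
    nodes: list[SkeletonNode]
    kind: ConstituentKind = ConstituentKind.NEURITE

    def __len__(self) -> int:
        return len(self.nodes)

    def coords(self) -> np.ndarray:
        """(n, 3) float array of node positions in μm."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.nodes], dtype=float)

    def length(self) -> float:
        """Polyline (chord-sum) length in μm."""
        xyz = self.coords()
        if len(xyz) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())


@dataclass
class SkeletonModel:
    """One traced dataset: a set of traces plus an identifying label.

    Dataset labels follow the ``<case><letter>`` scheme, e.g. ``S8A`` is
    dataset A of case S8; :func:`dataset_to_case` recovers the case label.
    """

    dataset_id: str
    traces: list[NeuriteTrace] = field(default_factory=list)

    @property
    def total_trace_length(self) -> float:
        """Sum of polyline lengths over neurite-kind traces (μm)."""
        return float(
            sum(t.length() for t in self.traces if t.kind is ConstituentKind.NEURITE)
        )

    def neurite_traces(self) -> list[NeuriteTrace]:
        return [t for t in self.traces if t.kind is ConstituentKind.NEURITE]

    def n_nodes(self) -> int:
        return sum(len(t) for t in self.traces)


def dataset_to_case(dataset_id: str) -> str:
    """Strip the trailing dataset letter from a dataset label.

    ``"S8A" -> "S8"``; a label without a trailing letter maps to itself.
    """
    if len(dataset_id) > 1 and dataset_id[-1].isalpha() and dataset_id[-2].isdigit():
        return dataset_id[:-1]
    return dataset_id


@dataclass
class CaseRecord:
    """Clinical and demographic metadata for one case.

    ``hallucination_score`` is the auditory-hallucination severity rating
    (dimensionless; controls are 0 by definition).  ``cpz_dose`` is the
    chlorpromazine-equivalent antipsychotic dose in mg/day; it is absent
    for unmedicated cases and for controls.
    """

    case_id: str
    group: str  # "schizophrenia" | "control"
    age: float
    sex: str
    hallucination_score: float = 0.0
    cpz_dose: Optional[float] = None

    VALID_GROUPS = ("schizophrenia", "control")

    def __post_init__(self) -> None:
        if self.group not in self.VALID_GROUPS:
            raise ValidationError(
                f"case {self.case_id}: group must be one of {self.VALID_GROUPS}, "
                f"got {self.group!r}"
            )
        if self.group == "control" and self.hallucination_score != 0:
            raise ValidationError(
                f"case {self.case_id}: control cases have hallucination_score 0"
            )


@dataclass(frozen=True)
class Violation:
    """One invariant breach found by :func:`validate_model`."""

    trace_id: str
    node_id: Optional[int]
    kind: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f"trace {self.trace_id}"
        if self.node_id is not None:
            loc += f", node {self.node_id}"
        return f"[{self.kind}] {loc}: {self.message}"


def _iter_trace_violations(trace: NeuriteTrace) -> Iterable[Violation]:
    if len(trace.nodes) < 2:
        yield Violation(trace.trace_id, None, "short_trace",
                        f"trace has {len(trace.nodes)} node(s), needs ≥ 2")
    for node in trace.nodes:
        if not node.is_finite():
            yield Violation(trace.trace_id, node.node_id, "nonfinite",
                            "non-finite coordinate or radius")
        elif node.radius <= 0:
            yield Violation(trace.trace_id, node.node_id, "nonpositive_radius",
                            f"radius {node.radius} μm must be > 0")
    for a, b in zip(trace.nodes, trace.nodes[1:]):
        if a.is_finite() and b.is_finite():
            d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            if d == 0.0:
                yield Violation(trace.trace_id, b.node_id, "coincident_nodes",
                                f"nodes {a.node_id} and {b.node_id} coincide")


def validate_model(model: SkeletonModel) -> list[Violation]:
    """Report every invariant breach in *model*.

    Checks: dataset label non-empty, node ids unique model-wide, every
    trace ≥ 2 nodes, no coincident consecutive nodes, all radii positive,
    all values finite.  Returns an empty list iff the model is analyzable.
    """
    violations: list[Violation] = []
    if not model.dataset_id:
        violations.append(Violation("<model>", None, "empty_dataset_id",
                                    "dataset_id must be non-empty"))
    seen: dict[int, str] = {}
    for trace in model.traces:
        violations.extend(_iter_trace_violations(trace))
        for node in trace.nodes:
            if node.node_id in seen:
                violations.append(Violation(
                    trace.trace_id, node.node_id, "duplicate_node_id",
                    f"node_id {node.node_id} already used in trace {seen[node.node_id]}"))
            else:
                seen[node.node_id] = trace.trace_id
    return violations
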