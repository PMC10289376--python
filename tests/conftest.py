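"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (least-squares
circumcenter, hand-evaluated Welch formula) kept independent of the
package's implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from neurocurve.model import ConstituentKind, NeuriteTrace, SkeletonNode


# ---------------------------------------------------------------------------
# trace construction helpers


_node_counter = itertools.count(1)


def make_trace(points, radii=None, trace_id="T0000",
               kind=ConstituentKind.NEURITE) -> NeuriteTrace:
    points = np.asarray(points, dtype=float)
    if radii is None:
        radii = np.full(len(points), 0.5)
    radii = np.asarray(radii, dtype=float)
    nodes = [SkeletonNode(next(_node_counter), *p, r)
             for p, r in zip(points.tolist(), radii.tolist())]
    return NeuriteTrace(trace_id=trace_id, nodes=nodes, kind=kind)


def straight_trace(length=10.0, n=11, **kw) -> NeuriteTrace:
    t = np.linspace(0.0, length, n)
    return make_trace(np.column_stack([t, np.zeros(n), np.zeros(n)]), **kw)


def circle_trace(radius=5.0, n=400, **kw) -> NeuriteTrace:
    """Open polygonal arc covering ~95% of a circle (open curve, no closure)."""
    ang = np.linspace(0.0, 1.9 * np.pi, n)
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.zeros(n)])
    return make_trace(pts, **kw)


def helix_trace(a=1.0, b=1.0, turns=4.0, n=800, **kw) -> NeuriteTrace:
    """Circular helix r(t) = (a cos t, a sin t, b t); curvature a/(a²+b²)."""
    t = np.linspace(0.0, 2 * np.pi * turns, n)
    pts = np.column_stack([a * np.cos(t), a * np.sin(t), b * t])
    return make_trace(pts, **kw)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ---------------------------------------------------------------------------
# independent oracles


def circumradius_lstsq(p1, p2, p3) -> float:
    """Circumradius via an independent equal-distance solve.

    Parametrizes the center as a + s·u + t·v in the triangle's plane and
    solves the two linear equal-distance conditions |c-p1|² = |c-p2|² =
    |c-p3|² by least squares.  Returns inf for collinear points.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u, v = b - a, c - a
    # center = a + s*u + t*v; |x-a|^2 = |x-b|^2  =>  2(b-a).x = |b|^2-|a|^2
    m = np.array([[2 * u @ u, 2 * u @ v],
                  [2 * v @ u, 2 * v @ v]])
    rhs = np.array([u @ u, v @ v])
    try:
        st = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        return float("inf")
    center = a + st[0] * u + st[1] * v
    return float(np.linalg.norm(center - a))


def welch_oracle(x, y):
    """Hand evaluation of Welch's t, Welch-Satterthwaite df and 2-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_cohort():
    """A 2+2-case cohort small enough for per-test generation."""
    from neurocurve.synthetic import SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(n_cases_per_group=3, neurites_per_case=15,
                               trace_length_range=(15.0, 25.0), seed=11)
    return generate_cohort(spec)
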