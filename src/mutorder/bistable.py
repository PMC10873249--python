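"""Deterministic analysis of a mutation-controlled bistable expression ODE.

The model is ``dx/dt = lam + f(x) - x`` where ``f`` is a cubic
autoregulation term and the dimensionless production rate ``lam`` is set
by the cell's mutation state through a Boolean control,
``lam = basal + jak2 * 1_J + tet2 * 1_T``.

For a suitable cubic the drift has one or three zeros depending on
``lam``; the three-root window is bounded by two saddle-node thresholds
and produces hysteresis: the stationary level reached after a sequence
of mutations depends on the order in which the production rate was
stepped, not only on its final value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AutoregCubic",
    "MutationState",
    "RegulationSpec",
    "FixedPoint",
    "FixedPointSet",
    "BifurcationThresholds",
    "CoupledModelSpec",
    "ExpressionTable",
    "ObservationFlags",
    "MonostableError",
    "eval_autoregulation",
    "drift",
    "potential",
    "find_fixed_points",
    "saddle_node_thresholds",
    "production_rate",
    "follow_branch",
    "mutation_trajectory_steady_states",
    "coupled_steady_states",
    "classify_observation",
    "REGULATION_PRESETS",
    "COUPLED_PRESET",
]

#: Tolerance below which two real roots are merged into one degenerate root.
_ROOT_MERGE_TOL = 1e-7


class MonostableError(ValueError):
    """Raised when a cubic admits no bistable window."""


class MutationState(enum.Enum):
    """Mutation pattern of a cell lineage.

    ``O`` is wild-type, ``J``/``T`` carry a single mutation and
    ``JT``/``TJ`` carry both, distinguished by acquisition order.
    """

    O = "O"
    J = "J"
    T = "T"
    JT = "JT"
    TJ = "TJ"

    @property
    def has_jak2(self) -> int:
        """Indicator ``1_J``: 1 if the JAK2 mutation is present."""
        return int(self in (MutationState.J, MutationState.JT, MutationState.TJ))

    @property
    def has_tet2(self) -> int:
        """Indicator ``1_T``: 1 if the TET2 mutation is present."""
        return int(self in (MutationState.T, MutationState.JT, MutationState.TJ))


@dataclass(frozen=True)
class AutoregCubic:
    """Cubic autoregulation term ``f(x)``.

    Parameters
    ----------
    coefficients
        Polynomial coefficients ``(c3, c2, c1, c0)`` in descending
        powers, i.e. ``f(x) = c3 x^3 + c2 x^2 + c1 x + c0``.  The
        leading coefficient must be negative so that ``x - f(x)``
        diverges to +/- infinity on the correct sides and the drift has
        at most three zeros.
    """

    coefficients: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.coefficients)
        if len(c) != 4:
            raise ValueError("a cubic needs exactly 4 coefficients (c3, c2, c1, c0)")
        if not c[0] < 0:
            raise ValueError("leading coefficient must be negative")
        object.__setattr__(self, "coefficients", c)

    @classmethod
    def default(cls) -> "AutoregCubic":
        """The reference cubic ``f(x) = -(x - 2)^3 + 2 (x - 2)``.

        Expanded: ``-x^3 + 6 x^2 - 10 x + 4``.  Its bistable window is
        ``lam in (2 - 2/(3 sqrt 3), 2 + 2/(3 sqrt 3))``, roughly
        (1.615, 2.385).
        """
        return cls((-1.0, 6.0, -10.0, 4.0))

    def __call__(self, x: float) -> float:
        c3, c2, c1, c0 = self.coefficients
        return ((c3 * x + c2) * x + c1) * x + c0

    def derivative(self, x: float) -> float:
        """``f'(x)``."""
        c3, c2, c1, _ = self.coefficients
        return (3.0 * c3 * x + 2.0 * c2) * x + c1

    def antiderivative(self, x: float) -> float:
        """``F(x) = int_0^x f(s) ds`` with ``F(0) = 0``."""
        c3, c2, c1, c0 = self.coefficients
        return (((c3 / 4.0 * x + c2 / 3.0) * x + c1 / 2.0) * x + c0) * x


@dataclass(frozen=True)
class RegulationSpec:
    """Boolean-controlled production rate ``lam = basal + jak2*1_J + tet2*1_T``."""

    basal: float
    jak2: float
    tet2: float

    def rate(self, state: MutationState) -> float:
        return self.basal + self.jak2 * state.has_jak2 + self.tet2 * state.has_tet2


@dataclass(frozen=True)
class FixedPoint:
    x: float
    stable: bool


@dataclass(frozen=True)
class FixedPointSet:
    """Real zeros of the drift at a given production rate, sorted ascending."""

    points: tuple[FixedPoint, ...]
    lam: float
    tol: float

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def stable(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.stable)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(p.x for p in self.points)


@dataclass(frozen=True)
class BifurcationThresholds:
    """Production rates at the two saddle-node points, ``lam_low < lam_high``."""

    lam_low: float
    lam_high: float


@dataclass(frozen=True)
class CoupledModelSpec:
    """Two-gene cascade: bistable Y feeding a linear X.

    Y follows ``dy/dt = lam_Y + f(y) - y`` with ``lam_Y`` set by
    ``regulation``; X follows the linear dynamics
    ``dx/dt = basal + direct_jak2 * 1_J + coupling * y - x`` so that at
    steady state ``x* = basal + direct_jak2 * 1_J + coupling * y*``.
    """

    regulation: RegulationSpec
    cubic: AutoregCubic = field(default_factory=AutoregCubic.default)
    basal: float = 1.0
    direct_jak2: float = -1.0
    coupling: float = 1.0


@dataclass(frozen=True)
class ExpressionTable:
    """Stationary expression level for each of the five mutation histories."""

    o: float
    j: float
    t: float
    jt: float
    tj: float

    def __getitem__(self, state: MutationState) -> float:
        return {
            MutationState.O: self.o,
            MutationState.J: self.j,
            MutationState.T: self.t,
            MutationState.JT: self.jt,
            MutationState.TJ: self.tj,
        }[state]

    def as_dict(self) -> dict[str, float]:
        return {"O": self.o, "J": self.j, "T": self.t, "JT": self.jt, "TJ": self.tj}


@dataclass(frozen=True)
class ObservationFlags:
    """Qualitative classification of an expression table.

    ``pattern`` is 1-4 following the observed gene families:

    1. one mutation only acts when the other is absent
       (``t ~= tj`` while ``o != j``);
    2. one mutation only acts when the other is present
       (``o ~= j`` while ``j != tj``);
    3. sign inversion (``o < j`` but ``t > tj``);
    4. order dependence (``jt != tj``).
    """

    non_additive: bool
    non_commutative: bool
    pattern: int | None


def eval_autoregulation(x: float, cubic: AutoregCubic) -> float:
    """Evaluate the autoregulation term ``f(x)``."""
    return cubic(x)


def drift(x: float, lam: float, cubic: AutoregCubic) -> float:
    """Right-hand side ``lam + f(x) - x`` of the expression ODE."""
    return lam + cubic(x) - x


def potential(x: float, lam: float, cubic: AutoregCubic) -> float:
    """Potential ``U(x) = -int_0^x (lam + f(s) - s) ds`` with ``U(0) = 0``.

    ``-dU/dx`` equals the drift, so minima of ``U`` are stable fixed
    points and maxima are unstable ones.
    """
    return 0.5 * x * x - lam * x - cubic.antiderivative(x)


def _drift_poly(lam: float, cubic: AutoregCubic) -> np.ndarray:
    c3, c2, c1, c0 = cubic.coefficients
    return np.array([c3, c2, c1 - 1.0, c0 + lam])


def find_fixed_points(
    lam: float, cubic: AutoregCubic, tol: float = 1e-9
) -> FixedPointSet:
    """All real zeros of the drift, sorted ascending, with stability labels.

    Stability follows the sign of the drift derivative ``f'(x) - 1``
    (negative means stable).  Real roots closer than ``1e-7`` are merged
    into a single degenerate root, which is reported as stable: the
    marginal root at a saddle-node still attracts from one side and is
    treated as an existing branch.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    roots = np.roots(_drift_poly(lam, cubic))
    # A cubic with real coefficients: keep roots with negligible imaginary part.
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-7)
    merged: list[float] = []
    for r in real:
        if merged and abs(r - merged[-1]) < _ROOT_MERGE_TOL:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    # Polish with Newton steps; np.roots is accurate but polishing makes the
    # residual invariant (< 1e-9) hold uniformly.
    points = []
    for r in merged:
        for _ in range(3):
            d = cubic.derivative(r) - 1.0
            if abs(d) > 1e-8:
                r -= drift(r, lam, cubic) / d
        slope = cubic.derivative(r) - 1.0
        points.append(FixedPoint(x=r, stable=slope <= 0.0))
    return FixedPointSet(points=tuple(points), lam=lam, tol=tol)


def saddle_node_thresholds(cubic: AutoregCubic) -> BifurcationThresholds:
    """Production rates at which the drift has a double root.

    Fixed points satisfy ``lam = g(x)`` with ``g(x) = x - f(x)``; the
    saddle-node thresholds are the values of ``g`` at its two critical
    points.  Raises :class:`MonostableError` when ``g`` is monotone.
    """
    c3, c2, c1, _ = cubic.coefficients
    # g'(x) = 1 - f'(x) = -3 c3 x^2 - 2 c2 x + (1 - c1)
    a, b, c = -3.0 * c3, -2.0 * c2, 1.0 - c1
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        raise MonostableError("no bistable window: x - f(x) is monotone")
    x1 = (-b - math.sqrt(disc)) / (2.0 * a)
    x2 = (-b + math.sqrt(disc)) / (2.0 * a)
    g = lambda x: x - cubic(x)
    lo, hi = sorted((g(x1), g(x2)))
    return BifurcationThresholds(lam_low=lo, lam_high=hi)


def production_rate(spec: RegulationSpec, state: MutationState) -> float:
    """Production rate of the given mutation state under ``spec``."""
    return spec.rate(state)


def _relax(x: float, lam: float, cubic: AutoregCubic) -> float:
    """Fixed point reached by the flow of the ODE started at ``x``.

    The one-dimensional flow is monotone between adjacent fixed points,
    so the limit is the nearest fixed point in the direction of the
    drift sign.
    """
    fps = find_fixed_points(lam, cubic)
    values = fps.values
    d = drift(x, lam, cubic)
    if abs(d) <= 1e-12:
        return min(values, key=lambda v: abs(v - x))
    if d > 0:
        above = [v for v in values if v > x]
        if not above:  # cannot happen for a valid cubic (drift -> -inf)
            raise RuntimeError("flow diverges upward; invalid cubic")
        return min(above)
    below = [v for v in values if v < x]
    if not below:
        raise RuntimeError("flow diverges downward; invalid cubic")
    return max(below)


def follow_branch(
    lam_path: Sequence[float], x_init: float, cubic: AutoregCubic
) -> float:
    """Quasi-static continuation of a stable branch along a rate path.

    At each successive production rate the state relaxes to the fixed
    point reached by the flow from the current level; when the branch it
    was on disappears past a saddle-node, the state jumps to the
    remaining branch.  Returns the stationary level after the last rate.
    """
    if len(lam_path) == 0:
        raise ValueError("lam_path must contain at least one rate")
    x = float(x_init)
    for lam in lam_path:
        x = _relax(x, float(lam), cubic)
    return x


#: lam sequences for the five mutation histories (JT: J acquired first).
_HISTORIES: dict[MutationState, tuple[MutationState, ...]] = {
    MutationState.O: (MutationState.O,),
    MutationState.J: (MutationState.O, MutationState.J),
    MutationState.T: (MutationState.O, MutationState.T),
    MutationState.JT: (MutationState.O, MutationState.J, MutationState.JT),
    MutationState.TJ: (MutationState.O, MutationState.T, MutationState.TJ),
}


def mutation_trajectory_steady_states(
    spec: RegulationSpec, cubic: AutoregCubic | None = None
) -> ExpressionTable:
    """Stationary level after each mutation history.

    The pre-mutation lineage starts on the stable fixed point reached by
    relaxation from ``x = 0`` at the wild-type rate (this selects the
    low branch when the wild-type rate sits inside the bistable window).
    Each history then steps the rate through the corresponding states
    with hysteretic branch following; JT and TJ are computed separately.
    """
    cubic = cubic or AutoregCubic.default()
    levels: dict[MutationState, float] = {}
    for final, states in _HISTORIES.items():
        path = [spec.rate(s) for s in states]
        levels[final] = follow_branch(path, 0.0, cubic)
    return ExpressionTable(
        o=levels[MutationState.O],
        j=levels[MutationState.J],
        t=levels[MutationState.T],
        jt=levels[MutationState.JT],
        tj=levels[MutationState.TJ],
    )


def coupled_steady_states(
    model: CoupledModelSpec,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Steady states ``(y_table, x_table)`` of the two-gene cascade."""
    y = mutation_trajectory_steady_states(model.regulation, model.cubic)

    def x_of(state: MutationState, y_star: float) -> float:
        return model.basal + model.direct_jak2 * state.has_jak2 + model.coupling * y_star

    x = ExpressionTable(
        o=x_of(MutationState.O, y.o),
        j=x_of(MutationState.J, y.j),
        t=x_of(MutationState.T, y.t),
        jt=x_of(MutationState.JT, y.jt),
        tj=x_of(MutationState.TJ, y.tj),
    )
    return y, x


def classify_observation(table: ExpressionTable, tol: float = 0.05) -> ObservationFlags:
    """Classify an expression table as (non-)additive/commutative.

    Additivity requires the shift caused by one mutation to be the same
    with and without the other mutation present; commutativity requires
    ``jt == tj``.  Comparisons use the absolute tolerance ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    jak2_shift_alone = table.j - table.o
    jak2_shift_after_t = table.tj - table.t
    tet2_shift_alone = table.t - table.o
    tet2_shift_after_j = table.jt - table.j
    non_additive = (
        abs(jak2_shift_alone - jak2_shift_after_t) > tol
        or abs(tet2_shift_alone - tet2_shift_after_j) > tol
    )
    non_commutative = abs(table.jt - table.tj) > tol

    pattern: int | None = None
    if non_commutative:
        pattern = 4
    elif abs(table.t - table.tj) <= tol and abs(table.o - table.j) > tol:
        pattern = 1
    elif abs(table.o - table.j) <= tol and abs(table.j - table.tj) > tol:
        pattern = 2
    elif table.j - table.o > tol and table.t - table.tj > tol:
        pattern = 3
    return ObservationFlags(
        non_additive=non_additive, non_commutative=non_commutative, pattern=pattern
    )


#: Boolean-control presets reproducing the published scenario panels.
REGULATION_PRESETS: dict[str, RegulationSpec] = {
    "fig2a": RegulationSpec(basal=0.5, jak2=1.0, tet2=1.0),
    "fig2b": RegulationSpec(basal=3.5, jak2=-1.0, tet2=-1.0),
    "fig2c": RegulationSpec(basal=1.5, jak2=1.0, tet2=-1.0),
    "fig2d": RegulationSpec(basal=2.5, jak2=-1.0, tet2=1.0),
    "fig4a": RegulationSpec(basal=2.0, jak2=1.0, tet2=-1.0),
    "fig4b": RegulationSpec(basal=2.0, jak2=-1.0, tet2=1.0),
}

#: Coupled-cascade preset: bistable Y (rate 1.5 + 1_J - 1_T) feeding
#: linear X with dx/dt = 1 - 1_J + y - x.
COUPLED_PRESET = CoupledModelSpec(
    regulation=RegulationSpec(basal=1.5, jak2=1.0, tet2=-1.0)
)
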