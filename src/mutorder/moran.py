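"""Generalized five-type Moran process for order-of-mutation statistics.

Cells occupy five states: wild-type ``O``, single mutants ``J`` and
``T``, and double mutants ``JT``/``TJ`` distinguished by acquisition
order.  Each discrete replacement step removes one cell (weighted by its
death coefficient) and lets another cell divide (weighted by its birth
coefficient); one daughter may acquire an additional mutation.  The
population size ``n`` is conserved.

Step semantics
--------------
The cell removed at a step is excluded from the birth selection, i.e.
division is drawn among the ``n - 1`` remaining cells.  The step is
applied in full (death, then division with possible mutation) before the
stopping condition is tested, and recorded counts are the post-step
values.  The process stops at the first appearance of a double mutant
(``n_JT = 1`` or ``n_TJ = 1``); outcomes are classified JAK2-first pure
(``n_T = 0``), TET2-first pure (``n_J = 0``), or ambiguous.

Both a Monte-Carlo sampler and a deterministic exact propagation of the
transient state probabilities are provided; the latter enumerates all
``(n_J, n_T)`` configurations with ``n_J + n_T <= n`` (no double mutants
exist before absorption).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "AbsorptionClass",
    "MoranParameters",
    "PopulationState",
    "TransitionDistribution",
    "AbsorptionRecord",
    "AbsorptionDistribution",
    "ClassStatistics",
    "AbsorptionStatistics",
    "AbsorptionTimeoutError",
    "PropagationError",
    "SCENARIOS",
    "make_scenario",
    "step_distribution",
    "simulate",
    "propagate_exact",
    "absorption_statistics",
    "system_size_sweep",
    "required_sample_size",
]

logger = logging.getLogger(__name__)

_TYPES = ("O", "J", "T", "JT", "TJ")


class AbsorptionTimeoutError(RuntimeError):
    """Raised when a Monte-Carlo run exceeds its step guard unabsorbed."""


class PropagationError(RuntimeError):
    """Raised when exact propagation fails to meet its stopping rule."""


class AbsorptionClass(enum.Enum):
    """Classification of the population when the first double mutant appears."""

    JAK2_FIRST = "JAK2_first_pure"
    TET2_FIRST = "TET2_first_pure"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MoranParameters:
    """Birth/death coefficients, mutation probabilities and population size.

    ``birth`` and ``death`` are per-type weights ordered
    ``(O, J, T, JT, TJ)``; ``m_oj``, ``m_ot``, ``m_jjt``, ``m_ttj`` are
    the probabilities that a newborn daughter acquires the corresponding
    extra mutation.
    """

    birth: tuple[float, float, float, float, float]
    m_oj: float
    m_ot: float
    m_jjt: float
    m_ttj: float
    n: int
    death: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "birth", tuple(float(b) for b in self.birth))
        object.__setattr__(self, "death", tuple(float(d) for d in self.death))
        if len(self.birth) != 5 or len(self.death) != 5:
            raise ValueError("birth and death need one weight per type (5)")
        if any(b <= 0 for b in self.birth) or any(d <= 0 for d in self.death):
            raise ValueError("all birth and death weights must be positive")
        for name in ("m_oj", "m_ot", "m_jjt", "m_ttj"):
            m = getattr(self, name)
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {m}")
        if self.m_oj + self.m_ot > 1.0 + 1e-12:
            raise ValueError("m_oj + m_ot must not exceed 1")
        if self.n < 2:
            raise ValueError("population size must be at least 2")

    def initial_state(self) -> "PopulationState":
        """All-wild-type population of size ``n``."""
        return PopulationState(self.n, 0, 0, 0, 0)


class PopulationState(tuple):
    """Cell counts ``(n_O, n_J, n_T, n_JT, n_TJ)``."""

    __slots__ = ()

    def __new__(cls, n_o: int, n_j: int, n_t: int, n_jt: int = 0, n_tj: int = 0):
        counts = (int(n_o), int(n_j), int(n_t), int(n_jt), int(n_tj))
        if any(c < 0 for c in counts):
            raise ValueError("cell counts must be non-negative")
        return super().__new__(cls, counts)

    n_o = property(lambda self: self[0])
    n_j = property(lambda self: self[1])
    n_t = property(lambda self: self[2])
    n_jt = property(lambda self: self[3])
    n_tj = property(lambda self: self[4])

    @property
    def total(self) -> int:
        return sum(self)

    def replace(self, i: int, delta: int) -> "PopulationState":
        counts = list(self)
        counts[i] += delta
        return PopulationState(*counts)


@dataclass(frozen=True)
class TransitionDistribution:
    """One-step successor distribution of a population state."""

    state: PopulationState
    successors: tuple[tuple[PopulationState, float], ...]

    def as_dict(self) -> dict[PopulationState, float]:
        return dict(self.successors)

    def total(self) -> float:
        return sum(p for _, p in self.successors)


@dataclass(frozen=True)
class AbsorptionRecord:
    """Outcome of a single Monte-Carlo run, recorded post-step.

    ``count`` is ``n_J`` for a JAK2-first outcome and ``n_T`` for a
    TET2-first outcome; it is ``None`` for ambiguous outcomes.
    """

    outcome: AbsorptionClass
    count: int | None
    time: int
    state: PopulationState


@dataclass
class AbsorptionDistribution:
    """Joint absorption law from exact propagation.

    Per class the marginal mass over the single-mutant count at
    absorption (``count_pmf``, indexed 0..n) and over the absorption
    step (``time_pmf``, indexed from step 1) are stored; ``class_mass``
    holds the total probability of each class, including ambiguous
    outcomes.  ``residual_survival`` is the unabsorbed mass left when
    propagation stopped after ``steps`` steps.
    """

    n: int
    class_mass: dict[AbsorptionClass, float]
    count_pmf: dict[AbsorptionClass, np.ndarray]
    time_pmf: dict[AbsorptionClass, np.ndarray]
    residual_survival: float
    steps: int
    survival_history: np.ndarray

    def total_mass(self) -> float:
        return sum(self.class_mass.values()) + self.residual_survival


@dataclass(frozen=True)
class ClassStatistics:
    """Conditional statistics of one pure absorption class."""

    probability: float
    mean_count: float
    sd_count: float
    mean_time: float
    sd_time: float


@dataclass(frozen=True)
class AbsorptionStatistics:
    jak2_first: ClassStatistics
    tet2_first: ClassStatistics
    ambiguous_probability: float
    residual_survival: float


#: Published example parameter rows (all death coefficients 1).
SCENARIOS: dict[str, dict] = {
    "A": dict(birth=(1, 2, 4, 4, 4), m_oj=0.1, m_ot=0.1, m_jjt=0.1, m_ttj=0.1),
    "B": dict(birth=(1, 2, 2, 2, 2), m_oj=0.1, m_ot=0.2, m_jjt=0.2, m_ttj=0.1),
    "C": dict(birth=(1, 2, 2, 2, 2), m_oj=0.1, m_ot=0.1, m_jjt=0.2, m_ttj=0.1),
}


def make_scenario(name: str, n: int = 100) -> MoranParameters:
    """Parameters of one of the published mechanism presets A, B or C."""
    try:
        row = SCENARIOS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None
    return MoranParameters(n=n, **row)


def _birth_outcome_weights(
    counts: Sequence[int], params: MoranParameters
) -> list[tuple[int, float]]:
    """Unnormalized weights of the daughter type added by a division.

    ``counts`` are the per-type cell counts eligible for division.
    Returns ``(type_index, weight)`` pairs; weights sum to the total
    birth weight of ``counts``.
    """
    o, j, t, jt, tj = counts
    b = params.birth
    return [
        (0, o * b[0] * (1.0 - params.m_oj - params.m_ot)),
        (1, o * b[0] * params.m_oj + j * b[1] * (1.0 - params.m_jjt)),
        (2, o * b[0] * params.m_ot + t * b[2] * (1.0 - params.m_ttj)),
        (3, j * b[1] * params.m_jjt + jt * b[3]),
        (4, t * b[2] * params.m_ttj + tj * b[4]),
    ]


def step_distribution(
    state: PopulationState, params: MoranParameters
) -> TransitionDistribution:
    """Exact one-step transition distribution from ``state``.

    Composes the death marginal (weights ``n_i d_i``) with the division
    outcome drawn among the remaining ``n - 1`` cells; successors that
    coincide are merged.
    """
    if state.total != params.n:
        raise ValueError(f"state sums to {state.total}, expected n={params.n}")
    death_total = sum(c * d for c, d in zip(state, params.death))
    if death_total <= 0:
        raise ValueError("no cell available for removal")
    probs: dict[PopulationState, float] = {}
    for i, (count, dw) in enumerate(zip(state, params.death)):
        if count == 0:
            continue
        p_death = count * dw / death_total
        reduced = state.replace(i, -1)
        outcomes = _birth_outcome_weights(reduced, params)
        birth_total = sum(w for _, w in outcomes)
        if birth_total <= 0:
            raise ValueError("no cell available for division")
        for k, w in outcomes:
            if w == 0.0:
                continue
            succ = reduced.replace(k, +1)
            probs[succ] = probs.get(succ, 0.0) + p_death * w / birth_total
    ordered = tuple(sorted(probs.items()))
    return TransitionDistribution(state=state, successors=ordered)


def _classify(state: PopulationState) -> AbsorptionClass:
    if state.n_jt >= 1 and state.n_t == 0 and state.n_tj == 0:
        return AbsorptionClass.JAK2_FIRST
    if state.n_tj >= 1 and state.n_j == 0 and state.n_jt == 0:
        return AbsorptionClass.TET2_FIRST
    return AbsorptionClass.AMBIGUOUS


def simulate(
    params: MoranParameters,
    seed: int | np.random.Generator,
    initial: PopulationState | None = None,
    max_steps: int | None = None,
) -> AbsorptionRecord:
    """Monte-Carlo run until the first double mutant appears.

    Sampling uses the exact per-step probabilities: the removed cell is
    drawn from the death weights, then the dividing cell from the birth
    weights of the remaining population.  ``seed`` may be an integer or
    a ``numpy.random.Generator`` (reused across replicates).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    state = initial if initial is not None else params.initial_state()
    if state.total != params.n:
        raise ValueError(f"initial state sums to {state.total}, expected {params.n}")
    b, d = params.birth, params.death
    step = 0
    counts = list(state)
    while counts[3] == 0 and counts[4] == 0:
        if max_steps is not None and step >= max_steps:
            raise AbsorptionTimeoutError(
                f"no double mutant after {max_steps} steps"
            )
        step += 1
        # death draw
        dw = [c * w for c, w in zip(counts, d)]
        total = sum(dw)
        u = rng.random() * total
        acc = 0.0
        for i, w in enumerate(dw):
            acc += w
            if u < acc:
                break
        counts[i] -= 1
        # division draw among the remaining cells
        outcomes = _birth_outcome_weights(counts, params)
        total = sum(w for _, w in outcomes)
        u = rng.random() * total
        acc = 0.0
        for k, w in outcomes:
            acc += w
            if u < acc:
                break
        counts[k] += 1
    final = PopulationState(*counts)
    outcome = _classify(final)
    if outcome is AbsorptionClass.JAK2_FIRST:
        count: int | None = final.n_j
    elif outcome is AbsorptionClass.TET2_FIRST:
        count = final.n_t
    else:
        count = None
    return AbsorptionRecord(outcome=outcome, count=count, time=step, state=final)


def propagate_exact(
    params: MoranParameters,
    survival_tol: float = 1e-8,
    min_steps: int = 400,
    max_steps: int = 10**6,
) -> AbsorptionDistribution:
    """Deterministic propagation of the transient state probabilities.

    The transient chain lives on the ``(n_J, n_T)`` grid with
    ``n_J + n_T <= n`` (``n_O`` implied); at each step the mass flowing
    into an absorbing event (a JT or TJ daughter) is recorded jointly
    with the post-step single-mutant counts and the step index.
    Propagation stops once the survival probability drops below
    ``survival_tol`` *and* more than ``min_steps`` steps were taken.
    """
    if not 0.0 < survival_tol < 1.0:
        raise ValueError("survival_tol must lie in (0, 1)")
    if min_steps < 0:
        raise ValueError("min_steps must be non-negative")
    n = params.n
    bO, bJ, bT, _, _ = params.birth
    dO, dJ, dT, _, _ = params.death
    idx = np.arange(n + 1)
    J, T = np.meshgrid(idx, idx, indexing="ij")
    valid = (J + T) <= n
    O = np.where(valid, n - J - T, 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        death_w = O * dO + J * dJ + T * dT
        p_death = {
            "O": np.where(valid & (death_w > 0), O * dO / death_w, 0.0),
            "J": np.where(valid & (death_w > 0), J * dJ / death_w, 0.0),
            "T": np.where(valid & (death_w > 0), T * dT / death_w, 0.0),
        }
    death_delta = {"O": (0, 0), "J": (-1, 0), "T": (0, -1)}

    # Division-outcome probabilities conditioned on the death type: the
    # removed cell does not divide, so weights come from the reduced counts.
    p_birth: dict[str, dict[str, np.ndarray]] = {}
    for dname, (dj, dt) in death_delta.items():
        Ob = O - (1 if dname == "O" else 0)
        Jb = J + dj
        Tb = T + dt
        Ob = np.clip(Ob, 0, None)
        Jb = np.clip(Jb, 0, None)
        Tb = np.clip(Tb, 0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            B = Ob * bO + Jb * bJ + Tb * bT
            ok = valid & (B > 0)
            p_birth[dname] = {
                "O": np.where(ok, Ob * bO * (1 - params.m_oj - params.m_ot) / B, 0.0),
                "J": np.where(
                    ok, (Ob * bO * params.m_oj + Jb * bJ * (1 - params.m_jjt)) / B, 0.0
                ),
                "T": np.where(
                    ok, (Ob * bO * params.m_ot + Tb * bT * (1 - params.m_ttj)) / B, 0.0
                ),
                "JT": np.where(ok, Jb * bJ * params.m_jjt / B, 0.0),
                "TJ": np.where(ok, Tb * bT * params.m_ttj / B, 0.0),
            }
    birth_delta = {"O": (0, 0), "J": (1, 0), "T": (0, 1)}

    p = np.zeros((n + 1, n + 1))
    p[0, 0] = 1.0

    class_mass = {c: 0.0 for c in AbsorptionClass}
    count_pmf = {
        AbsorptionClass.JAK2_FIRST: np.zeros(n + 1),
        AbsorptionClass.TET2_FIRST: np.zeros(n + 1),
    }
    time_mass: dict[AbsorptionClass, list[float]] = {
        AbsorptionClass.JAK2_FIRST: [],
        AbsorptionClass.TET2_FIRST: [],
        AbsorptionClass.AMBIGUOUS: [],
    }
    survival_history = []

    def shift_add(dst: np.ndarray, src: np.ndarray, sj: int, st: int) -> None:
        m = n + 1
        dst[max(0, sj) : m - max(0, -sj), max(0, st) : m - max(0, -st)] += src[
            max(0, -sj) : m - max(0, sj), max(0, -st) : m - max(0, st)
        ]

    step = 0
    survival = 1.0
    while survival >= survival_tol or step <= min_steps:
        if step >= max_steps:
            raise PropagationError(
                f"survival probability {survival:.3e} still above "
                f"{survival_tol:.1e} after {max_steps} steps"
            )
        step += 1
        new_p = np.zeros_like(p)
        jt_step = {c: 0.0 for c in AbsorptionClass}
        for dname, (dj, dt) in death_delta.items():
            w = p * p_death[dname]
            pb = p_birth[dname]
            for aname, (aj, at) in birth_delta.items():
                shift_add(new_p, w * pb[aname], dj + aj, dt + at)
            # Absorbing events: post-step counts are the pre-step counts
            # adjusted for the simultaneous death.
            j_post = J + dj
            t_post = T + dt
            m_jt = w * pb["JT"]
            pure = valid & (t_post == 0)
            pure_mass = m_jt[pure]
            np.add.at(count_pmf[AbsorptionClass.JAK2_FIRST], j_post[pure], pure_mass)
            jt_step[AbsorptionClass.JAK2_FIRST] += float(pure_mass.sum())
            jt_step[AbsorptionClass.AMBIGUOUS] += float(m_jt[valid & (t_post > 0)].sum())
            m_tj = w * pb["TJ"]
            pure = valid & (j_post == 0)
            pure_mass = m_tj[pure]
            np.add.at(count_pmf[AbsorptionClass.TET2_FIRST], t_post[pure], pure_mass)
            jt_step[AbsorptionClass.TET2_FIRST] += float(pure_mass.sum())
            jt_step[AbsorptionClass.AMBIGUOUS] += float(m_tj[valid & (j_post > 0)].sum())
        for c in AbsorptionClass:
            class_mass[c] += jt_step[c]
            time_mass[c].append(jt_step[c])
        p = new_p
        survival = float(p.sum())
        survival_history.append(survival)

    logger.info(
        "exact propagation: n=%d, %d steps, residual survival %.3e", n, step, survival
    )
    time_pmf = {
        c: np.asarray(time_mass[c])
        for c in (AbsorptionClass.JAK2_FIRST, AbsorptionClass.TET2_FIRST)
    }
    return AbsorptionDistribution(
        n=n,
        class_mass=class_mass,
        count_pmf=count_pmf,
        time_pmf=time_pmf,
        residual_survival=survival,
        steps=step,
        survival_history=np.asarray(survival_history),
    )


def _moments(pmf: np.ndarray, support: np.ndarray) -> tuple[float, float]:
    mass = pmf.sum()
    mean = float((pmf * support).sum() / mass)
    var = float((pmf * support**2).sum() / mass - mean**2)
    return mean, math.sqrt(max(var, 0.0))


def absorption_statistics(dist: AbsorptionDistribution) -> AbsorptionStatistics:
    """Conditional mean/sd of count and absorption time per pure class."""
    per_class = {}
    for c in (AbsorptionClass.JAK2_FIRST, AbsorptionClass.TET2_FIRST):
        mass = dist.class_mass[c]
        if mass <= 0.0:
            raise ValueError(f"no probability mass in class {c.value}")
        counts = dist.count_pmf[c]
        mean_c, sd_c = _moments(counts, np.arange(len(counts)))
        times = dist.time_pmf[c]
        mean_t, sd_t = _moments(times, np.arange(1, len(times) + 1))
        per_class[c] = ClassStatistics(
            probability=mass,
            mean_count=mean_c,
            sd_count=sd_c,
            mean_time=mean_t,
            sd_time=sd_t,
        )
    return AbsorptionStatistics(
        jak2_first=per_class[AbsorptionClass.JAK2_FIRST],
        tet2_first=per_class[AbsorptionClass.TET2_FIRST],
        ambiguous_probability=dist.class_mass[AbsorptionClass.AMBIGUOUS],
        residual_survival=dist.residual_survival,
    )


def system_size_sweep(
    scenario: str,
    n_list: Iterable[int],
    survival_tol: float = 1e-8,
    min_steps: int = 400,
) -> pd.DataFrame:
    """Exact conditional statistics for a scenario across population sizes."""
    rows = []
    for n in n_list:
        params = make_scenario(scenario, n=n)
        dist = propagate_exact(params, survival_tol=survival_tol, min_steps=min_steps)
        stats = absorption_statistics(dist)
        for cls, s in (
            (AbsorptionClass.JAK2_FIRST, stats.jak2_first),
            (AbsorptionClass.TET2_FIRST, stats.tet2_first),
        ):
            rows.append(
                dict(
                    n=n,
                    outcome=cls.value,
                    mean_count=s.mean_count,
                    sd_count=s.sd_count,
                    mean_T=s.mean_time,
                    sd_T=s.sd_time,
                    class_probability=s.probability,
                )
            )
    return pd.DataFrame(rows)


def required_sample_size(
    mean_1: float,
    sd_1: float,
    mean_2: float,
    sd_2: float,
    alpha: float = 0.01,
    power: float = 0.80,
) -> int:
    """Per-group sample size for a two-sided two-sample t-test.

    Uses the normal-approximation formula
    ``n = (z_{1-alpha/2} + z_{power})^2 (s1^2 + s2^2) / delta^2``,
    rounded up and floored at 2.
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    if sd_1 <= 0 or sd_2 <= 0:
        raise ValueError("standard deviations must be positive")
    delta = mean_1 - mean_2
    if delta == 0:
        raise ValueError("means are equal; no sample size resolves the difference")
    z = _sstats.norm.ppf
    n = (z(1 - alpha / 2.0) + z(power)) ** 2 * (sd_1**2 + sd_2**2) / delta**2
    return max(2, math.ceil(n))
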