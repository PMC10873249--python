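"""Deterministic report generation.

All tabular output is CSV with a ``#``-prefixed metadata header (tool
version, seed, tolerances) followed by a normal header row; numbers are
formatted with 6 significant digits so regenerated reports are
byte-identical.  A JSON mirror of every table is available.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__
from .bistable import (
    COUPLED_PRESET,
    REGULATION_PRESETS,
    AutoregCubic,
    MutationState,
    RegulationSpec,
    coupled_steady_states,
    find_fixed_points,
    mutation_trajectory_steady_states,
)
from .moran import (
    AbsorptionClass,
    absorption_statistics,
    make_scenario,
    propagate_exact,
)

__all__ = [
    "format_number",
    "write_table",
    "bifurcation_table",
    "scenario_table",
    "moran_statistics_table",
    "reproduce_paper",
]

_STATE_ORDER = ("O", "J", "T", "JT", "TJ")


def format_number(value) -> str:
    """Fixed 6-significant-digit formatting used in every report."""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{float(value):.6g}"


def write_table(
    path: str | Path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    metadata: Mapping[str, object],
    fmt: str = "csv",
) -> Path:
    """Write rows as CSV (with ``#`` metadata header) or JSON."""
    path = Path(path)
    rows = [list(r) for r in rows]
    if fmt == "csv":
        lines = [f"# {k}: {v}" for k, v in metadata.items()]
        lines.append(",".join(columns))
        for row in rows:
            lines.append(",".join(format_number(v) if not isinstance(v, str) else v for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "metadata": dict(metadata),
            "columns": list(columns),
            "rows": [
                [v if isinstance(v, str) else float(format_number(v)) for v in row]
                for row in rows
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    return path


def bifurcation_table(
    lam_min: float,
    lam_max: float,
    step: float,
    cubic: AutoregCubic | None = None,
) -> list[tuple[float, float, str]]:
    """Rows ``(lambda, x_star, stability)`` over a production-rate grid."""
    cubic = cubic or AutoregCubic.default()
    if step <= 0:
        raise ValueError("step must be positive")
    rows = []
    n_steps = int(round((lam_max - lam_min) / step))
    for i in range(n_steps + 1):
        lam = lam_min + i * step
        for point in find_fixed_points(lam, cubic):
            rows.append((lam, point.x, "stable" if point.stable else "unstable"))
    return rows


def scenario_table(
    preset: str, cubic: AutoregCubic | None = None
) -> list[tuple[str, float, float]] | list[tuple[str, float, float, float]]:
    """Steady-state rows for a named scenario preset.

    Boolean-control presets yield ``(state, lambda, x_star)``; the
    coupled preset ``fig3`` yields ``(state, lambda_y, y_star, x_star)``.
    """
    if preset == "fig3":
        y, x = coupled_steady_states(COUPLED_PRESET)
        reg = COUPLED_PRESET.regulation
        return [
            (s, reg.rate(MutationState(s)), y[MutationState(s)], x[MutationState(s)])
            for s in _STATE_ORDER
        ]
    try:
        spec = REGULATION_PRESETS[preset]
    except KeyError:
        known = sorted(REGULATION_PRESETS) + ["fig3"]
        raise ValueError(f"unknown preset {preset!r}; expected one of {known}") from None
    table = mutation_trajectory_steady_states(spec, cubic)
    return [
        (s, spec.rate(MutationState(s)), table[MutationState(s)]) for s in _STATE_ORDER
    ]


def moran_statistics_table(
    scenarios: Sequence[str] = ("A", "B", "C"),
    n: int = 100,
    survival_tol: float = 1e-8,
    min_steps: int = 400,
) -> list[tuple]:
    """Rows of conditional absorption statistics per scenario and class."""
    rows = []
    for name in scenarios:
        dist = propagate_exact(
            make_scenario(name, n=n), survival_tol=survival_tol, min_steps=min_steps
        )
        stats = absorption_statistics(dist)
        for cls, s in (
            (AbsorptionClass.JAK2_FIRST, stats.jak2_first),
            (AbsorptionClass.TET2_FIRST, stats.tet2_first),
        ):
            rows.append(
                (
                    name,
                    cls.value,
                    s.mean_count,
                    s.sd_count,
                    s.mean_time,
                    s.sd_time,
                    s.probability,
                    dist.residual_survival,
                )
            )
    return rows


def reproduce_paper(
    out_dir: str | Path, seed: int = 0, fmt: str = "csv"
) -> dict[str, Path]:
    """Regenerate every published figure/table quantity into ``out_dir``.

    Returns a mapping from report name to the written file.  All values
    are recomputed; the Moran table alone takes a few seconds per
    scenario at n=100.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if fmt == "csv" else "json"
    meta = {
        "generator": f"mutorder {__version__}",
        "seed": seed,
        "survival_tol": "1e-08",
        "min_steps": 400,
    }
    files: dict[str, Path] = {}

    files["fig1_bifurcation"] = write_table(
        out_dir / f"fig1_bifurcation.{ext}",
        ("lambda", "x_star", "stability"),
        bifurcation_table(0.0, 4.0, 0.01),
        meta,
        fmt,
    )

    rows2 = []
    for preset in ("fig2a", "fig2b", "fig2c", "fig2d"):
        for state, lam, x_star in scenario_table(preset):
            rows2.append((preset, state, lam, x_star))
    files["fig2_scenarios"] = write_table(
        out_dir / f"fig2_scenarios.{ext}",
        ("preset", "state", "lambda", "x_star"),
        rows2,
        meta,
        fmt,
    )

    files["fig3_coupled"] = write_table(
        out_dir / f"fig3_coupled.{ext}",
        ("state", "lambda_y", "y_star", "x_star"),
        scenario_table("fig3"),
        meta,
        fmt,
    )

    rows4 = []
    for preset in ("fig4a", "fig4b"):
        for state, lam, x_star in scenario_table(preset):
            rows4.append((preset, state, lam, x_star))
    files["fig4_order"] = write_table(
        out_dir / f"fig4_order.{ext}",
        ("preset", "state", "lambda", "x_star"),
        rows4,
        meta,
        fmt,
    )

    files["table3_moran"] = write_table(
        out_dir / f"table3_moran.{ext}",
        (
            "scenario",
            "outcome",
            "mean_count",
            "sd_count",
            "mean_T",
            "sd_T",
            "class_probability",
            "residual_survival",
        ),
        moran_statistics_table(),
        meta,
        fmt,
    )
    return files
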