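"""Multi-method shimming comparison over a cohort, with paired statistics.

The roster mirrors the standard evaluation protocol for head shim hardware:
static second-order SH shimming (S2) as the clinical baseline, S2 plus a
static multi-coil array (S2+MC8/32/48), dynamic slice-based SH shimming of
increasing order (D1/D2/D3), and dynamic first-order SH combined with an
array (D1+MC8/32/48).  All methods beyond the raw baseline operate on the
second-order-removed map.

The default comparison arrays are *nested* stand-ins (MC8 is the eight
channel ring design; MC32 adds 24 grid loops; MC48 adds 16 more), so that
channel-count monotonicity of the optimal residual holds by construction —
the published high-count array wire paths are not reproduced here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coils import LoopElement, MCArrayGeometry, build_cylindrical_grid_array, build_mc_array
from .errors import ConfigError
from .fieldmap import FieldMap
from .solver import compose_method

log = logging.getLogger(__name__)

FULL_ROSTER = (
    "baseline",
    "S2",
    "S2+MC8",
    "S2+MC32",
    "S2+MC48",
    "D1",
    "D2",
    "D3",
    "D1+MC8",
    "D1+MC32",
    "D1+MC48",
)


def default_arrays() -> dict[str, list[LoopElement]]:
    """Nested MC8 / MC32 / MC48 stand-in arrays.

    MC8 is the optimized eight-channel ring design (50 turns, 37 cm former).
    MC32 = MC8 + 24 single-turn-style grid loops (3 rows x 8, 30 cm former,
    20 turns); MC48 = MC32 + 16 interleaved grid loops.  Nesting guarantees
    that every smaller array's shim settings remain feasible for the larger
    one.
    """
    mc8 = build_mc_array(MCArrayGeometry())
    grid24 = build_cylindrical_grid_array(
        n_rows=3, n_per_row=8, former_diameter=300.0, loop_radius=30.0,
        turns=20, z_span=270.0, z_center=0.0,
    )
    grid16 = build_cylindrical_grid_array(
        n_rows=2, n_per_row=8, former_diameter=300.0, loop_radius=30.0,
        turns=20, z_span=180.0, z_center=0.0, azimuth_offset_deg=22.5,
    )
    mc32 = mc8 + grid24
    mc48 = mc32 + grid16
    return {"MC8": mc8, "MC32": mc32, "MC48": mc48}


@dataclass
class ComparisonTable:
    """Subjects x methods table of residual stds (Hz), plus summary rows."""

    data: pd.DataFrame  # index: subject, columns: method labels

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ConfigError("comparison table has missing cells")
        if (self.data.values < 0).any():
            raise ConfigError("residual stds must be nonnegative")

    @property
    def mean(self) -> pd.Series:
        return self.data.mean(axis=0)

    @property
    def sem(self) -> pd.Series:
        """Standard error over subjects, sd/sqrt(n)."""
        return self.data.std(axis=0, ddof=1) / np.sqrt(len(self.data))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_hz": self.mean, "sem_hz": self.sem})


def run_comparison(
    cohort: list[FieldMap],
    roster: tuple[str, ...] = FULL_ROSTER,
    arrays: dict[str, list[LoopElement]] | None = None,
    current_limit: float = 2.5,
    window: int = 1,
    n_segments: int = 64,
) -> ComparisonTable:
    """Residual std of every roster method on every cohort subject."""
    unknown = [m for m in roster if m != "baseline" and m not in FULL_ROSTER]
    if unknown:
        raise ConfigError(f"unknown method labels {unknown}; roster: {FULL_ROSTER}")
    if arrays is None:
        arrays = default_arrays()
    rows = []
    for i, fm in enumerate(cohort):
        cache: dict[str, object] = {}
        row = {}
        for label in roster:
            result = compose_method(
                fm,
                label,
                arrays=arrays,
                current_limit=current_limit,
                window=window,
                n_segments=n_segments,
                precomputed_bases=cache,  # type: ignore[arg-type]
            )
            row[label] = result.residual_std
        log.info("subject %d: %s", i, {k: round(v, 2) for k, v in row.items()})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(roster))
    df.index.name = "subject"
    return ComparisonTable(data=df)


def paired_tests(table: ComparisonTable, alpha_family: float = 0.05) -> pd.DataFrame:
    """All pairwise two-sided paired t tests with Bonferroni correction.

    The family threshold is ``alpha_family / n_pairs`` with ``n_pairs``
    derived from the methods actually compared.  Zero-variance differences
    are reported with p = 1 and flagged degenerate.
    """
    methods = list(table.data.columns)
    if len(table.data) < 2 or len(methods) < 2:
        raise ConfigError("need >= 2 subjects and >= 2 methods for paired tests")
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    threshold = alpha_family / len(pairs)
    records = []
    for a, b in pairs:
        diff = table.data[a].values - table.data[b].values
        degenerate = bool(np.allclose(diff, diff[0]) and np.isclose(np.std(diff), 0.0))
        if degenerate:
            t_stat, p = np.nan, 1.0
        else:
            t_stat, p = stats.ttest_rel(table.data[a], table.data[b])
        records.append(
            {
                "method_a": a,
                "method_b": b,
                "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
                "p": float(p),
                "significant": bool(p < threshold),
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["alpha_family"] = alpha_family
    df.attrs["n_pairs"] = len(pairs)
    df.attrs["threshold"] = threshold
    return df


def report(
    table: ComparisonTable,
    tests: pd.DataFrame | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the table as CSV, a JSON summary and a mean +- SE bar chart."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {outdir}: {exc}") from exc
    files: dict[str, Path] = {}
    files["table"] = outdir / "comparison.csv"
    table.data.to_csv(files["table"])
    files["summary"] = outdir / "summary.json"
    summary = {
        "methods": {
            m: {"mean_hz": float(table.mean[m]), "sem_hz": float(table.sem[m])}
            for m in table.data.columns
        },
        "n_subjects": int(len(table.data)),
    }
    if tests is not None:
        files["tests"] = outdir / "paired_tests.csv"
        tests.to_csv(files["tests"], index=False)
        summary["alpha_family"] = tests.attrs.get("alpha_family")
        summary["bonferroni_threshold"] = tests.attrs.get("threshold")
    files["summary"].write_text(json.dumps(summary, indent=2))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(
        table.data.columns,
        table.mean,
        yerr=table.sem,
        capsize=3,
        color="steelblue",
    )
    ax.set_ylabel("residual field std (Hz)")
    ax.set_title(f"Shim performance over {len(table.data)} synthetic subjects (mean ± SE)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    files["chart"] = outdir / "comparison.png"
    fig.savefig(files["chart"], dpi=120)
    plt.close(fig)
    return files


def read_comparison_csv(path: str | Path) -> ComparisonTable:
    df = pd.read_csv(path, index_col=0)
    return ComparisonTable(data=df)
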