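"""Report assembly: the summary/comparison tables of a profiled library.

Builds the standard deliverables of a property-profiling study from a
profile table (see :func:`drugspace.pipeline.profile_records`):

* full-set descriptor summary (mean/SD/50-75-90th percentiles),
* the same summary for the Lipinski-fail subset,
* flexibility/saturation summary (rotatable bonds, aromatic rings, Fsp3),
* macrocycle subset summary,
* pairwise descriptor r^2 correlations,
* per-period approval/fail trend table,
* the NPR point cloud (with pass/fail labels) for shape plotting.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import (
    DEFAULT_QUANTILE_METHOD,
    correlation_matrix,
    summary_table,
    temporal_trend,
)

RO5_COLUMNS = ("mwt", "clogp", "hbd", "hba")
SHAPE2D_COLUMNS = ("rotatable_bonds", "aromatic_rings", "fsp3")


def build_report(
    profile: pd.DataFrame,
    shape: pd.DataFrame | None = None,
    method: str = DEFAULT_QUANTILE_METHOD,
) -> dict[str, pd.DataFrame]:
    """Assemble all report tables from a profile table.

    ``shape`` is an optional per-compound table with ``id``,
    ``npr1_boltzmann`` and ``npr2_boltzmann`` columns from the 3D layer;
    when given, a pass/fail-labelled NPR point cloud is included.
    """
    ok = profile[~profile["descriptor_failure"].astype(bool)].copy()
    fails = ok[ok["lipinski_fail"].astype(bool)]
    macro = ok[ok["macrocycle"].astype(bool)]

    tables = {
        "table1": summary_table(ok, RO5_COLUMNS, method=method),
        "table3": summary_table(ok, SHAPE2D_COLUMNS, method=method),
        "correlations": correlation_matrix(ok, RO5_COLUMNS),
        "trends": temporal_trend(ok),
    }
    if len(fails):
        tables["table2"] = summary_table(fails, RO5_COLUMNS, method=method)
    if len(macro):
        tables["table4"] = summary_table(
            macro, RO5_COLUMNS + ("rotatable_bonds", "aromatic_rings"), method=method
        )
    if shape is not None:
        pts = shape.merge(
            ok[["id", "lipinski_fail"]], on="id", how="inner", validate="1:1"
        )
        tables["pmi_points"] = pts[
            ["id", "npr1_boltzmann", "npr2_boltzmann", "lipinski_fail"]
        ].rename(columns={"lipinski_fail": "fail"})
    return tables


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv")
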