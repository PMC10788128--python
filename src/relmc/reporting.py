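"""Wide table layouts, CSV output and run manifests.

The tidy criterion table from :func:`relmc.engine.run_grid` is the
canonical record; the wide layouts mirror how simulation results for
reliability indices are conventionally printed (rows = length x sample
size [x condition], columns = estimators, cells = percentages with two
decimals).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "wide_table",
    "format_percent",
    "write_run",
    "read_tidy",
]

_ESTIMATOR_LABEL = {"alpha": "Alpha", "omega": "Omega", "glb": "GLB", "glba": "GLBa"}
_ESTIMATOR_ORDER = ["Alpha", "Omega", "GLB", "GLBa"]

#: criteria whose raw values are fractions and are printed x100
_FRACTION_CRITERIA = {"fpm", "fnm", "rmse"}


def _percent_value(row) -> float:
    v = row["value"]
    return v * 100.0 if row["criterion"] in _FRACTION_CRITERIA else v


def wide_table(tidy: pd.DataFrame, criterion: str) -> pd.DataFrame:
    """Pivot a tidy table to the conventional wide layout for one criterion.

    Index columns are ``k`` and ``n`` (plus ``model`` and
    ``true_reliability`` when several populations appear); estimator
    columns hold percentages.
    """
    sub = tidy[tidy["criterion"] == criterion].copy()
    if sub.empty:
        raise ValueError(f"criterion {criterion!r} not present in table")
    sub["pct"] = sub.apply(_percent_value, axis=1)
    sub["Estimator"] = sub["estimator"].map(lambda e: _ESTIMATOR_LABEL.get(e, e))
    index = ["k", "n"]
    if sub["model"].nunique() > 1:
        index.append("model")
    if sub["true_reliability"].nunique() > 1:
        index.append("true_reliability")
    wide = sub.pivot_table(index=index, columns="Estimator", values="pct")
    cols = [c for c in _ESTIMATOR_ORDER if c in wide.columns] + [
        c for c in wide.columns if c not in _ESTIMATOR_ORDER
    ]
    wide = wide[cols].sort_index()
    wide.columns.name = None
    return wide.reset_index()


def format_percent(wide: pd.DataFrame) -> pd.DataFrame:
    """Render estimator columns as two-decimal percent strings."""
    out = wide.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f" and col not in ("true_reliability",):
            out[col] = out[col].map(lambda v: f"{v:.2f}%")
    return out


_STUDY_TABLES = {
    "tn": [("rmse", "rmse"), ("pct_bias_absolute", "pct_bias")],
    "fpm": [("fpm", "fpm")],
    "fnm": [("fnm", "fnm")],
    "fpm_weak": [("fpm", "fpm_weak")],
}


def write_run(
    tidy: pd.DataFrame,
    outdir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write tidy CSV, wide-format CSVs and a JSON manifest to ``outdir``.

    Returns a mapping of artifact name to path.  Wide tables keep full
    precision; two-decimal rendering is left to :func:`format_percent`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tidy_path = outdir / "criteria_tidy.csv"
    tidy.to_csv(tidy_path, index=False)
    paths["tidy"] = tidy_path

    for study in tidy["study"].unique():
        sub = tidy[tidy["study"] == study]
        for criterion, stem in _STUDY_TABLES.get(study, []):
            if (sub["criterion"] == criterion).any():
                wide = wide_table(sub, criterion)
                p = outdir / f"{study}_{stem}_wide.csv"
                wide.to_csv(p, index=False)
                paths[f"{study}_{stem}"] = p

    if manifest is not None:
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        paths["manifest"] = mpath
    return paths


def read_tidy(path: str | Path) -> pd.DataFrame:
    """Re-read a tidy criterion CSV (round-trips with :func:`write_run`)."""
    return pd.read_csv(path)
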