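"""Reading and writing feature tables and fitted models.

The on-disk table format is a plain CSV with samples as rows: the first
column holds the sample id, followed by ``group`` and ``is_qc`` metadata
columns and one numeric column per feature.  A transposed layout (features
as rows, samples as columns, with ``group``/``is_qc`` as extra rows) is
supported through the ``orientation`` flag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .opls import OplsModel
from .tables import FeatureTable

__all__ = ["read_feature_table", "write_feature_table", "save_model", "load_model"]

_ORIENTATIONS = ("samples_rows", "features_rows")


def read_feature_table(path, orientation: str = "samples_rows") -> FeatureTable:
    """Parse a feature-table CSV into a validated :class:`FeatureTable`."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}; use one of {_ORIENTATIONS}")
    df = pd.read_csv(path, index_col=0)
    if orientation == "features_rows":
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids in {path}: {dupes}")
    for col in ("group", "is_qc"):
        if col not in df.columns:
            raise ValueError(f"feature table {path} lacks required column {col!r}")
    groups = df["group"].astype(str)
    is_qc = df["is_qc"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes", "1.0")
    )
    values = df.drop(columns=["group", "is_qc"])
    try:
        values = values.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric intensity cell in {path}: {exc}") from exc
    return FeatureTable(values, groups, is_qc)


def write_feature_table(
    table: FeatureTable, path, orientation: str = "samples_rows"
) -> None:
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}; use one of {_ORIENTATIONS}")
    df = pd.concat(
        [table.groups.rename("group"), table.is_qc.rename("is_qc"), table.values],
        axis=1,
    )
    df.index.name = "sample_id"
    if orientation == "features_rows":
        df = df.T
        df.index.name = "feature_id"
    df.to_csv(path)


def save_model(model: OplsModel, path) -> None:
    """Serialise a fitted OPLS-DA model (weights, scores, diagnostics) to JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path) -> OplsModel:
    d = json.loads(Path(path).read_text())
    n_ortho = len(d["w_ortho"])
    p = len(d["w"])
    n = len(d["t"])
    model = OplsModel(
        w=np.array(d["w"]),
        p=np.array(d["p"]),
        t=np.array(d["t"]),
        c=float(d["c"]),
        w_ortho=np.array(d["w_ortho"]).reshape(n_ortho, p),
        p_ortho=np.array(d["p_ortho"]).reshape(n_ortho, p),
        t_ortho=np.array(d["t_ortho"]).reshape(n_ortho, n),
        x_mean=np.array(d["x_mean"]),
        y_mean=float(d["y_mean"]),
        ss_x=float(d["ss_x"]),
        ss_y=float(d["ss_y"]),
        r2y=float(d["r2y"]),
        class_labels=tuple(d["class_labels"]) if d.get("class_labels") else None,
        feature_ids=pd.Index(d["feature_ids"]) if d.get("feature_ids") else None,
    )
    return model
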