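"""Result serialization: ensemble tables and run reports.

Ensembles are written as tab-separated tables (one row per parameter set:
linear-scale values at 17 significant digits, objective components, stage
label, acceptance flag); run reports are JSON with the fully resolved
configuration and all seeds, sufficient to replay a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .ensemble import ParameterEnsemble

__all__ = ["ensemble_to_frame", "write_ensemble", "read_ensemble", "write_report"]


def ensemble_to_frame(ens: ParameterEnsemble) -> pd.DataFrame:
    data: dict[str, Any] = {
        name: ens.values[:, j] for j, name in enumerate(ens.parameter_names)
    }
    if ens.objectives is not None:
        data["o_fix"] = ens.objectives[:, 0]
        data["o_basin"] = ens.objectives[:, 1]
        data["o_relax"] = ens.objectives[:, 2]
    data["stage"] = ens.stage_found
    if ens.accepted is not None:
        data["accepted"] = ens.accepted
    return pd.DataFrame(data)


def write_ensemble(ens: ParameterEnsemble, path) -> None:
    ensemble_to_frame(ens).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ensemble(path) -> ParameterEnsemble:
    df = pd.read_csv(path, sep="\t")
    meta = {"o_fix", "o_basin", "o_relax", "stage", "accepted"}
    names = tuple(c for c in df.columns if c not in meta)
    obj = None
    if {"o_fix", "o_basin", "o_relax"} <= set(df.columns):
        obj = df[["o_fix", "o_basin", "o_relax"]].to_numpy()
    return ParameterEnsemble(
        parameter_names=names,
        log10_values=np.log10(df[list(names)].to_numpy(dtype=float)),
        stage_found=list(df["stage"]) if "stage" in df else [],
        objectives=obj,
        accepted=df["accepted"].to_numpy(dtype=bool) if "accepted" in df else None,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (frozenset, set, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
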