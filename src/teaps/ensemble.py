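"""Parameter ensembles with provenance.

An ensemble is a collection of parameter sets found by a search, kept in
log10 scale (the searches' native coordinates) with per-set provenance:
the stage that produced the set, its objective components and whether it
passed the final acceptance filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import ParameterSet

__all__ = ["ParameterEnsemble"]


@dataclass
class ParameterEnsemble:
    parameter_names: tuple[str, ...]
    log10_values: np.ndarray                  # (m, n_params)
    stage_found: list[str] = field(default_factory=list)
    objectives: Optional[np.ndarray] = None   # (m, 3): o_fix, o_basin, o_relax
    accepted: Optional[np.ndarray] = None     # (m,) bool

    def __post_init__(self) -> None:
        self.log10_values = np.atleast_2d(np.asarray(self.log10_values, dtype=float))
        m = self.log10_values.shape[0]
        if not self.stage_found:
            self.stage_found = ["unknown"] * m
        if len(self.stage_found) != m:
            raise ValueError("stage_found length mismatch")
        if self.objectives is not None:
            obj = np.asarray(self.objectives, dtype=float)
            self.objectives = obj.reshape(m, -1) if obj.size else obj.reshape(m, 3)
        if self.accepted is not None:
            self.accepted = np.asarray(self.accepted, dtype=bool).reshape(m)

    def __len__(self) -> int:
        return self.log10_values.shape[0]

    @property
    def values(self) -> np.ndarray:
        """Parameter values in linear scale, (m, n_params)."""
        return 10.0**self.log10_values

    @property
    def sets(self) -> list[ParameterSet]:
        return [
            ParameterSet.from_array(self.parameter_names, row) for row in self.values
        ]

    def subset(self, mask) -> "ParameterEnsemble":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ParameterEnsemble(
            parameter_names=self.parameter_names,
            log10_values=self.log10_values[idx],
            stage_found=[self.stage_found[i] for i in idx],
            objectives=None if self.objectives is None else self.objectives[idx],
            accepted=None if self.accepted is None else self.accepted[idx],
        )

    @property
    def accepted_subset(self) -> "ParameterEnsemble":
        if self.accepted is None:
            raise ValueError("ensemble has no acceptance flags")
        return self.subset(self.accepted)

    def column(self, name: str, log10: bool = True) -> np.ndarray:
        j = self.parameter_names.index(name)
        col = self.log10_values[:, j]
        return col if log10 else 10.0**col

    @classmethod
    def concatenate(cls, parts: Sequence["ParameterEnsemble"]) -> "ParameterEnsemble":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("nothing to concatenate")
        names = parts[0].parameter_names
        if any(p.parameter_names != names for p in parts):
            raise ValueError("parameter name mismatch")
        has_obj = all(p.objectives is not None for p in parts)
        has_acc = all(p.accepted is not None for p in parts)
        return cls(
            parameter_names=names,
            log10_values=np.vstack([p.log10_values for p in parts]),
            stage_found=[s for p in parts for s in p.stage_found],
            objectives=np.vstack([p.objectives for p in parts]) if has_obj else None,
            accepted=np.concatenate([p.accepted for p in parts]) if has_acc else None,
        )
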