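"""Dose-ladder construction, DMSO normalization and combination matrices.

A combination experiment titrates two drugs against each other in an n×n
checkerboard (6×6 by default, three-fold dilution from a top dose anchored
near the IC50). The screened block is stored as a (n+1)×(n+1) surface with
explicit zero-dose edges: row/column 0 hold the monotherapy responses and
well (0, 0) the vehicle control, so every reference model can be evaluated
from the same plate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["DoseMatrix", "build_grid", "normalize_to_control", "assemble_matrix"]


def build_grid(top: float, factor: float = 3.0, n: int = 6) -> np.ndarray:
    """Descending dose ladder: ``dose[i] = top / factor**i`` for i in 0..n-1."""
    if top <= 0:
        raise ValueError("top dose must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 1:
        raise ValueError("need at least one dose level")
    return top / factor ** np.arange(n, dtype=float)


def normalize_to_control(raw, control_wells) -> np.ndarray:
    """Divide raw signal (RLU) by the mean of the vehicle-control wells.

    Values above 1 are legitimate (wells outgrowing the control) and are
    preserved.
    """
    controls = np.asarray(control_wells, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 control wells")
    mean = controls.mean()
    if mean <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(raw, dtype=float) / mean


@dataclass
class DoseMatrix:
    """One combination experiment on one culture.

    ``viability`` has shape (n_replicates, n+1, n+1); axis index 0 on each
    dose axis is dose zero, index i >= 1 the i-th smallest nonzero dose.
    Missing wells are NaN. ``doses_a``/``doses_b`` are the nonzero ladders
    in descending order, as dispensed.
    """

    culture: str
    drug_a: str
    drug_b: str
    doses_a: np.ndarray  # descending, length n
    doses_b: np.ndarray
    viability: np.ndarray  # (n_rep, n+1, n+1)
    missing_wells: list = field(default_factory=list)

    @property
    def axis_a(self) -> np.ndarray:
        """Ascending dose axis including the zero edge."""
        return np.concatenate([[0.0], np.sort(self.doses_a)])

    @property
    def axis_b(self) -> np.ndarray:
        return np.concatenate([[0.0], np.sort(self.doses_b)])

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[0]

    def replicate_mean(self) -> np.ndarray:
        """Per-well mean over replicates, NaN where all replicates missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.viability, axis=0)

    def combo_block(self) -> np.ndarray:
        """Replicate-mean viability over the n×n nonzero-dose block."""
        return self.replicate_mean()[1:, 1:]

    def mono_a(self) -> np.ndarray:
        """Replicate-mean monotherapy viability of drug A (ascending doses)."""
        return self.replicate_mean()[1:, 0]

    def mono_b(self) -> np.ndarray:
        return self.replicate_mean()[0, 1:]

    def validate(self, dilution_factor: Optional[float] = 3.0,
                 strict_control: bool = False) -> None:
        for name, ladder in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if np.any(ladder <= 0) or np.any(np.diff(ladder) >= 0):
                raise ValueError(f"{name} must be strictly decreasing and positive")
            if dilution_factor is not None and ladder.size > 1:
                ratios = ladder[:-1] / ladder[1:]
                if not np.allclose(ratios, dilution_factor, rtol=1e-9):
                    raise ValueError(
                        f"{name} is not a {dilution_factor}-fold ladder"
                    )
        if np.nanmin(self.viability) < 0:
            raise ValueError("viabilities must be non-negative")
        ctrl = self.replicate_mean()[0, 0]
        if not (0.9 <= ctrl <= 1.1):
            # an untreated well should sit at the control level; a breach is
            # usually a normalization bug, but technical noise at duplicate
            # depth crosses the band occasionally, so only strict mode raises
            msg = (f"control well mean {ctrl:.3f} outside [0.9, 1.1]; "
                   "check the normalization")
            if strict_control:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy export: one row per (dose_a, dose_b, replicate, viability)."""
        ax_a, ax_b = self.axis_a, self.axis_b
        rows = []
        for r in range(self.n_replicates):
            for i, da in enumerate(ax_a):
                for j, db in enumerate(ax_b):
                    rows.append((da, db, r, self.viability[r, i, j]))
        return pd.DataFrame(rows, columns=["dose_a", "dose_b", "replicate",
                                           "viability"])


def assemble_matrix(
    wells: Iterable[tuple[float, float, int, float]] | Mapping,
    culture: str = "",
    drug_a: str = "",
    drug_b: str = "",
    doses_a: Optional[Sequence[float]] = None,
    doses_b: Optional[Sequence[float]] = None,
    missing_policy: str = "mask",
    dilution_factor: Optional[float] = 3.0,
    max_missing_fraction: float = 0.2,
) -> DoseMatrix:
    """Assemble normalized wells keyed by (dose_a, dose_b, replicate).

    ``wells`` is an iterable of (dose_a, dose_b, replicate, viability)
    tuples or an equivalent mapping. The design must include the zero-dose
    edges. Missing wells are masked (NaN) under the default policy and an
    error under ``missing_policy="fail"``; silent imputation is never
    performed. If expected dose ladders are supplied, a mismatch with the
    observed doses (e.g. swapped axes) is an error.
    """
    if missing_policy not in ("mask", "fail"):
        raise ValueError(f"unknown missing-well policy {missing_policy!r}")
    if isinstance(wells, Mapping):
        items = [(da, db, r, v) for (da, db, r), v in wells.items()]
    else:
        items = list(wells)

    seen: dict[tuple[float, float, int], float] = {}
    for da, db, r, v in items:
        key = (float(da), float(db), int(r))
        if key in seen:
            raise ValueError(f"duplicate well key {key}")
        seen[key] = float(v)

    obs_a = np.array(sorted({k[0] for k in seen if k[0] > 0}))
    obs_b = np.array(sorted({k[1] for k in seen if k[1] > 0}))
    if obs_a.size == 0 or obs_b.size == 0:
        raise ValueError("no nonzero doses found on one or both axes")
    for expected, observed, name in ((doses_a, obs_a, "a"), (doses_b, obs_b, "b")):
        if expected is not None:
            exp = np.sort(np.asarray(expected, dtype=float))
            if exp.size != observed.size or not np.allclose(exp, observed,
                                                            rtol=1e-9):
                raise ValueError(
                    f"dose mismatch on axis {name}: expected {exp}, "
                    f"observed {observed} (swapped axes?)"
                )
    reps = sorted({k[2] for k in seen})
    ax_a = np.concatenate([[0.0], obs_a])
    ax_b = np.concatenate([[0.0], obs_b])
    ia = {d: i for i, d in enumerate(ax_a)}
    ib = {d: i for i, d in enumerate(ax_b)}
    ir = {r: i for i, r in enumerate(reps)}

    grid = np.full((len(reps), ax_a.size, ax_b.size), np.nan)
    for (da, db, r), v in seen.items():
        if da not in ia or db not in ib:
            raise ValueError(f"well dose ({da}, {db}) not on the dose axes")
        grid[ir[r], ia[da], ib[db]] = v

    missing = [
        (float(ax_a[i]), float(ax_b[j]), reps[r])
        for r in range(len(reps))
        for i in range(ax_a.size)
        for j in range(ax_b.size)
        if np.isnan(grid[r, i, j])
    ]
    frac_missing = len(missing) / grid.size
    if missing and missing_policy == "fail":
        raise ValueError(f"{len(missing)} missing wells under policy 'fail'")
    if frac_missing > max_missing_fraction:
        raise ValueError(
            f"{frac_missing:.0%} of wells missing exceeds the "
            f"{max_missing_fraction:.0%} limit"
        )

    matrix = DoseMatrix(
        culture=culture,
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=obs_a[::-1].copy(),
        doses_b=obs_b[::-1].copy(),
        viability=grid,
        missing_wells=missing,
    )
    matrix.validate(dilution_factor=dilution_factor)
    return matrix


def matrices_from_platemap(
    plates: pd.DataFrame, dilution_factor: Optional[float] = 3.0,
    missing_policy: str = "mask",
) -> dict[tuple[str, str, str], DoseMatrix]:
    """Normalize a plate-map table and assemble one DoseMatrix per experiment.

    Expects the columns {plate, well, culture, drug_a, dose_a_um, drug_b,
    dose_b_um, replicate, rlu, is_control}; control wells define the
    DMSO reference per plate. Returns matrices keyed by
    (culture, drug_a, drug_b).
    """
    required = {"plate", "culture", "drug_a", "dose_a_um", "drug_b",
                "dose_b_um", "replicate", "rlu", "is_control"}
    if not required.issubset(plates.columns):
        raise ValueError(f"plate map missing columns {required - set(plates.columns)}")
    out: dict[tuple[str, str, str], DoseMatrix] = {}
    for plate_id, plate in plates.groupby("plate", sort=True):
        controls = plate.loc[plate["is_control"], "rlu"].to_numpy()
        treated = plate.loc[~plate["is_control"]]
        viab = normalize_to_control(treated["rlu"].to_numpy(), controls)
        treated = treated.assign(viability=viab)
        for (culture, da, db), grp in treated.groupby(
            ["culture", "drug_a", "drug_b"], sort=True
        ):
            wells = list(zip(grp["dose_a_um"], grp["dose_b_um"],
                             grp["replicate"], grp["viability"]))
            out[(culture, da, db)] = assemble_matrix(
                wells, culture=culture, drug_a=da, drug_b=db,
                dilution_factor=dilution_factor, missing_policy=missing_policy,
            )
    return out
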