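"""Cohort-level summaries: driver-event frequencies and the screened panel.

The screen was designed against the genetic landscape of IDH-wildtype
glioblastoma: per-gene alteration frequencies in a clinical cohort decide
which targets are worth pairing, and the screened panel is summarized by
its split between combinations aimed at driver-gene products and the rest.
The 43-combination panel (drugs, targets and the external prediction
scores that ranked them) ships as a packaged fixture; the prediction model
itself is consumed, not reimplemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_CATEGORIES",
    "ComboRecord",
    "round_half_up",
    "event_frequencies",
    "selection_composition",
    "load_combination_panel",
]

EVENT_CATEGORIES = frozenset(
    {"amplification", "deep_deletion", "gain", "loss", "mutation", "none"}
)

#: Default driving-event rules. Oncogene activation counts amplification and
#: mutation; for tumor suppressors homozygous (deep) loss is the driving
#: event. IDH1 R132H and gene fusions are deliberately absent.
DEFAULT_DRIVER_RULES: dict[str, frozenset[str]] = {
    "EGFR": frozenset({"amplification", "mutation"}),
    "PDGFRA": frozenset({"amplification", "mutation"}),
    "PIK3CA": frozenset({"amplification", "mutation"}),
    "PIK3R1": frozenset({"mutation"}),
    "MDM2": frozenset({"amplification"}),
    "CDK4": frozenset({"amplification"}),
    "NF1": frozenset({"mutation", "deep_deletion"}),
    "CDKN2A": frozenset({"deep_deletion"}),
    "PTEN": frozenset({"deep_deletion", "mutation"}),
}


@dataclass(frozen=True)
class ComboRecord:
    """One screened drug pair with targets and its external prediction score."""

    index: int
    drug_1: str
    target_1: str
    drug_2: str
    target_2: str
    prediction_score: Optional[int]  # None = not calculated

    SCORE_RANGE = (0, 520)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (reporting style)."""
    return int(np.floor(x + 0.5))


def event_frequencies(
    table: pd.DataFrame,
    driver_rules: Mapping[str, frozenset[str] | set[str]] = DEFAULT_DRIVER_RULES,
) -> tuple[dict[str, int], pd.Series, int]:
    """Per-gene driving-event frequencies and the driver-negative fraction.

    ``table`` is long-format with columns {patient, gene, event}; each
    (patient, gene) pair carries exactly one category. Returns per-gene
    integer percentages of patients with a driving event, the per-patient
    driver-positive flag, and the integer percentage of driver-negative
    patients.
    """
    required = {"patient", "gene", "event"}
    if table.empty:
        raise ValueError("alteration table is empty")
    if not required.issubset(table.columns):
        raise ValueError(f"missing columns {required - set(table.columns)}")
    bad = set(table["event"]) - EVENT_CATEGORIES
    if bad:
        raise ValueError(f"unknown event categories: {sorted(bad)}")
    if table.duplicated(["patient", "gene"]).any():
        raise ValueError("each (patient, gene) must appear exactly once")

    n_patients = table["patient"].nunique()
    driving = table.apply(
        lambda r: r["event"] in driver_rules.get(r["gene"], frozenset()),
        axis=1,
    )
    per_gene = {
        gene: round_half_up(100.0 * grp.sum() / n_patients)
        for gene, grp in driving.groupby(table["gene"])
    }
    per_patient = driving.groupby(table["patient"]).any()
    pct_negative = round_half_up(100.0 * (~per_patient).sum() / n_patients)
    return per_gene, per_patient, pct_negative


def selection_composition(n_driver_combos: int, n_nondriver_combos: int
                          ) -> tuple[int, int]:
    """Integer-rounded percentage split of the panel (driver, non-driver)."""
    if n_driver_combos < 0 or n_nondriver_combos < 0:
        raise ValueError("counts must be non-negative")
    total = n_driver_combos + n_nondriver_combos
    if total == 0:
        raise ValueError("at least one count must be positive")
    return (round_half_up(100.0 * n_driver_combos / total),
            round_half_up(100.0 * n_nondriver_combos / total))


def load_combination_panel(path: Optional[str] = None) -> list[ComboRecord]:
    """Parse the packaged 43-combination panel fixture.

    The 'Not calculated' sentinel for prediction scores is preserved as
    None. Malformed rows raise with their row index.
    """
    if path is None:
        source = resources.files("synscreen.data") / "combination_panel.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["number", "drug_1", "target_1", "drug_2", "target_2",
                "prediction_score"]
    if list(df.columns) != expected:
        raise ValueError(f"fixture columns {list(df.columns)} != {expected}")
    records = []
    lo, hi = ComboRecord.SCORE_RANGE
    for i, row in df.iterrows():
        try:
            raw = row["prediction_score"].strip()
            if raw.lower() == "not calculated":
                score = None
            else:
                score = int(raw)
                if not lo <= score <= hi:
                    raise ValueError(f"score {score} outside [{lo}, {hi}]")
            records.append(ComboRecord(
                index=int(row["number"]),
                drug_1=row["drug_1"].strip(),
                target_1=row["target_1"].strip(),
                drug_2=row["drug_2"].strip(),
                target_2=row["target_2"].strip(),
                prediction_score=score,
            ))
        except (ValueError, AttributeError) as err:
            raise ValueError(f"malformed row {i}: {err}") from err
    return records
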