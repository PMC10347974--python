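"""Synthetic combination screens with known ground truth.

Every pipeline stage is testable without external data: the generator draws
per-drug, per-culture Hill monotherapy curves, anchors each 6×6 three-fold
checkerboard at the drug's absolute IC50 (a fixed 10 µM top dose when the
IC50 is never reached), builds combination responses as the Bliss product
``va * vb`` minus an injected interaction excess for a designated
synergistic subset, adds truncated Gaussian replicate noise, and emits raw
RLU plate maps with DMSO control wells so the normalization path is
exercised end to end. A dose-shift (Loewe-consistent) interaction mode is
available as an alternative to the Bliss-excess default.

The interaction weight peaks mid-grid by default so the zero-dose edges
remain honest monotherapies and the excess fades toward the dose extremes,
as a pharmacological interaction would.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .doseresponse import HillFit, absolute_ic50
from .grids import DoseMatrix, build_grid, matrices_from_platemap

__all__ = ["SynthConfig", "SynthScreen", "simulate_screen", "make_blobs"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a simulated screen.

    Defaults mirror the screened design: 6-point three-fold ladders in
    technical duplicate, replicate noise of 0.05 viability SD, and a
    Bliss-excess interaction of 0.15 injected into 10 of 40 combinations
    across 10 cultures.
    """

    n_combinations: int = 40
    n_cultures: int = 10
    n_synergistic: int = 10
    interaction_delta: float = 0.15  # per-well Bliss excess (viability)
    noise_sd: float = 0.05
    n_replicates: int = 2
    dilution_factor: float = 3.0
    n_levels: int = 6
    n_drugs: Optional[int] = None  # default: smallest pool with enough pairs
    e0_range: tuple[float, float] = (1.0, 1.0)  # DMSO-normalized plateau
    einf_range: tuple[float, float] = (0.0, 0.3)
    log10_ec50_range: tuple[float, float] = (-2.0, 0.0)  # µM
    h_range: tuple[float, float] = (0.8, 2.5)
    insensitive_top_dose: float = 10.0  # µM, when the IC50 is not reached
    interaction_mode: str = "bliss_excess"  # or "dose_shift"
    dose_shift_alpha: float = 1.0  # potency boost per unit partner occupancy
    interaction_weight: str = "unimodal"  # or "uniform"
    rlu_scale: float = 1.0e6
    n_control_wells: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_synergistic > self.n_combinations:
            raise ValueError("n_synergistic exceeds n_combinations")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.interaction_delta <= 0.5:
            raise ValueError("interaction_delta must lie in [0, 0.5]")
        if self.interaction_mode not in ("bliss_excess", "dose_shift"):
            raise ValueError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.interaction_weight not in ("unimodal", "uniform"):
            raise ValueError(f"unknown weight shape {self.interaction_weight!r}")


@dataclass
class SynthScreen:
    """A fully simulated screen plus the ground truth that produced it."""

    config: SynthConfig
    drugs: list[str]
    cultures: list[str]
    combinations: list[tuple[str, str]]
    synergistic: set[str]  # combination ids "drugA+drugB"
    true_hill: dict[tuple[str, str], HillFit]  # (drug, culture) -> params
    plates: pd.DataFrame  # plate-map CSV dialect, raw RLU
    true_delta: dict[str, float] = field(default_factory=dict)

    def combination_id(self, pair: tuple[str, str]) -> str:
        return f"{pair[0]}+{pair[1]}"

    def matrices(self) -> dict[tuple[str, str, str], DoseMatrix]:
        """Normalize and assemble DoseMatrix objects via the grids path."""
        return matrices_from_platemap(
            self.plates, dilution_factor=self.config.dilution_factor
        )


def _pool_size(n_combinations: int) -> int:
    n = 2
    while n * (n - 1) // 2 < n_combinations:
        n += 1
    return n


def _interaction_weight(n: int, shape: str) -> np.ndarray:
    """Unimodal per-well weight over the n×n block, peak normalized to 1."""
    if shape == "uniform":
        return np.ones((n, n))
    idx = np.arange(1, n + 1, dtype=float)
    center = (n + 1) / 2.0
    w = np.exp(-((idx - center) / (0.45 * n)) ** 2)
    w2 = np.outer(w, w)
    return w2 / w2.max()


def simulate_screen(config: SynthConfig) -> SynthScreen:
    """Generate the full screen; bit-identical for the same config and seed."""
    rng = np.random.default_rng(config.seed)
    n_drugs = config.n_drugs or _pool_size(config.n_combinations)
    if n_drugs * (n_drugs - 1) // 2 < config.n_combinations:
        raise ValueError("drug pool too small for the requested combinations")
    drugs = [f"D{i + 1:02d}" for i in range(n_drugs)]
    cultures = [f"C{i + 1:02d}" for i in range(config.n_cultures)]
    all_pairs = list(itertools.combinations(drugs, 2))
    pick = rng.choice(len(all_pairs), size=config.n_combinations, replace=False)
    combinations = [all_pairs[i] for i in sorted(pick)]
    syn_pick = rng.choice(config.n_combinations, size=config.n_synergistic,
                          replace=False)
    synergistic = {f"{combinations[i][0]}+{combinations[i][1]}"
                   for i in syn_pick}

    true_hill: dict[tuple[str, str], HillFit] = {}
    for drug in drugs:
        for culture in cultures:
            e0 = rng.uniform(*config.e0_range)
            einf = rng.uniform(*config.einf_range)
            ec50 = 10.0 ** rng.uniform(*config.log10_ec50_range)
            h = rng.uniform(*config.h_range)
            true_hill[(drug, culture)] = HillFit(e0, einf, ec50, h, 0.0, 0,
                                                 True, True)

    n = config.n_levels
    weight = _interaction_weight(n, config.interaction_weight)
    rows: list[tuple] = []
    n_negative = 0
    n_wells_total = 0
    plate_counter = 0
    true_delta: dict[str, float] = {}

    for culture in cultures:
        base = config.rlu_scale
        for pair in combinations:
            drug_a, drug_b = pair
            combo_id = f"{drug_a}+{drug_b}"
            fa = true_hill[(drug_a, culture)]
            fb = true_hill[(drug_b, culture)]
            delta = (config.interaction_delta if combo_id in synergistic
                     else 0.0)
            true_delta[combo_id] = config.interaction_delta \
                if combo_id in synergistic else 0.0

            tops = []
            for f in (fa, fb):
                ic50 = absolute_ic50(f)
                tops.append(ic50 if ic50 is not None
                            else config.insensitive_top_dose)
            axis_a = np.concatenate([[0.0], np.sort(build_grid(
                tops[0], config.dilution_factor, n))])
            axis_b = np.concatenate([[0.0], np.sort(build_grid(
                tops[1], config.dilution_factor, n))])

            va = fa.predict(axis_a)
            vb = fb.predict(axis_b)
            if config.interaction_mode == "dose_shift" and delta > 0:
                # potency boost: each drug sees an effective dose inflated
                # by the partner's receptor occupancy d/(d+ec50)
                occ_b = axis_b / (axis_b + fb.ec50)
                occ_a = axis_a / (axis_a + fa.ec50)
                eff_a = axis_a[:, None] * (
                    1.0 + config.dose_shift_alpha * delta / 0.15 * occ_b[None, :])
                eff_b = axis_b[None, :] * (
                    1.0 + config.dose_shift_alpha * delta / 0.15 * occ_a[:, None])
                clean = fa.predict(eff_a) * fb.predict(eff_b)
            else:
                clean = np.outer(va, vb)
                if delta > 0:
                    clean = clean.copy()
                    clean[1:, 1:] -= delta * weight
            n_negative += int((clean < 0).sum())
            n_wells_total += clean.size

            plate_counter += 1
            plate_id = f"P{plate_counter:05d}"
            well_counter = 0
            for r in range(config.n_replicates):
                noise = rng.normal(0.0, config.noise_sd, clean.shape) \
                    if config.noise_sd > 0 else np.zeros_like(clean)
                v_obs = np.clip(clean + noise, 0.0, 1.2)
                for i, da in enumerate(axis_a):
                    for j, db in enumerate(axis_b):
                        well_counter += 1
                        rows.append((
                            plate_id, f"W{well_counter:03d}", culture,
                            drug_a, da, drug_b, db, r,
                            v_obs[i, j] * base, False,
                        ))
            ctrl = np.clip(
                1.0 + rng.normal(0.0, config.noise_sd, config.n_control_wells),
                0.0, 1.2) if config.noise_sd > 0 \
                else np.ones(config.n_control_wells)
            for c in ctrl:
                well_counter += 1
                rows.append((plate_id, f"W{well_counter:03d}", culture,
                             "DMSO", 0.0, "DMSO", 0.0, 0, c * base, True))

    if n_wells_total and n_negative / n_wells_total > 0.10:
        warnings.warn(
            f"interaction delta drives {n_negative / n_wells_total:.0%} of "
            "wells negative before truncation"
        )
    plates = pd.DataFrame(rows, columns=[
        "plate", "well", "culture", "drug_a", "dose_a_um", "drug_b",
        "dose_b_um", "replicate", "rlu", "is_control",
    ])
    return SynthScreen(
        config=config, drugs=drugs, cultures=cultures,
        combinations=combinations, synergistic=synergistic,
        true_hill=true_hill, plates=plates, true_delta=true_delta,
    )


def make_blobs(k: int, n_per: int, sep: float, seed: int = 0,
               n_features: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic unit-SD Gaussian clusters with known labels.

    Cluster centers sit on an integer lattice scaled by ``sep``, so any two
    centers are at least ``sep`` standard deviations apart. ``sep = 0``
    collapses all clusters onto one center.
    """
    if k < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    side = max(1, math.ceil(k ** (1.0 / n_features)))
    lattice = list(itertools.product(range(side + 1), repeat=n_features))[:k]
    centers = sep * np.asarray(lattice, dtype=float)
    labels = np.repeat(np.arange(k), n_per)
    X = centers[labels] + rng.standard_normal((k * n_per, n_features))
    return X, labels
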