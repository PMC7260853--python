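"""Synthetic cohort generator.

Simulates cohorts of control/mutant animals with lumbar hemi-sections
carrying marker-positive cells, so the full analysis pipeline can be
exercised and calibrated without microscopy data.  Cell counts per
section are Poisson with a lognormal per-animal random effect; cell
positions come from a Gaussian mixture in normalized coordinates,
truncated to the unit frame by rejection sampling.  Mutant arms may
scale expected counts (count_ratio), translate cluster centers (shift)
and rescale cluster spreads (dispersion_ratio).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import SectionGeometry, write_cells_csv

__all__ = [
    "ClusterSpec",
    "EffectSpec",
    "CohortConfig",
    "Cohort",
    "sample_section",
    "generate_cohort",
    "write_cohort",
    "load_config",
]

GENOTYPES = ("control", "mutant")

# rejection sampling cap; the moderate spreads used in practice accept
# most draws, so this is only a guard against degenerate configs
_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class ClusterSpec:
    """One Gaussian component of the positional mixture (normalized units)."""

    center: tuple[float, float]
    sd: tuple[float, float]
    weight: float = 1.0
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sd[0] > 0 and self.sd[1] > 0):
            raise ValueError(f"cluster sd must be positive, got {self.sd}")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError(f"correlation must be in (-1, 1), got {self.correlation}")
        if self.weight <= 0:
            raise ValueError(f"cluster weight must be positive, got {self.weight}")


@dataclass(frozen=True)
class EffectSpec:
    """Genotype effect applied to the mutant arm.

    count_ratio < 1 models a cell-loss phenotype; a nonzero shift models
    a positional-displacement phenotype; dispersion_ratio rescales
    cluster spreads.
    """

    count_ratio: float = 1.0
    shift: tuple[float, float] = (0.0, 0.0)
    dispersion_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.count_ratio <= 0:
            raise ValueError(f"count_ratio must be > 0, got {self.count_ratio}")
        if self.dispersion_ratio <= 0:
            raise ValueError(
                f"dispersion_ratio must be > 0, got {self.dispersion_ratio}"
            )

    @property
    def is_null(self) -> bool:
        return (
            self.count_ratio == 1.0
            and self.shift == (0.0, 0.0)
            and self.dispersion_ratio == 1.0
        )


def _default_mixture() -> tuple[ClusterSpec, ...]:
    return (ClusterSpec(center=(0.5, 0.6), sd=(0.12, 0.12)),)


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of one simulated cohort (one marker)."""

    n_animals_per_genotype: int = 3
    n_sections_per_animal: int = 4
    mean_cells_per_section: float = 40.0
    mean_width_um: float = 300.0
    mean_height_um: float = 400.0
    geometry_jitter: float = 0.05  # fractional sd of width/height
    mixture: tuple[ClusterSpec, ...] = field(default_factory=_default_mixture)
    effect: EffectSpec = field(default_factory=EffectSpec)
    animal_effect_sd: float = 0.15  # sd of the lognormal per-animal count effect
    marker: str = "M1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_genotype < 1 or self.n_sections_per_animal < 1:
            raise ValueError("animal and section counts must be >= 1")
        if self.mean_cells_per_section <= 0:
            raise ValueError("mean_cells_per_section must be positive")
        if self.mean_width_um <= 0 or self.mean_height_um <= 0:
            raise ValueError("mean section dimensions must be positive")
        if not (0 <= self.geometry_jitter < 0.5):
            raise ValueError("geometry_jitter must be in [0, 0.5)")
        if self.animal_effect_sd < 0:
            raise ValueError("animal_effect_sd must be >= 0")
        if len(self.mixture) == 0:
            raise ValueError("mixture must have at least one component")
        total = sum(c.weight for c in self.mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "CohortConfig":
        data = dict(data)
        if "mixture" in data:
            data["mixture"] = tuple(
                ClusterSpec(
                    center=tuple(c["center"]),
                    sd=tuple(c["sd"]),
                    weight=c.get("weight", 1.0),
                    correlation=c.get("correlation", 0.0),
                )
                for c in data["mixture"]
            )
        if "effect" in data:
            e = dict(data["effect"])
            if "shift" in e:
                e["shift"] = tuple(e["shift"])
            data["effect"] = EffectSpec(**e)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class Cohort:
    """Generated dataset: cells, section inventory, and a truth log."""

    cells: pd.DataFrame
    sections: pd.DataFrame
    log: dict[str, Any]


def load_config(path) -> CohortConfig:
    """Load a cohort config from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return CohortConfig.from_mapping(data)


def _mutant_mixture(config: CohortConfig) -> tuple[ClusterSpec, ...]:
    e = config.effect
    return tuple(
        ClusterSpec(
            center=(c.center[0] + e.shift[0], c.center[1] + e.shift[1]),
            sd=(c.sd[0] * e.dispersion_ratio, c.sd[1] * e.dispersion_ratio),
            weight=c.weight,
            correlation=c.correlation,
        )
        for c in config.mixture
    )


def _sample_mixture(
    mixture: Sequence[ClusterSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n points from the mixture truncated to the unit square."""
    if n == 0:
        return np.empty((0, 2))
    weights = np.array([c.weight for c in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights)
    out = np.empty((n, 2))
    for k, spec in enumerate(mixture):
        idx = np.flatnonzero(comp == k)
        if idx.size == 0:
            continue
        sx, sy = spec.sd
        rho = spec.correlation
        cov = np.array(
            [[sx * sx, rho * sx * sy], [rho * sx * sy, sy * sy]]
        )
        chol = np.linalg.cholesky(cov)
        mean = np.asarray(spec.center)
        pts = mean + rng.standard_normal((idx.size, 2)) @ chol.T
        bad = np.any((pts < 0.0) | (pts > 1.0), axis=1)
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > _MAX_REJECTION_ROUNDS:
                raise RuntimeError(
                    "rejection sampling failed to place points inside the "
                    "frame; cluster lies too far outside the unit square"
                )
            m = int(bad.sum())
            pts[bad] = mean + rng.standard_normal((m, 2)) @ chol.T
            bad = np.any((pts < 0.0) | (pts > 1.0), axis=1)
        out[idx] = pts
    return out


def sample_section(
    config: CohortConfig,
    genotype: str,
    animal_effect: float,
    rng: np.random.Generator,
    section_id: str = "s1",
    animal_id: str = "a1",
) -> tuple[SectionGeometry, np.ndarray]:
    """Draw one hemi-section: its geometry and cell positions.

    Returns the geometry and an ``(k, 2)`` array of Cartesian µm
    positions in the section frame.  The count is Poisson with mean
    ``mean_cells_per_section × animal_effect × count_ratio`` (the ratio
    applied only to mutants); zero-cell sections are legal.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
    mutant = genotype == "mutant"
    jit = config.geometry_jitter
    width = config.mean_width_um * max(1e-3, 1.0 + jit * rng.standard_normal())
    height = config.mean_height_um * max(1e-3, 1.0 + jit * rng.standard_normal())
    geom = SectionGeometry(
        section_id=section_id, animal_id=animal_id, width_um=width, height_um=height
    )
    mean = config.mean_cells_per_section * animal_effect
    if mutant:
        mean *= config.effect.count_ratio
    k = int(rng.poisson(mean))
    mixture = _mutant_mixture(config) if mutant else config.mixture
    pts_norm = _sample_mixture(mixture, k, rng)
    xy_um = pts_norm * np.array([width, height])
    return geom, xy_um


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-genotype cohort, deterministic given the seed.

    The returned log records the true per-section counts and effect
    parameters so that recovery tests can compare against the truth.
    """
    rng = np.random.default_rng(config.seed)
    cell_rows: list[pd.DataFrame] = []
    section_rows: list[dict[str, Any]] = []
    per_section_counts: dict[str, int] = {}
    animal_effects: dict[str, float] = {}
    for genotype in GENOTYPES:
        for a in range(config.n_animals_per_genotype):
            animal_id = f"{genotype[:3]}_{a + 1}"
            eff = float(np.exp(config.animal_effect_sd * rng.standard_normal()))
            animal_effects[animal_id] = eff
            for s in range(config.n_sections_per_animal):
                section_id = f"{animal_id}_sec{s + 1}"
                geom, xy_um = sample_section(
                    config, genotype, eff, rng,
                    section_id=section_id, animal_id=animal_id,
                )
                per_section_counts[section_id] = len(xy_um)
                section_rows.append(
                    {
                        "animal_id": animal_id,
                        "genotype": genotype,
                        "section_id": section_id,
                        "marker": config.marker,
                        "section_width_um": geom.width_um,
                        "section_height_um": geom.height_um,
                        "n_cells": len(xy_um),
                    }
                )
                if len(xy_um):
                    cell_rows.append(
                        pd.DataFrame(
                            {
                                "animal_id": animal_id,
                                "genotype": genotype,
                                "section_id": section_id,
                                "marker": config.marker,
                                "x_um": xy_um[:, 0],
                                "y_um": xy_um[:, 1],
                                "section_width_um": geom.width_um,
                                "section_height_um": geom.height_um,
                            }
                        )
                    )
    cells = (
        pd.concat(cell_rows, ignore_index=True)
        if cell_rows
        else pd.DataFrame(
            columns=[
                "animal_id", "genotype", "section_id", "marker",
                "x_um", "y_um", "section_width_um", "section_height_um",
            ]
        )
    )
    sections = pd.DataFrame(section_rows)
    log = {
        "config": config.to_dict(),
        "seed": config.seed,
        "marker": config.marker,
        "animal_effects": animal_effects,
        "per_section_counts": per_section_counts,
        "total_cells": int(sum(per_section_counts.values())),
    }
    return Cohort(cells=cells, sections=sections, log=log)


def pooled_points(config: CohortConfig) -> dict[str, np.ndarray]:
    """Fast path: normalized pooled points per genotype, skipping tables.

    Statistically identical to pooling :func:`generate_cohort` output;
    used by calibration simulations where only the pooled coordinates
    and per-animal structure matter.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for genotype in GENOTYPES:
        chunks = []
        animal_idx = []
        mutant = genotype == "mutant"
        mixture = _mutant_mixture(config) if mutant else config.mixture
        for a in range(config.n_animals_per_genotype):
            eff = float(np.exp(config.animal_effect_sd * rng.standard_normal()))
            mean = config.mean_cells_per_section * eff
            if mutant:
                mean *= config.effect.count_ratio
            counts = rng.poisson(mean, size=config.n_sections_per_animal)
            k = int(counts.sum())
            chunks.append(_sample_mixture(mixture, k, rng))
            animal_idx.append(np.full(k, a))
        out[genotype] = (
            np.concatenate(chunks) if chunks else np.empty((0, 2))
        )
        labels[genotype] = (
            np.concatenate(animal_idx) if animal_idx else np.empty(0, dtype=int)
        )
    out["control_animal"] = labels["control"]
    out["mutant_animal"] = labels["mutant"]
    return out


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write cells.csv, sections.csv and the generator log JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / "cells.csv",
        "sections": out / "sections.csv",
        "log": out / "generator_log.json",
    }
    write_cells_csv(cohort.cells, paths["cells"])
    cohort.sections.to_csv(paths["sections"], index=False)
    paths["log"].write_text(
        json.dumps(cohort.log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
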