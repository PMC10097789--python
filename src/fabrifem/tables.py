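"""Published load tables and constants, shipped as CSV fixtures.

The fixtures mirror, row for row, the printed tables of the study this
pipeline reproduces: the tissue material constants, the muscular forces
for the two gait-cycle leg configurations (30% and 60%, OpenSim muscle
nomenclature), the hip-joint reaction forces, and the Frost mechanostat
thresholds.

Two direction entries of the muscle table were typographically corrupt
in the available transcription (their printed triples were far from unit
norm); they were restored by the minimal edit that re-establishes the
unit-norm constraint and are noted in the repository history.  All other
numbers are verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constitutive import MaterialCard
from .postprocess import FrostThresholds

#: Muscle names (OpenSim nomenclature) in printed row order.
MUSCLES = (
    "Glut_max1", "Glut_max2", "Glut_max3",
    "Glut_med1", "Glut_med2", "Glut_med3",
    "Glut_min1", "Glut_min2", "Glut_min3",
    "Iliacus", "Pect", "Perif", "Psoas", "Quadfem", "Gem",
)

DIRECTION_NORM_TOL = 5e-3   # 3-decimal printed rounding bounds the deviation


@dataclass
class MuscleLoad:
    attachment_set: str
    direction: np.ndarray     # unit 3-vector (printed rounding)
    magnitude_N: float


@dataclass
class LoadCase:
    """Point muscle forces plus a rod-distributed joint reaction."""

    name: str
    muscle_loads: list
    reaction_direction: np.ndarray
    reaction_magnitude_N: float
    joint_center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    joint_surface_set: str = "joint_surface"

    def __post_init__(self) -> None:
        self.reaction_direction = _check_unit(self.reaction_direction)
        if self.reaction_magnitude_N < 0:
            raise ValueError("reaction magnitude must be non-negative")
        for ml in self.muscle_loads:
            ml.direction = _check_unit(ml.direction)
            if ml.magnitude_N < 0:
                raise ValueError(f"negative magnitude for {ml.attachment_set}")

    def total_muscle_force(self) -> np.ndarray:
        return sum(
            (ml.direction * ml.magnitude_N for ml in self.muscle_loads),
            start=np.zeros(3),
        )

    def reaction_vector(self) -> np.ndarray:
        return self.reaction_direction * self.reaction_magnitude_N


def _check_unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > DIRECTION_NORM_TOL:
        raise ValueError(f"direction {v} has norm {n:.4f}, not unit within {DIRECTION_NORM_TOL}")
    return v


def _data(name: str) -> pd.DataFrame:
    with resources.files("fabrifem.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table(name: str) -> pd.DataFrame:
    """Raw fixture table; name in {material, muscles, reactions, frost}."""
    files = {
        "material": "table1_material.csv",
        "muscles": "table2_muscles.csv",
        "reactions": "table3_reactions.csv",
        "frost": "table4_frost.csv",
    }
    return _data(files[name])


def material_card() -> MaterialCard:
    row = load_table("material").iloc[0]
    return MaterialCard(
        E0=float(row.E0_MPa), nu0=float(row.nu0), G0=float(row.G0_MPa),
        k=float(row.k), l=float(row.l),
    )


def load_case(config: int) -> LoadCase:
    mus = load_table("muscles")
    rea = load_table("reactions")
    sub = mus[mus.config == config]
    if len(sub) != len(MUSCLES):
        raise ValueError(f"configuration {config} must have {len(MUSCLES)} muscle rows")
    loads = [
        MuscleLoad(r.muscle, np.array([r.nx, r.ny, r.nz]), float(r.magnitude_N))
        for r in sub.itertuples()
    ]
    rr = rea[rea.config == config].iloc[0]
    return LoadCase(
        name=f"config{config}",
        muscle_loads=loads,
        reaction_direction=np.array([rr.nx, rr.ny, rr.nz]),
        reaction_magnitude_N=float(rr.magnitude_N),
    )


def frost_thresholds() -> FrostThresholds:
    df = load_table("frost").set_index("threshold")

    def rng(row, lo, hi):
        a = float(row[lo])
        b = float(row[hi]) if pd.notna(row[hi]) else a
        return (a, b)

    strain = {k: rng(df.loc[k], "strain_lo_ustrain", "strain_hi_ustrain") for k in df.index}
    stress = {k: rng(df.loc[k], "stress_lo_MPa", "stress_hi_MPa") for k in df.index}
    sed = {k: rng(df.loc[k], "sed_lo_MPa", "sed_hi_MPa") for k in df.index}
    return FrostThresholds(strain_ustrain=strain, stress_MPa=stress, sed_MPa=sed)


def builtin_tables():
    """(MaterialCard, LoadCase config1, LoadCase config2, FrostThresholds)."""
    return material_card(), load_case(1), load_case(2), frost_thresholds()
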