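"""Electron-equivalent (COD) energy accounting for controlled feeding studies.

Dietary energy is tracked in two currencies: kilocalories (the clinical
currency) and grams of chemical oxygen demand (gCOD, the amount of O2 needed
to fully oxidize the organic matter). COD is the natural currency for
host-microbe energy partitioning because the same electron equivalents are
available to the host in the small intestine and to the fermenting community
in the colon. This module converts between the two currencies, partitions a
day's intake into the five substrate classes used by the colonic fermentation
model, and computes the host-side summary quantities: host metabolizable
energy (ME, the percent of intake COD not lost in feces), non-metabolizable
kcal, methane combustion energy, and daily energy balance.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "MacroIntake",
    "SubstrateCOD",
    "CODFactors",
    "PhysicalConstants",
    "EnergySummary",
    "DEFAULT_COD_FACTORS",
    "CONSTANTS",
    "WD_MEAN_DIET",
    "MBD_MEAN_DIET",
    "mean_daily_intake",
    "partition_substrates",
    "host_me",
    "nonmetabolizable_kcal",
    "methane_energy",
    "energy_balance",
    "kcal_cod_interconvert",
    "read_intake_csv",
    "write_energy_summary_csv",
]

#: kcal per gram used by menu software for digestible carbohydrate and protein / fat
ATWATER_KCAL_PER_G = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class MacroIntake:
    """One participant-day of dietary energy and macronutrient masses.

    ``cho_g`` is total carbohydrate *including* fiber and resistant starch.
    In the kcal ledger fiber contributes 0 kcal while resistant starch counts
    at the full carbohydrate factor (menu-software convention); in the COD
    ledger all carbohydrate mass carries electrons equally.
    """

    kcal_total: float  # kcal/day
    cho_g: float       # g/day, total carbohydrate incl. fiber and RS
    fiber_g: float     # g/day, total dietary fiber
    rs_g: float        # g/day, resistant starch
    protein_g: float   # g/day
    fat_g: float       # g/day

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"MacroIntake.{f.name} must be >= 0, got {v}")
        if self.rs_g + self.fiber_g > self.cho_g * (1 + 1e-12):
            raise ValueError(
                "rs_g + fiber_g exceeds total carbohydrate: "
                f"{self.rs_g} + {self.fiber_g} > {self.cho_g}"
            )
        any_macro = self.cho_g > 0 or self.protein_g > 0 or self.fat_g > 0
        if any_macro and self.kcal_total <= 0:
            raise ValueError("kcal_total must be > 0 when any macronutrient mass is > 0")

    def __add__(self, other: "MacroIntake") -> "MacroIntake":
        return MacroIntake(*(getattr(self, f.name) + getattr(other, f.name) for f in fields(self)))

    def scale(self, c: float) -> "MacroIntake":
        return MacroIntake(*(c * getattr(self, f.name) for f in fields(self)))


@dataclass(frozen=True)
class SubstrateCOD:
    """Daily electron-equivalent fluxes (gCOD/day) in the five model substrate classes."""

    ass: float      # available sugar & starch (digestible CHO net of RS and fiber)
    rs: float       # resistant starch
    nsp: float      # non-starch polysaccharides (dietary fiber)
    protein: float
    fat: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"SubstrateCOD.{f.name} must be >= 0")

    def total(self) -> float:
        return self.ass + self.rs + self.nsp + self.protein + self.fat

    def __add__(self, other: "SubstrateCOD") -> "SubstrateCOD":
        return SubstrateCOD(*(getattr(self, f.name) + getattr(other, f.name) for f in fields(self)))

    def scale(self, c: float) -> "SubstrateCOD":
        return SubstrateCOD(*(c * getattr(self, f.name) for f in fields(self)))


@dataclass(frozen=True)
class CODFactors:
    """Stoichiometric oxygen demand per gram of macronutrient.

    Defaults are theoretical oxygen demands: 1.185 gCOD/g for polysaccharide
    (C6H10O5 monomer basis, also applied to sugars, fiber, and resistant
    starch), 1.50 gCOD/g for mixed dietary protein, and 2.90 gCOD/g for
    triglyceride fat. ``kcal_per_gcod_default`` is a mixed-diet scalar for
    conversions when no composition is available.
    """

    gcod_per_g_carbohydrate: float = 1.185
    gcod_per_g_protein: float = 1.50
    gcod_per_g_fat: float = 2.90
    kcal_per_gcod_default: float = 3.06

    def __post_init__(self) -> None:
        if not 1.0 <= self.gcod_per_g_carbohydrate <= 1.3:
            raise ValueError("carbohydrate COD factor outside plausible range [1.0, 1.3]")
        if not 1.3 <= self.gcod_per_g_protein <= 1.7:
            raise ValueError("protein COD factor outside plausible range [1.3, 1.7]")
        if not 2.7 <= self.gcod_per_g_fat <= 3.0:
            raise ValueError("fat COD factor outside plausible range [2.7, 3.0]")
        if not 2.8 <= self.kcal_per_gcod_default <= 3.5:
            raise ValueError("default kcal/gCOD outside plausible range [2.8, 3.5]")


_REFERENCE_TEMP_K = 298.15  # 25 degC
_GAS_CONSTANT_ML_ATM = 82.057338  # ml*atm/(mol*K)


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants used across the ledger."""

    ch4_combustion: float = 212.8          # kcal/mol CH4, enthalpy of combustion
    molar_volume_ml: float = round(_GAS_CONSTANT_ML_ATM * _REFERENCE_TEMP_K / 1.0, -1)  # 24470 -> see below
    avogadro: float = 6.022e23             # /mol
    bp_mass: float = 660.0                 # g/mol per base pair of dsDNA


# Ideal-gas molar volume at 25 degC, 1 atm. The conventional rounded value
# 24,450 ml/mol is used so that 1000 ml CH4 = 212.8/24.45 = 8.703 kcal.
CONSTANTS = PhysicalConstants(molar_volume_ml=24450.0)

DEFAULT_COD_FACTORS = CODFactors()


@dataclass(frozen=True)
class EnergySummary:
    """Host-side daily energy summary for one participant-diet."""

    intake_cod: float            # gCOD/day
    fecal_cod: float             # gCOD/day
    host_me_pct: float           # % of intake COD retained by the host
    nonmetab_kcal: float         # kcal/day lost in feces
    energy_balance_kcal: float   # kcal/day, intake - expenditure


def mean_daily_intake(
    kcal_per_day: float,
    cho_frac: float,
    fat_frac: float,
    protein_frac: float,
    fiber_g_per_1000kcal: float,
    rs_g_per_1000kcal: float,
) -> MacroIntake:
    """Build a :class:`MacroIntake` from a diet template.

    ``cho_frac``/``fat_frac``/``protein_frac`` are the fractions of total kcal
    from digestible carbohydrate, fat, and protein. Fiber (0 kcal) is added on
    top of the digestible carbohydrate mass; resistant starch is carved out of
    it (RS carries kcal but resists small-intestinal digestion).
    """
    digestible_cho_g = kcal_per_day * cho_frac / ATWATER_KCAL_PER_G["carbohydrate"]
    fiber_g = fiber_g_per_1000kcal * kcal_per_day / 1000.0
    rs_g = rs_g_per_1000kcal * kcal_per_day / 1000.0
    return MacroIntake(
        kcal_total=kcal_per_day,
        cho_g=digestible_cho_g + fiber_g,
        fiber_g=fiber_g,
        rs_g=rs_g,
        protein_g=kcal_per_day * protein_frac / ATWATER_KCAL_PER_G["protein"],
        fat_g=kcal_per_day * fat_frac / ATWATER_KCAL_PER_G["fat"],
    )


# Mean daily diets of the two crossover arms (8 inpatient days):
# WD (Western Diet): 17,008 kcal/8 d; 48/35/16 % kcal from CHO/fat/protein;
# fiber 6.4 g/1000 kcal; estimated resistant starch 1.2 g/1000 kcal.
WD_MEAN_DIET = mean_daily_intake(17008 / 8, 0.48, 0.35, 0.16, 6.4, 1.2)
# MBD (Microbiome Enhancer Diet): 16,909 kcal/8 d; 49/34/17 %; fiber 26.0; RS 10.3.
MBD_MEAN_DIET = mean_daily_intake(16909 / 8, 0.49, 0.34, 0.17, 26.0, 10.3)


def partition_substrates(
    intake: MacroIntake, factors: CODFactors = DEFAULT_COD_FACTORS
) -> SubstrateCOD:
    """Partition a day's intake into the five substrate classes, in gCOD/day.

    Available sugar and starch (ASS) is total carbohydrate minus resistant
    starch minus fiber; RS and fiber (NSP) are kept as separate classes
    because they escape small-intestinal digestion and reach the colon.
    """
    ass_g = intake.cho_g - intake.rs_g - intake.fiber_g
    if ass_g < -1e-9:
        raise ValueError(
            "negative available sugar & starch mass: "
            f"cho_g={intake.cho_g}, rs_g={intake.rs_g}, fiber_g={intake.fiber_g}"
        )
    f_cho = factors.gcod_per_g_carbohydrate
    return SubstrateCOD(
        ass=max(ass_g, 0.0) * f_cho,
        rs=intake.rs_g * f_cho,
        nsp=intake.fiber_g * f_cho,
        protein=intake.protein_g * factors.gcod_per_g_protein,
        fat=intake.fat_g * factors.gcod_per_g_fat,
    )


def host_me(intake_cod: float, fecal_cod: float) -> float:
    """Host metabolizable energy: % of intake electron equivalents kept by the host."""
    if intake_cod <= 0:
        raise ValueError(f"intake_cod must be > 0, got {intake_cod}")
    if fecal_cod < 0:
        raise ValueError(f"fecal_cod must be >= 0, got {fecal_cod}")
    return 100.0 * (1.0 - fecal_cod / intake_cod)


def nonmetabolizable_kcal(host_me_pct: float, ei_kcal: float) -> float:
    """Daily kcal not absorbed by the host (lost in feces)."""
    if not 0.0 <= host_me_pct <= 100.0:
        raise ValueError(f"host_me_pct must be in [0, 100], got {host_me_pct}")
    if ei_kcal < 0:
        raise ValueError(f"ei_kcal must be >= 0, got {ei_kcal}")
    return ei_kcal * (1.0 - host_me_pct / 100.0)


def methane_energy(vol_ml_per_day: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Combustion energy (kcal/day) of exhaled/eructed methane from its daily volume."""
    if vol_ml_per_day < 0:
        raise ValueError(f"methane volume must be >= 0, got {vol_ml_per_day}")
    return vol_ml_per_day / constants.molar_volume_ml * constants.ch4_combustion


def energy_balance(ei_kcal: float, ee_kcal: float) -> float:
    """Daily energy balance = energy intake - energy expenditure (kcal/day)."""
    if ei_kcal < 0 or ee_kcal < 0:
        raise ValueError("energy intake and expenditure must be >= 0")
    return ei_kcal - ee_kcal


def total_cod(intake: MacroIntake, factors: CODFactors = DEFAULT_COD_FACTORS) -> float:
    """Total dietary electron equivalents (gCOD/day) for a day's intake."""
    return partition_substrates(intake, factors).total()


def kcal_cod_interconvert(
    value: float,
    direction: str,
    composition: MacroIntake | None = None,
    factors: CODFactors = DEFAULT_COD_FACTORS,
) -> float:
    """Convert between kcal/day and gCOD/day.

    With a ``composition``, the conversion uses the diet's own composition-
    weighted factor kcal_total / total_COD (kcal per gCOD), which makes the
    round trip exact; otherwise the mixed-diet default scalar is used.
    """
    if direction not in ("kcal_to_cod", "cod_to_kcal"):
        raise ValueError(f"direction must be 'kcal_to_cod' or 'cod_to_kcal', got {direction!r}")
    if composition is not None:
        cod = total_cod(composition, factors)
        if composition.kcal_total <= 0:
            if cod > 0:
                raise ValueError("composition has zero kcal but nonzero macronutrient mass")
            return 0.0
        if cod <= 0:
            raise ValueError("composition has zero COD; no composition-weighted factor exists")
        kcal_per_gcod = composition.kcal_total / cod
    else:
        kcal_per_gcod = factors.kcal_per_gcod_default
    if direction == "kcal_to_cod":
        return value / kcal_per_gcod
    return value * kcal_per_gcod


# ---------------------------------------------------------------------------
# External interface: CSV I/O

INTAKE_COLUMNS = [
    "participant_id", "diet", "day", "kcal",
    "cho_g", "fiber_g", "rs_g", "protein_g", "fat_g",
]


def read_intake_csv(path) -> pd.DataFrame:
    """Read a per-participant-day intake table; validates schema and invariants."""
    df = pd.read_csv(path, comment="#")
    missing = set(INTAKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intake CSV {path} missing columns: {sorted(missing)}")
    for i, row in df.iterrows():
        try:
            MacroIntake(row.kcal, row.cho_g, row.fiber_g, row.rs_g, row.protein_g, row.fat_g)
        except ValueError as exc:
            raise ValueError(
                f"invalid intake row {i} (participant {row.participant_id}, "
                f"diet {row.diet}, day {row.day}): {exc}"
            ) from exc
    return df


def write_energy_summary_csv(summaries: pd.DataFrame, path) -> None:
    """Write an energy-summary table with a units header comment."""
    with open(path, "w") as fh:
        fh.write(
            "# Units: intake_cod, fecal_cod in gCOD/day; host_me_pct in %; "
            "nonmetab_kcal, energy_balance_kcal in kcal/day\n"
        )
        summaries.to_csv(fh, index=False)
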