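"""Fecal bacterial biomass from absolute 16S rRNA gene quantification.

qPCR against a plasmid standard curve yields 16S gene copies per gram of
feces; multiplying by marker-normalized daily fecal weight gives copies/day,
and dividing by the mean rRNA operon count per genome, then scaling by cell
dry mass and the COD content of dry biomass, expresses the community's daily
biomass production in the same electron-equivalent currency (gCOD/day) as the
diet and feces.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .energy_accounting import CONSTANTS, PhysicalConstants

__all__ = [
    "QpcrStandard",
    "BiomassParams",
    "DEFAULT_BIOMASS_PARAMS",
    "plasmid_copy_number",
    "daily_16s_copies",
    "biomass_cod",
    "copies_from_biomass_cod",
]


@dataclass(frozen=True)
class QpcrStandard:
    """A quantified plasmid standard: DNA concentration and construct length."""

    dna_conc: float        # ng/uL
    plasmid_length: int    # bp

    def __post_init__(self) -> None:
        if self.dna_conc < 0:
            raise ValueError("dna_conc must be >= 0")
        if self.plasmid_length <= 0:
            raise ValueError("plasmid_length must be > 0")


@dataclass(frozen=True)
class BiomassParams:
    """Conversion from 16S gene copies to biomass electron equivalents.

    Defaults: 4 rRNA operons per genome (gut-community average), 2.8e-13 g
    dry mass per cell, and 1.42 gCOD per g dry weight (C5H7O2N biomass
    stoichiometry). All three are exposed because they are community- and
    condition-dependent.
    """

    copies_per_genome: float = 4.0
    cell_dry_mass_g: float = 2.8e-13
    cod_per_dw: float = 1.42

    def __post_init__(self) -> None:
        if self.copies_per_genome < 1:
            raise ValueError("copies_per_genome must be >= 1")
        if self.cell_dry_mass_g <= 0:
            raise ValueError("cell_dry_mass_g must be > 0")
        if not 1.2 <= self.cod_per_dw <= 1.6:
            raise ValueError("cod_per_dw outside plausible range [1.2, 1.6]")


DEFAULT_BIOMASS_PARAMS = BiomassParams()


def plasmid_copy_number(
    std: QpcrStandard, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Copies/uL of a plasmid standard from its mass concentration and length.

    copies/uL = (ng/uL) * N_A / (length_bp * 1e9 ng/g * 660 g/mol/bp).
    """
    return (
        std.dna_conc * constants.avogadro
        / (std.plasmid_length * 1e9 * constants.bp_mass)
    )


def daily_16s_copies(copies_per_g: float, fecal_g_per_day: float, recovery: float) -> float:
    """Daily 16S gene output: copies/g feces x marker-normalized g feces/day.

    ``fecal_g_per_day`` may be the raw composite-mean daily weight, in which
    case dividing by ``recovery`` applies the marker adjustment here; pass
    recovery=1 if the weight is already marker-normalized.
    """
    if copies_per_g < 0 or fecal_g_per_day < 0:
        raise ValueError("copies_per_g and fecal_g_per_day must be >= 0")
    if recovery <= 0:
        raise ValueError(f"recovery must be > 0, got {recovery}")
    return copies_per_g * fecal_g_per_day / recovery


def biomass_cod(copies_per_day: float, p: BiomassParams = DEFAULT_BIOMASS_PARAMS) -> float:
    """Fecal bacterial biomass production (gCOD/day) from daily 16S gene output."""
    if copies_per_day < 0:
        raise ValueError("copies_per_day must be >= 0")
    return copies_per_day / p.copies_per_genome * p.cell_dry_mass_g * p.cod_per_dw


def copies_from_biomass_cod(
    biomass_gcod_per_day: float, p: BiomassParams = DEFAULT_BIOMASS_PARAMS
) -> float:
    """Inverse of :func:`biomass_cod`; used to synthesize qPCR readouts."""
    if biomass_gcod_per_day < 0:
        raise ValueError("biomass must be >= 0")
    return biomass_gcod_per_day / (p.cell_dry_mass_g * p.cod_per_dw) * p.copies_per_genome


# ---------------------------------------------------------------------------
# External interface

QPCR_COLUMNS = ["participant_id", "diet", "copies_per_g"]
STANDARDS_COLUMNS = ["dna_ng_per_ul", "plasmid_length_bp"]


def read_qpcr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR CSV {path} missing columns: {sorted(missing)}")
    return df


def read_standards_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(STANDARDS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"standards CSV {path} missing columns: {sorted(missing)}")
    return df
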