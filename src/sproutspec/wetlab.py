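"""Deterministic chemistry calculators for the conventional reference
methods: gravimetric water content, iodometric titrant standardization,
ascorbic acid mass, and unit conversions.

The iodometric chain standardizes sodium thiosulfate against potassium
iodate, iodine against the thiosulfate, and converts the net sample
titre into ascorbic acid mass using the equivalent weight of ascorbic
acid against iodine: 176.13 / 2 = 88.065 mg per milliequivalent (two
electrons exchanged in the oxidation).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, DataError, NegativeTitreError

#: molar mass of L-ascorbic acid, g/mol
ASCORBIC_MOLAR_MASS = 176.13
#: electrons transferred in the oxidation of ascorbic acid by iodine
ASCORBIC_ELECTRONS = 2
#: equivalent weight against iodine, mg per milliequivalent
ASCORBIC_EQUIV_WEIGHT_MG = ASCORBIC_MOLAR_MASS / ASCORBIC_ELECTRONS  # 88.065

#: titrated aliquot volume assumed by the 0.1 factor in the printed
#: standardization equations (1/10 mL)
STANDARDIZATION_ALIQUOT_ML = 10.0


@dataclass
class GravimetricRecord:
    """Container-corrected wet and dry masses in grams."""

    m_wet: float
    m_dry: float

    def __post_init__(self) -> None:
        if not 0 < self.m_dry <= self.m_wet:
            raise DataError(
                f"need 0 < m_dry <= m_wet, got m_dry={self.m_dry}, m_wet={self.m_wet}"
            )


@dataclass
class TitrationRecord:
    """Volumes (mL) and normalities (eq/L) of one determination."""

    v_sample: float = 0.0
    v_blank: float = 0.0
    v_iodate: float = 0.0
    v_thio: float = 0.0
    n_iodate: float = 0.01
    n_thio: float = 0.0
    n_iodine: float = 0.0
    aliquot_ml: float = 25.0
    extract_total_ml: float = 200.0
    bean_mass_g: float = 100.0

    def __post_init__(self) -> None:
        for name in ("v_sample", "v_blank", "v_iodate", "v_thio"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


def water_content_pct(rec: GravimetricRecord) -> float:
    """Water content as percent mass lost on oven drying:
    100 * (m_wet - m_dry) / m_wet."""
    return 100.0 * (rec.m_wet - rec.m_dry) / rec.m_wet


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise DataError(f"{name} must be >= 0, got {v}")


def standardize_thiosulfate(v_iodate: float, n_iodate: float) -> float:
    """Thiosulfate normality from the iodate titre of a 10 mL thiosulfate
    aliquot: v_iodate * n_iodate * 0.1 (the 0.1 is 1 / 10 mL)."""
    _check_nonneg(v_iodate=v_iodate, n_iodate=n_iodate)
    return v_iodate * n_iodate * (1.0 / STANDARDIZATION_ALIQUOT_ML)


def standardize_iodine(v_thio: float, n_thio: float) -> float:
    """Iodine normality from the thiosulfate titre of a 10 mL iodine
    aliquot: v_thio * n_thio * 0.1."""
    _check_nonneg(v_thio=v_thio, n_thio=n_thio)
    return v_thio * n_thio * (1.0 / STANDARDIZATION_ALIQUOT_ML)


def standardize_general(v_titrant: float, n_titrant: float, v_analyte: float) -> float:
    """General N1 V1 = N2 V2 standardization for non-10 mL aliquots."""
    _check_nonneg(v_titrant=v_titrant, n_titrant=n_titrant)
    if v_analyte <= 0:
        raise ConfigError("analyte volume must be > 0")
    return v_titrant * n_titrant / v_analyte


def ascorbic_mass_mg(
    rec: TitrationRecord, titrant_normality: float | None = None
) -> float:
    """Ascorbic acid mass (mg) in the titrated aliquot:
    N * (v_sample - v_blank) * 88.065.

    ``titrant_normality`` defaults to ``rec.n_thio`` (the normality
    symbol as printed); pass ``rec.n_iodine`` to use the standardized
    iodine normality instead — the formula is the same either way.
    """
    n = rec.n_thio if titrant_normality is None else titrant_normality
    if n <= 0:
        raise ConfigError("titrant normality must be > 0")
    if rec.v_sample < rec.v_blank:
        raise NegativeTitreError(
            f"sample titre {rec.v_sample} mL below blank {rec.v_blank} mL"
        )
    return n * (rec.v_sample - rec.v_blank) * ASCORBIC_EQUIV_WEIGHT_MG


def to_mg_per_100g(mg_in_aliquot: float, rec: TitrationRecord) -> float:
    """Scale an aliquot mass to mg per 100 g of starting material.

    Assumes the nominal extraction recipe (``extract_total_ml`` of water
    per ``bean_mass_g`` of material) and ignores the material's own water
    contribution to the extract volume.
    """
    if rec.aliquot_ml <= 0 or rec.extract_total_ml <= 0 or rec.bean_mass_g <= 0:
        raise ConfigError("aliquot_ml, extract_total_ml and bean_mass_g must be > 0")
    return mg_in_aliquot * (rec.extract_total_ml / rec.aliquot_ml) * (100.0 / rec.bean_mass_g)


def mg_per_100g_to_mg_per_l(mg_per_100g: float, rec: TitrationRecord | None = None) -> float:
    """Convert a per-mass content to the extract concentration in mg/L
    under the nominal extraction recipe."""
    rec = rec or TitrationRecord()
    mg_per_g = mg_per_100g / 100.0
    total_mg = mg_per_g * rec.bean_mass_g
    return total_mg / (rec.extract_total_ml / 1000.0)


def mg_per_l_to_mg_per_100g(mg_per_l: float, rec: TitrationRecord | None = None) -> float:
    rec = rec or TitrationRecord()
    total_mg = mg_per_l * rec.extract_total_ml / 1000.0
    return total_mg / rec.bean_mass_g * 100.0
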