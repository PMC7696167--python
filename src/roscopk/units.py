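"""Unit conventions and conversions.

All internal computation uses molar units: doses in µmol, concentrations in
nmol/L, amounts in nmol.  Assay outputs (and the printed exposure metrics)
are in mass units, ng/mL and ng·h/mL, and differ per analyte because the
parent drug and its carboxylate metabolite have different molar masses.
"""

from __future__ import annotations

#: Molar mass of roscovitine (parent), g/mol.
MW_PARENT = 354.45
#: Molar mass of the carboxylate metabolite M3, g/mol.
MW_METABOLITE = 368.43

#: Assay lower limit of quantification, ng/mL (both analytes).
LLOQ_NG_ML = 5.00

_MW = {"parent": MW_PARENT, "metabolite": MW_METABOLITE}


def molar_mass(analyte: str) -> float:
    """Molar mass (g/mol) for ``'parent'`` or ``'metabolite'``."""
    try:
        return _MW[analyte]
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}; expected 'parent' or 'metabolite'")


def mg_to_umol(dose_mg: float, molar_mass_g_mol: float = MW_PARENT) -> float:
    """Convert an administered dose in mg to µmol.

    Parameters
    ----------
    dose_mg : float
        Dose in milligrams, >= 0.
    molar_mass_g_mol : float
        Molar mass in g/mol, > 0.  Defaults to the parent drug.
    """
    if molar_mass_g_mol <= 0:
        raise ValueError(f"molar mass must be > 0, got {molar_mass_g_mol}")
    if dose_mg < 0:
        raise ValueError(f"dose must be >= 0, got {dose_mg}")
    return dose_mg * 1000.0 / molar_mass_g_mol


def ng_ml_to_nmol_l(x, analyte: str):
    """Convert a concentration from ng/mL to nmol/L."""
    return x * 1000.0 / molar_mass(analyte)


def nmol_l_to_ng_ml(x, analyte: str):
    """Convert a concentration from nmol/L to ng/mL."""
    return x * molar_mass(analyte) / 1000.0


def lloq_nmol_l(analyte: str) -> float:
    """The 5.00 ng/mL quantification limit expressed in nmol/L."""
    return ng_ml_to_nmol_l(LLOQ_NG_ML, analyte)
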