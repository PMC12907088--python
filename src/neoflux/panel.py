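"""Default neonicotinoid analyte panel: 8 parents and 6 metabolites.

The parent->metabolite map follows the transformation pairs monitored in
suburban WWTP influents: imidacloprid (IMI) has three metabolic derivatives
(DN-IMI, 5-OH-IMI, IMI-urea, collectively "mIMIs"); dinotefuran (DIN),
thiamethoxam (THIA) and acetamiprid (ACE) each have one.

LOD/LOQ endpoints for THI and DIN are the printed method limits; the
remaining per-analyte LOD/LOQ and all PNEC values are synthetic stand-ins
(plausible order-of-magnitude values, not measured ones) — compound-level
analytical limits and no-effect concentrations must be supplied by the user
for real assessments.
"""

from __future__ import annotations

from .core_data import AnalyteClass, AnalyteDef

__all__ = ["default_panel", "PARENT_CODES", "METABOLITE_CODES", "DEFAULT_PAIRING"]

PARENT_CODES = ["ACE", "CLO", "DIN", "IMI", "IMID", "NIT", "THI", "THIA"]
METABOLITE_CODES = ["N-DM-ACE", "DN-IMI", "5-OH-IMI", "IMI-urea", "N-DN-THIA", "DIN-U"]

# parent -> (pair label, metabolite set); mIMIs aggregates IMI's three derivatives
DEFAULT_PAIRING: dict[str, tuple[str, list[str]]] = {
    "DIN": ("DIN/DIN-U", ["DIN-U"]),
    "IMI": ("IMI/mIMIs", ["DN-IMI", "5-OH-IMI", "IMI-urea"]),
    "THIA": ("THIA/N-DN-THIA", ["N-DN-THIA"]),
    "ACE": ("ACE/N-DM-ACE", ["N-DM-ACE"]),
}


def default_panel() -> list[AnalyteDef]:
    """Return the 14-analyte default panel (synthetic LOD/LOQ/PNEC stand-ins)."""
    P = AnalyteClass.PARENT
    M = AnalyteClass.METABOLITE
    return [
        AnalyteDef("ACE", P, None, lod=0.0040, loq=0.0133, pnec=500.0),
        AnalyteDef("CLO", P, None, lod=0.0090, loq=0.0300, pnec=130.0),
        AnalyteDef("DIN", P, None, lod=0.0349, loq=0.1166, pnec=600.0),
        AnalyteDef("IMI", P, None, lod=0.0060, loq=0.0200, pnec=8.0),
        AnalyteDef("IMID", P, None, lod=0.0050, loq=0.0167, pnec=400.0),
        AnalyteDef("NIT", P, None, lod=0.0120, loq=0.0400, pnec=1000.0),
        AnalyteDef("THI", P, None, lod=0.0015, loq=0.0050, pnec=10.0),
        AnalyteDef("THIA", P, None, lod=0.0080, loq=0.0267, pnec=140.0),
        AnalyteDef("N-DM-ACE", M, "ACE", lod=0.0070, loq=0.0233, pnec=None),
        AnalyteDef("DN-IMI", M, "IMI", lod=0.0100, loq=0.0333, pnec=None),
        AnalyteDef("5-OH-IMI", M, "IMI", lod=0.0150, loq=0.0500, pnec=None),
        AnalyteDef("IMI-urea", M, "IMI", lod=0.0110, loq=0.0367, pnec=None),
        AnalyteDef("N-DN-THIA", M, "THIA", lod=0.0130, loq=0.0433, pnec=None),
        AnalyteDef("DIN-U", M, "DIN", lod=0.0200, loq=0.0667, pnec=None),
    ]
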