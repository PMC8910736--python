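"""Built-in reference set of CHH-derivatized RCCs from pea root nodules.

Twenty-two differentially abundant derivatives annotated by reversed-
phase UHPLC-Orbitrap-MS in nodules of osmotically stressed pea, kept as
package data: retention time, observed and reference (calculated) m/z of
the protonated cation, elemental composition, published ppm error and
group fold change, and the tentative structure assignment.  Fragment
peak lists (ion-trap CID, one-decimal m/z with relative intensities) are
carried for the derivatives used as worked examples.

The reference m/z values are the published calculated values.  For a few
entries they differ from a recomputation out of the composition by more
than the 4th decimal (up to 1.4 mDa for the lipid-derived cation); the
published ppm errors are consistent with the published reference m/z,
so both are preserved verbatim as data while ``monoisotopic_mass``
always reports the recomputed value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chh import Ms2Spectrum, rcc_from_derivative
from .formula import ElementalFormula

__all__ = ["KnownDerivative", "REFERENCE_DERIVATIVES", "reference_rccs"]


@dataclass(frozen=True)
class KnownDerivative:
    rt_min: float
    observed_mz: float
    reference_mz: float
    composition: str
    error_ppm: float
    fold_change: float
    direction: str  # "up" | "down"
    assignment: str
    fragments: tuple[tuple[float, float], ...] | None = None

    @property
    def cation(self) -> ElementalFormula:
        return ElementalFormula.parse(self.composition, charge=1)

    @property
    def rcc(self) -> ElementalFormula:
        return rcc_from_derivative(self.cation)

    def ms2(self) -> Ms2Spectrum | None:
        if self.fragments is None:
            return None
        return Ms2Spectrum(self.observed_mz, self.fragments)


REFERENCE_DERIVATIVES: tuple[KnownDerivative, ...] = (
    KnownDerivative(
        3.7, 348.1555, 348.1554, "C17H22N3O5", -0.3, 2.7, "up", "glyceraldehyde",
        fragments=(
            (216.1, 6), (261.1, 100), (262.1, 31), (276.1, 19), (301.2, 3),
            (303.2, 9.4), (318.1, 94), (319.2, 6), (330.1, 13), (331.2, 3),
        ),
    ),
    KnownDerivative(
        6.2, 388.1507, 388.1503, "C19H22N3O6", -1.0, 2.1, "up",
        "4,5-dioxovaleric acid",
        fragments=(
            (216.0, 7.1), (262.2, 18.6), (276.1, 5.7), (288.1, 7.1),
            (301.0, 6.4), (315.9, 2.9), (318.1, 13.6), (328.1, 9.3),
            (343.2, 7.9), (344.1, 15.7), (352.4, 15.0), (360.0, 4.6),
            (370.1, 100), (371.1, 20.0),
        ),
    ),
    KnownDerivative(6.6, 288.1344, 288.1344, "C15H18N3O3", 0.0, 1.5, "down",
                    "formaldehyde"),
    KnownDerivative(7.9, 316.1655, 316.1656, "C17H22N3O3", 0.3, 1.7, "down",
                    "unknown m/z 316.17, propanal-related signal 1"),
    KnownDerivative(
        8.2, 372.1914, 372.1917, "C20H26N3O4", 0.8, 1.6, "down",
        "4-hydroxy-5-hexenal, isomer 1",
        fragments=(
            (218.1, 0.05), (244.1, 30), (261.1, 0.5), (276.1, 16),
            (302.2, 0.6), (315.2, 0.25), (328.3, 0.1), (342.2, 0.3),
            (353.0, 2.5), (354.2, 100),
        ),
    ),
    KnownDerivative(8.3, 316.1655, 316.1656, "C17H22N3O3", 0.3, 2.0, "down",
                    "unknown m/z 316.17, propanal-related signal 2"),
    KnownDerivative(8.3, 398.2074, 398.2073, "C22H28N3O4", -0.3, 1.6, "down",
                    "hydroxy-2,4-octadienal"),
    KnownDerivative(8.4, 372.1917, 372.1917, "C20H26N3O4", 0.0, 1.6, "down",
                    "4-hydroxy-5-hexenal, isomer 2"),
    KnownDerivative(8.5, 328.1653, 328.1656, "C18H22N3O3", 0.9, 2.1, "down",
                    "methacrolein"),
    KnownDerivative(8.5, 360.1915, 360.1915, "C19H26N3O4", 0.6, 1.8, "down",
                    "3-hydroxy-pentanal"),
    KnownDerivative(8.5, 414.2021, 414.2022, "C22H28N3O5", 0.2, 2.2, "down",
                    "8-oxo-4-hydroxy-6-octenal"),
    KnownDerivative(8.5, 426.2021, 426.2022, "C23H28N3O5", 0.2, 2.7, "down",
                    "9-oxo-2,4-nonadienoic acid"),
    KnownDerivative(8.8, 444.2120, 444.2127, "C23H30N3O6", 1.6, 2.1, "down",
                    "9-oxo-2,6-dihydroxy-1-nonenal"),
    KnownDerivative(8.8, 472.2450, 472.2439, "C25H34N3O6", -2.3, 3.8, "down",
                    "4-hydroxy-11-oxo-2-undecenoic acid"),
    KnownDerivative(8.9, 330.1811, 330.1812, "C18H24N3O3", 0.3, 1.6, "down",
                    "butanal"),
    KnownDerivative(9.4, 388.2226, 388.2229, "C21H30N3O4", 0.8, 2.0, "down",
                    "7-hydroxy-heptanal"),
    KnownDerivative(9.9, 288.1346, 288.1344, "C15H18N3O3", -0.7, 5.3, "down",
                    "unknown m/z 288.13, formaldehyde-related signal 1"),
    KnownDerivative(10.1, 496.2807, 496.2802, "C28H38N3O5", -1.0, 1.7, "up",
                    "unknown, m/z 496.28, signal 4"),
    KnownDerivative(10.2, 368.1964, 368.1968, "C21H26N3O3", 1.1, 1.7, "down",
                    "2,4-heptadienal"),
    KnownDerivative(10.3, 444.2495, 444.2490, "C24H34N3O5", -1.1, 1.9, "down",
                    "10-oxo-4-hydroxy-decanal"),
    KnownDerivative(11.0, 288.1344, 288.1344, "C15H18N3O3", 0.0, 2.1, "down",
                    "unknown m/z 288.13, formaldehyde-related signal 2"),
    KnownDerivative(13.5, 758.5685, 758.5667, "C40H79N4O7P", -2.4, 4.4, "down",
                    "unknown, m/z 758.57, signal 2"),
)


def reference_rccs() -> list[ElementalFormula]:
    """Neutral RCC formulas recovered from the reference derivatives."""
    return [d.rcc for d in REFERENCE_DERIVATIVES]
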