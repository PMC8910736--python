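"""Derivatization chemistry of CHH hydrazones.

7-(Diethylamino)coumarin-3-carbohydrazide (CHH, C14H17N3O3) traps
reactive carbonyl compounds (RCCs) as hydrazones: the hydrazide and the
carbonyl condense with loss of one water, and the tertiary amino group
gives the derivative excellent positive-mode ionization.  Every observed
feature is therefore a protonated cation

    [RCC + CHH - H2O + H]+

whose composition must contain the coumarin scaffold.  Collision-induced
dissociation of these cations is dominated by two diagnostic fragments,
m/z 244.1 (loss of the RCC plus hydrazine, -N2H4) and m/z 262.1 (loss of
the RCC plus the amino group, -NH2), which mark a feature as a CHH
derivative regardless of the carbonyl attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .formula import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ElementalFormula,
    monoisotopic_mass,
    ppm_error,
)

__all__ = [
    "CHH",
    "WATER",
    "PROTON",
    "CATION_SCAFFOLD",
    "DIAGNOSTIC_IONS",
    "NEUTRAL_LOSSES",
    "Ms2Spectrum",
    "AnnotationResult",
    "derivative_from_rcc",
    "rcc_from_derivative",
    "candidate_compositions",
    "annotate_ms2",
    "read_mgf",
]

#: The derivatization reagent, 7-(diethylamino)coumarin-3-carbohydrazide.
CHH = ElementalFormula.parse("C14H17N3O3")
WATER = ElementalFormula.parse("H2O")
PROTON = ElementalFormula({"H": 1}, charge=1)

#: Atoms the CHH scaffold contributes to every derivative cation
#: (CHH - H2O + H); any annotated cation must contain at least these.
CATION_SCAFFOLD = CHH - WATER + PROTON  # C14H16N3O2, charge +1

#: Fragment m/z values diagnostic for CHH derivatives (ion-trap CID,
#: printed to one decimal).
DIAGNOSTIC_IONS = (244.1, 262.1)

#: Common neutral losses from the precursor, monoisotopic masses in Da.
NEUTRAL_LOSSES: dict[str, float] = {
    "H2O": 18.011,
    "NH2": 16.019,
    "N2H4": 32.037,
    "CO2": 43.990,
    "CH2O2": 46.005,
}

#: Default per-element caps for composition search; the smallest box
#: containing every derivative in the built-in reference set (up to the
#: C40H79N4O7P lipid-derived cation).
DEFAULT_ELEMENT_BOUNDS: dict[str, int] = {
    "C": 45, "H": 90, "N": 5, "O": 10, "P": 1, "S": 1,
}

#: Scaffold-imposed minimum counts for a candidate cation.
SCAFFOLD_MINIMUM: dict[str, int] = {"C": 15, "H": 16, "N": 3, "O": 3}


@dataclass(frozen=True)
class Ms2Spectrum:
    """A fragment spectrum: precursor m/z and (m/z, relative %) peaks."""

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        peaks = tuple((float(m), float(i)) for m, i in self.peaks)
        for m, i in peaks:
            if m <= 0:
                raise ValueError(f"fragment m/z must be positive, got {m}")
            if not (0 < i <= 100):
                raise ValueError(f"relative intensity must be in (0, 100], got {i}")
            if m > self.precursor_mz + 1.0:
                raise ValueError(
                    f"fragment m/z {m} above precursor {self.precursor_mz}"
                )
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class AnnotationResult:
    """Outcome of MS/MS-level annotation of one feature."""

    is_chh_derivative: bool
    rcc_neutral_formula: ElementalFormula | None = None
    matched_diagnostic_ions: tuple[float, ...] = ()
    matched_neutral_losses: tuple[tuple[str, float], ...] = ()
    ppm_error: float | None = None


def derivative_from_rcc(rcc: ElementalFormula) -> ElementalFormula:
    """Protonated hydrazone cation formed from a neutral carbonyl.

    cation = RCC + CHH - H2O + H, charge +1.  One carbonyl is
    derivatized; polycarbonyls are treated as mono-derivatized.
    """
    if rcc.charge != 0:
        raise ValueError("RCC formula must be neutral")
    if rcc.get("C") < 1 or rcc.get("O") < 1:
        raise ValueError(
            f"{rcc.hill()} is not a carbonyl compound (needs >=1 C and >=1 O)"
        )
    return rcc + CATION_SCAFFOLD


def rcc_from_derivative(cation: ElementalFormula) -> ElementalFormula:
    """Neutral carbonyl recovered from a derivative cation (exact inverse)."""
    if cation.charge != 1:
        raise ValueError("derivative must be a +1 cation")
    if not cation.contains(CATION_SCAFFOLD):
        raise ValueError(f"{cation.hill()} is not a CHH derivative")
    rcc = cation - CATION_SCAFFOLD
    return ElementalFormula(rcc.counts, 0)


def candidate_compositions(
    observed_mz: float,
    tol_ppm: float = 3.0,
    element_bounds: dict[str, int] | None = None,
) -> list[ElementalFormula]:
    """Cation compositions within a ppm window that contain the scaffold.

    Exhaustively enumerates C/H/N/O(/P/S) cation formulas whose m/z lies
    within ``tol_ppm`` of ``observed_mz`` and whose counts dominate the
    CHH cation scaffold (>=C15, >=H16, N >= 3, O >= 3), sorted by
    absolute ppm error.  An empty list is a valid outcome.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    bounds = dict(DEFAULT_ELEMENT_BOUNDS)
    if element_bounds:
        bounds.update(element_bounds)

    lo = observed_mz * (1 - tol_ppm * 1e-6)
    hi = observed_mz * (1 + tol_ppm * 1e-6)
    mC, mH = MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"]
    out: list[tuple[float, ElementalFormula]] = []
    for p in range(0, bounds.get("P", 0) + 1):
        for s in range(0, bounds.get("S", 0) + 1):
            for n in range(SCAFFOLD_MINIMUM["N"], bounds["N"] + 1):
                for o in range(SCAFFOLD_MINIMUM["O"], bounds["O"] + 1):
                    base = (
                        n * MONOISOTOPIC_MASS["N"]
                        + o * MONOISOTOPIC_MASS["O"]
                        + p * MONOISOTOPIC_MASS["P"]
                        + s * MONOISOTOPIC_MASS["S"]
                        - ELECTRON_MASS
                    )
                    for c in range(SCAFFOLD_MINIMUM["C"], bounds["C"] + 1):
                        rem_lo = lo - base - c * mC
                        rem_hi = hi - base - c * mC
                        if rem_hi < SCAFFOLD_MINIMUM["H"] * mH:
                            break  # heavier C only lowers the H budget
                        h_lo = max(SCAFFOLD_MINIMUM["H"], math.ceil(rem_lo / mH))
                        h_hi = min(bounds["H"], math.floor(rem_hi / mH))
                        for h in range(h_lo, h_hi + 1):
                            f = ElementalFormula(
                                {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s},
                                charge=1,
                            )
                            err = ppm_error(observed_mz, monoisotopic_mass(f))
                            if abs(err) <= tol_ppm:
                                out.append((abs(err), f))
    out.sort(key=lambda t: (t[0], t[1].hill()))
    return [f for _, f in out]


def annotate_ms2(
    spec: Ms2Spectrum,
    frag_tol: float = 0.3,
    composition: ElementalFormula | None = None,
    observed_mz: float | None = None,
) -> AnnotationResult:
    """Flag a spectrum as a CHH derivative and annotate neutral losses.

    A peak within ``frag_tol`` of either diagnostic ion (m/z 244.1 or
    262.1) marks the feature as a derivative; peaks are additionally
    annotated as known neutral losses from the precursor.  If a cation
    ``composition`` is supplied, the RCC formula is recovered from it and
    the precursor ppm error is reported.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    diagnostics = tuple(
        d
        for d in DIAGNOSTIC_IONS
        if any(abs(m - d) <= frag_tol for m, _ in spec.peaks)
    )
    losses = []
    for m, _ in spec.peaks:
        delta = spec.precursor_mz - m
        for name, loss_mass in NEUTRAL_LOSSES.items():
            if abs(delta - loss_mass) <= frag_tol:
                losses.append((name, loss_mass))
                break

    rcc = None
    err = None
    scaffold_ok = False
    if composition is not None:
        scaffold_ok = composition.contains(CATION_SCAFFOLD)
        if scaffold_ok:
            rcc = rcc_from_derivative(composition)
        calc = monoisotopic_mass(composition)
        err = ppm_error(
            observed_mz if observed_mz is not None else spec.precursor_mz, calc
        )
    return AnnotationResult(
        is_chh_derivative=bool(diagnostics) or scaffold_ok,
        rcc_neutral_formula=rcc,
        matched_diagnostic_ions=diagnostics,
        matched_neutral_losses=tuple(losses),
        ppm_error=err,
    )


def read_mgf(path) -> list[Ms2Spectrum]:
    """Read MS/MS peak lists from an MGF file.

    Intensities are rescaled to relative percent of the base peak.
    """
    from pyteomics import mgf

    spectra = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            mzs = entry["m/z array"]
            ints = entry["intensity array"]
            if len(mzs) == 0:
                continue
            top = float(max(ints))
            peaks = tuple(
                (float(m), max(float(i) / top * 100.0, 1e-6))
                for m, i in zip(mzs, ints)
            )
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=float(entry["params"]["pepmass"][0]),
                    peaks=peaks,
                )
            )
    return spectra
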