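"""Derivatization arithmetic, composition search and MS/MS annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbonylome.chh import (
    CATION_SCAFFOLD,
    Ms2Spectrum,
    annotate_ms2,
    candidate_compositions,
    derivative_from_rcc,
    rcc_from_derivative,
    read_mgf,
)
from carbonylome.formula import ElementalFormula, monoisotopic_mass, ppm_error
from carbonylome.registry import REFERENCE_DERIVATIVES, reference_rccs


class TestDerivatization:
    @pytest.mark.parametrize(
        ("rcc", "cation"),
        [
            ("CH2O", "C15H18N3O3"),    # formaldehyde
            ("C3H6O3", "C17H22N3O5"),  # glyceraldehyde
            ("C5H6O4", "C19H22N3O6"),  # 4,5-dioxovaleric acid (mono-derivative)
        ],
    )
    def test_known_hydrazone_cations(self, rcc, cation):
        got = derivative_from_rcc(ElementalFormula.parse(rcc))
        assert got.hill().rstrip("+") == cation
        assert got.charge == 1

    def test_non_carbonyl_rejected(self):
        with pytest.raises(ValueError, match="not a carbonyl"):
            derivative_from_rcc(ElementalFormula.parse("CH4"))

    def test_non_scaffold_cation_rejected(self):
        with pytest.raises(ValueError, match="not a CHH derivative"):
            rcc_from_derivative(ElementalFormula({"C": 5, "H": 10, "O": 1},
                                                 charge=1))

    @pytest.mark.parametrize("entry", REFERENCE_DERIVATIVES,
                             ids=lambda e: e.assignment[:24])
    def test_registry_compositions_contain_scaffold(self, entry):
        assert entry.cation.contains(CATION_SCAFFOLD)
        # round trip through the recovered RCC
        assert derivative_from_rcc(entry.rcc).hill() == entry.cation.hill()

    def test_octadienal_rcc_recovered(self):
        cation = ElementalFormula.parse("C22H28N3O4", charge=1)
        assert rcc_from_derivative(cation).hill() == "C8H12O2"


@settings(deadline=None, max_examples=200)
@given(
    c=st.integers(1, 30), o=st.integers(1, 6),
    h=st.integers(0, 60), n=st.integers(0, 2),
)
def test_derivatization_round_trip(c, o, h, n):
    """rcc_from_derivative is the exact inverse of derivative_from_rcc."""
    rcc = ElementalFormula({"C": c, "O": o, "H": h, "N": n})
    assert rcc_from_derivative(derivative_from_rcc(rcc)).counts == rcc.counts


class TestCandidateCompositions:
    def test_glyceraldehyde_found(self):
        hits = candidate_compositions(348.1554, 3.0)
        assert "C17H22N3O5+" in [f.hill() for f in hits]

    def test_below_scaffold_mass_empty(self):
        assert candidate_compositions(100.0, 3.0) == []

    def test_all_candidates_within_tolerance_brute_force(self):
        """Every hit re-scores within tolerance; brute-force enumeration
        over the same bounds finds nothing extra."""
        observed, tol = 388.1503, 3.0
        hits = {f.hill() for f in candidate_compositions(observed, tol)}
        for f in candidate_compositions(observed, tol):
            assert abs(ppm_error(observed, monoisotopic_mass(f))) <= tol
        brute = set()
        for c in range(15, 46):
            for h in range(16, 91):
                for n in range(3, 6):
                    for o in range(3, 11):
                        for p in range(2):
                            for s in range(2):
                                f = ElementalFormula(
                                    {"C": c, "H": h, "N": n, "O": o,
                                     "P": p, "S": s}, charge=1)
                                m = monoisotopic_mass(f)
                                if m > 2 * observed:
                                    break
                                if abs(ppm_error(observed, m)) <= tol:
                                    brute.add(f.hill())
        assert hits == brute

    def test_sorted_by_abs_ppm(self):
        hits = candidate_compositions(472.2450, 30.0)
        errs = [abs(ppm_error(472.2450, monoisotopic_mass(f))) for f in hits]
        assert errs == sorted(errs)


class TestAnnotateMs2:
    def test_dova_spectrum_losses(self):
        """The dioxovaleric-acid derivative shows the m/z 262 diagnostic,
        water loss (370.1) and CO2 loss (344.1)."""
        spec = REFERENCE_DERIVATIVES[1].ms2()
        res = annotate_ms2(spec)
        assert res.is_chh_derivative
        assert 262.1 in res.matched_diagnostic_ions
        names = {n for n, _ in res.matched_neutral_losses}
        assert {"H2O", "CO2"} <= names

    def test_244_diagnostic(self):
        spec = REFERENCE_DERIVATIVES[4].ms2()  # 4-hydroxy-5-hexenal
        res = annotate_ms2(spec)
        assert 244.1 in res.matched_diagnostic_ions

    def test_unrelated_spectrum_not_flagged(self):
        res = annotate_ms2(Ms2Spectrum(300.0, ((100.0, 50.0),)))
        assert not res.is_chh_derivative
        assert res.matched_diagnostic_ions == ()
        assert res.matched_neutral_losses == ()

    def test_empty_peak_list_ok(self):
        res = annotate_ms2(Ms2Spectrum(300.0, ()))
        assert not res.is_chh_derivative

    def test_composition_recovers_rcc(self):
        spec = REFERENCE_DERIVATIVES[0].ms2()
        res = annotate_ms2(
            spec, composition=ElementalFormula.parse("C17H22N3O5", charge=1)
        )
        assert res.rcc_neutral_formula.hill() == "C3H6O3"
        assert abs(res.ppm_error) < 3

    def test_spectrum_invariants_enforced(self):
        with pytest.raises(ValueError):
            Ms2Spectrum(300.0, ((100.0, 0.0),))
        with pytest.raises(ValueError):
            Ms2Spectrum(300.0, ((302.0, 10.0),))


def test_mgf_round_trip(tmp_path):
    """Spectra written as MGF are read back with the same peaks."""
    path = tmp_path / "spec.mgf"
    path.write_text(
        "BEGIN IONS\nTITLE=row2\nPEPMASS=388.1507\nCHARGE=1+\n"
        "262.2 18.6\n344.1 15.7\n370.1 100.0\nEND IONS\n"
    )
    (spec,) = read_mgf(path)
    assert spec.precursor_mz == pytest.approx(388.1507)
    assert len(spec.peaks) == 3
    res = annotate_ms2(spec)
    assert res.is_chh_derivative


def test_reference_rccs_are_carbonyls():
    for rcc in reference_rccs():
        assert rcc.get("C") >= 1 and rcc.get("O") >= 1
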