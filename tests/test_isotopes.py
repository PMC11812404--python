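"""Natural-abundance patterns, correction matrices, and stripping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from polysirm import (
    IsotopologueVector,
    build_correction_matrix,
    enrichment_summary,
    natural_pattern,
    parse_formula,
    strip,
)
from polysirm.constants import ISOTOPES
from polysirm.formulas import derivatize
from polysirm.isotopes import CorrectedDistribution

A13 = ISOTOPES["C"][1][1]  # natural 13C abundance


def binom_pattern(n, p=A13):
    """Independent binomial oracle for carbon-only patterns."""
    k = np.arange(n + 1)
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def test_natural_pattern_single_carbon():
    assert np.allclose(natural_pattern(parse_formula("C1")), [1 - A13, A13])


def test_natural_pattern_carbon_binomial_oracle():
    for n in [2, 5, 17, 45]:
        pat = natural_pattern(parse_formula(f"C{n}"))
        assert np.allclose(pat, binom_pattern(n), atol=1e-14)
        assert pat.sum() == pytest.approx(1.0, abs=1e-12)


def test_natural_pattern_two_carbons_reference_values():
    pat = natural_pattern(parse_formula("C2"))
    assert pat == pytest.approx([0.97871449, 0.02117102, 0.00011449], abs=1e-7)


def test_natural_pattern_empty_formula_is_delta():
    from polysirm import MolecularFormula

    assert np.allclose(natural_pattern(MolecularFormula({})), [1.0])
    # H-only formula under carbon-only correction: no carbon, still delta
    assert np.allclose(natural_pattern(parse_formula("H10")), [1.0])


def test_natural_pattern_multi_element_matches_manual_convolution():
    f = parse_formula("C2O1")
    pat = natural_pattern(f, elements=("C", "O"))
    o = ISOTOPES["O"]
    o_pmf = np.array([o[0][1], o[1][1], o[2][1]])
    expected = np.convolve(binom_pattern(2), o_pmf / o_pmf.sum())
    assert np.allclose(pat, expected, atol=1e-14)


# --------------------------------------------------------------------------
# correction matrices


def test_correction_matrix_one_carbon_no_tag():
    sp = derivatize(parse_formula("CH4"), 0)
    A = build_correction_matrix(sp).A
    assert np.allclose(A, [[1 - A13, 0.0], [A13, 1.0]])


def test_correction_matrix_zero_abundance_is_identity():
    sp = derivatize(parse_formula("C4H12N2"), 2)
    table = dict(ISOTOPES)
    table["C"] = [(12.0, 1.0), (13.0033548, 0.0)]
    A = build_correction_matrix(sp, abundances=table).A
    assert np.allclose(A, np.eye(5))


def test_correction_matrix_column0_is_full_natural_pattern(registry):
    for sp in registry.values():
        n = sp.labelable_carbons
        A = build_correction_matrix(sp).A
        full = natural_pattern(parse_formula(f"C{n + sp.tag_carbons}"))
        assert np.allclose(A[:, 0], full[: n + 1], atol=1e-14)


def test_correction_columns_are_untruncated_pmfs(registry):
    # column sums equal 1 up to the mass lost to truncation at shift n
    for sp in registry.values():
        A = build_correction_matrix(sp).A
        n = sp.labelable_carbons
        sums = A.sum(axis=0)
        assert np.all(sums <= 1 + 1e-12)
        # column n cannot be truncated upward beyond... the last column keeps
        # only shift-0 mass of the tag pattern; explicit untruncated check:
        tag_pat = natural_pattern(parse_formula(f"C{sp.tag_carbons}")) if sp.tag_carbons else np.array([1.0])
        assert A[n, n] == pytest.approx(tag_pat[0], abs=1e-12)
        assert np.allclose(np.triu(A, 1), 0.0)  # lower triangular (purity off)


def test_purity_one_matches_purity_off(registry):
    sp = registry["putrescine"]
    A_off = build_correction_matrix(sp).A
    A_on = build_correction_matrix(sp, purity=1.0).A
    assert np.array_equal(A_off, A_on)


def test_purity_correction_shifts_mass_down():
    sp = derivatize(parse_formula("C4H12N2"), 0)
    A = build_correction_matrix(sp, purity=0.97).A
    # a fully labeled molecule can now appear one shift lower
    assert A[3, 4] > 0
    assert A.sum(axis=0) == pytest.approx(np.ones(5), abs=1e-12)


@pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
def test_invalid_purity_rejected(p, registry):
    with pytest.raises(ValueError):
        build_correction_matrix(registry["putrescine"], purity=p)


# --------------------------------------------------------------------------
# stripping


def _strip_areas(sp, areas, cm):
    return strip(IsotopologueVector(species=sp, areas=areas), cm)


def test_strip_roundtrip_noise_free(registry, rng):
    for sp in registry.values():
        n = sp.labelable_carbons
        cm = build_correction_matrix(sp)
        x = rng.dirichlet(np.ones(n + 1))
        d = _strip_areas(sp, cm.A @ x * 1e7, cm)
        assert np.abs(d.fractions - x).max() < 1e-10
        assert d.residual < 1e-10


def test_strip_unlabeled_control_recovers_f0(registry):
    # natural-abundance-only measurement: all signal returns to shift 0
    for sp in registry.values():
        cm = build_correction_matrix(sp)
        d = _strip_areas(sp, cm.A[:, 0] * 2e6, cm)
        assert d.fractions[0] >= 0.99
        assert d.sigma13C <= 0.01


def test_strip_scale_invariance(registry, rng):
    sp = registry["spermidine"]
    cm = build_correction_matrix(sp)
    m = cm.A @ rng.dirichlet(np.ones(8)) * np.exp(rng.normal(0, 0.05, 8))
    d1 = _strip_areas(sp, m, cm)
    d2 = _strip_areas(sp, 137.5 * m, cm)
    assert np.allclose(d1.fractions, d2.fractions, atol=1e-12)
    assert d1.residual == pytest.approx(d2.residual, abs=1e-12)


def test_strip_nnls_stays_nonnegative_where_inversion_goes_negative(registry):
    sp = registry["putrescine"]
    cm = build_correction_matrix(sp)
    m = cm.A[:, 0].copy()
    m[1] = 0.0  # M+1 below its natural-abundance share: inversion dives negative
    unconstrained = np.linalg.solve(cm.A, m)
    assert unconstrained.min() < 0
    d = _strip_areas(sp, m, cm)
    assert np.all(d.fractions >= 0)


def test_strip_matches_back_substitution_when_feasible(registry, rng):
    # NNLS equals plain triangular solve whenever that solve is nonnegative
    for name in ["putrescine", "ornithine", "agmatine"]:
        sp = registry[name]
        cm = build_correction_matrix(sp)
        x = rng.dirichlet(np.ones(sp.labelable_carbons + 1))
        m = cm.A @ x
        direct = np.linalg.solve(cm.A, m)
        assert direct.min() >= -1e-12
        d = _strip_areas(sp, m, cm)
        assert np.allclose(d.fractions, direct / direct.sum(), atol=1e-9)


def test_strip_rejects_zero_and_mismatched_input(registry):
    sp = registry["putrescine"]
    cm = build_correction_matrix(sp)
    with pytest.raises(ValueError):
        _strip_areas(sp, np.zeros(5), cm)
    other = build_correction_matrix(registry["spermidine"])
    with pytest.raises(ValueError):
        strip(IsotopologueVector(species=sp, areas=np.ones(5)), other)


def test_isotopologue_vector_validation(registry):
    sp = registry["putrescine"]
    with pytest.raises(ValueError):
        IsotopologueVector(species=sp, areas=np.ones(3))
    with pytest.raises(ValueError):
        IsotopologueVector(species=sp, areas=-np.ones(5))
    with pytest.raises(ValueError):
        IsotopologueVector(species=sp, areas=np.ones(5), arm="labelled")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_roundtrip_identity_property(data, registry):
    name = data.draw(st.sampled_from(sorted(registry)))
    sp = registry[name]
    n = sp.labelable_carbons
    raw = data.draw(
        st.lists(st.floats(0.001, 1.0), min_size=n + 1, max_size=n + 1)
    )
    x = np.array(raw) / np.sum(raw)
    cm = build_correction_matrix(sp)
    d = _strip_areas(sp, cm.A @ x * 5e6, cm)
    assert np.abs(d.fractions - x).max() < 1e-8


# --------------------------------------------------------------------------
# enrichment metrics


@pytest.mark.parametrize(
    "fractions,sigma,atom",
    [
        ([1, 0, 0, 0, 0], 0.0, 0.0),  # unlabeled
        ([0, 0, 0, 0, 1], 1.0, 1.0),  # fully labeled
        ([0.5, 0, 0.5, 0, 0], 0.5, 0.25),  # n=4, half at M+2
    ],
)
def test_enrichment_metrics_closed_form(registry, fractions, sigma, atom):
    sp = derivatize(parse_formula("C4H12N2"), 2)
    d = CorrectedDistribution(
        species=sp, fractions=np.array(fractions, float), residual=0.0
    )
    assert d.sigma13C == pytest.approx(sigma)
    assert d.atom_enrichment == pytest.approx(atom)
    tbl = enrichment_summary(d)
    assert len(tbl) == 5
    assert tbl["fraction"].to_numpy() == pytest.approx(fractions)
    assert np.allclose(tbl["sigma13C"].to_numpy(), sigma)
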