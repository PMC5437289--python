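"""Correction-matrix construction and constrained MID recovery."""

import itertools

import numpy as np
import pytest

from tracermet.chem_core import FragmentSpec, IsotopeTable, parse_formula
from tracermet.isotope_correction import (
    TracerPurity,
    build_correction_matrix,
    correct_mid,
    _purity_distribution,
)
from tracermet.peak_integration import RawMID
from tracermet.synthetic_data import forward_measure, NoiseModel


def test_identity_matrix_without_heavy_isotopes(pure_light_table):
    fragment = FragmentSpec("toy", parse_formula("C"), n_carbons=1)
    cm = build_correction_matrix(fragment, pure_light_table, purity=TracerPurity(1.0))
    assert np.allclose(cm.matrix, np.eye(2))


def test_column_zero_is_natural_distribution(carbon_only_table):
    fragment = FragmentSpec("toy", parse_formula("C2"), n_carbons=2)
    cm = build_correction_matrix(fragment, carbon_only_table)
    assert np.allclose(cm.matrix[:, 0], [0.97871449, 0.02117102, 0.00011449], atol=5e-9)


def test_purity_factor_is_binomial():
    # one tracer atom at 99% enrichment → [0.01, 0.99]
    assert np.allclose(_purity_distribution(1, TracerPurity(0.99)), [0.01, 0.99])
    # no purity declared → delta at j
    assert np.allclose(_purity_distribution(2, None), [0, 0, 1])


def test_purity_outside_range_rejected():
    for bad in (0.5, 0.3, 1.01):
        with pytest.raises(ValueError):
            TracerPurity(bad)


def test_matrix_columns_are_shifted_reduced_distributions(default_isotopes):
    """Column j = natural distribution of the fragment minus j carbons, shifted by j."""
    fragment = FragmentSpec("ala", parse_formula("C11H26NO2Si2"), n_carbons=3)
    cm = build_correction_matrix(fragment, default_isotopes)
    from tracermet.chem_core import natural_distribution

    for j in range(4):
        reduced = natural_distribution(
            fragment.fragment_formula.remove("C", j), default_isotopes
        )
        expected = np.zeros(4)
        upto = min(len(reduced), 4 - j)
        expected[j : j + upto] = reduced[:upto]
        assert np.allclose(cm.matrix[:, j], expected, atol=1e-12)


@pytest.mark.parametrize("purity", [None, 0.99, 0.98])
def test_pure_column_measurements_recover_unit_vectors(default_isotopes, purity):
    fragment = FragmentSpec("glu", parse_formula("C19H42NO4Si3"), n_carbons=5)
    tp = TracerPurity(purity) if purity else None
    cm = build_correction_matrix(fragment, default_isotopes, tp)
    for j in (0, fragment.n_carbons):
        raw = RawMID("glu", cm.matrix[:, j] * 1e6)
        corrected = correct_mid(raw, cm)
        expected = np.zeros(6)
        expected[j] = 1.0
        assert np.allclose(corrected.fractions, expected, atol=1e-9)


def test_forward_then_invert_recovers_truth(default_isotopes):
    fragment = FragmentSpec("toy", parse_formula("C2H4O"), n_carbons=2)
    cm = build_correction_matrix(fragment, default_isotopes)
    truth = np.array([0.2, 0.3, 0.5])
    raw = RawMID("toy", cm.matrix @ truth * 5e5)
    corrected = correct_mid(raw, cm)
    assert np.allclose(corrected.fractions, truth, atol=1e-9)
    assert corrected.residual_norm < 1e-9
    assert not corrected.flagged


def test_round_trip_on_large_fragments(default_isotopes, rng):
    """Noise-free recovery within 1e-9 for random MIDs on a TBDMS-sized fragment."""
    formula = parse_formula("C20H40O6Si2")
    for n in range(1, 7):
        fragment = FragmentSpec("big", formula, n_carbons=n)
        cm = build_correction_matrix(fragment, default_isotopes, TracerPurity(0.99))
        for _ in range(5):
            truth = rng.dirichlet(np.ones(n + 1))
            corrected = correct_mid(RawMID("big", cm.matrix @ truth), cm)
            assert np.allclose(corrected.fractions, truth, atol=1e-9)
            assert corrected.fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_grid_search_oracle_agreement(default_isotopes, rng):
    """NNLS solution matches exhaustive simplex grid search on 3-dim cases."""
    fragment = FragmentSpec("toy", parse_formula("C5H9NOSi"), n_carbons=2)
    cm = build_correction_matrix(fragment, default_isotopes)
    truth = np.array([0.27, 0.41, 0.32])
    measured = cm.matrix @ truth
    measured_noisy = measured * rng.lognormal(0.0, 0.01, size=3)
    for obs in (measured, measured_noisy):
        corrected = correct_mid(RawMID("toy", obs * 1e6), cm)
        best_x, best_r = None, np.inf
        for i, j in itertools.product(range(101), repeat=2):
            if i + j > 100:
                continue
            x = np.array([i, j, 100 - i - j]) / 100.0
            r = np.linalg.norm(cm.matrix @ x - obs / obs.sum())
            if r < best_r:
                best_x, best_r = x, r
        assert np.max(np.abs(corrected.fractions - best_x)) <= 0.01 + 1e-9
        assert corrected.residual_norm <= best_r + 1e-12


def test_monotone_noise_response(default_isotopes):
    """Mean absolute recovery error grows with multiplicative noise σ."""
    fragment = FragmentSpec("pro", parse_formula("C13H28NO2Si2"), n_carbons=5)
    cm = build_correction_matrix(fragment, default_isotopes)
    truth = np.array([0.3, 0.25, 0.2, 0.1, 0.1, 0.05])
    errors = []
    for sigma in (0.0, 0.005, 0.01, 0.02):
        per_seed = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            errs = [
                np.abs(
                    correct_mid(
                        forward_measure(
                            truth, fragment, default_isotopes,
                            noise=NoiseModel(sigma=sigma), rng=rng,
                        ),
                        cm,
                    ).fractions
                    - truth
                ).mean()
                for _ in range(50)
            ]
            per_seed.append(np.mean(errs))
        errors.append(np.mean(per_seed))
    assert all(a <= b + 1e-12 for a, b in zip(errors, errors[1:]))


def test_ols_mode_reports_clipped_mass(default_isotopes, rng):
    fragment = FragmentSpec("toy", parse_formula("C4H8O2Si"), n_carbons=2)
    cm = build_correction_matrix(fragment, default_isotopes)
    truth = np.array([0.98, 0.02, 0.0])
    raw = forward_measure(truth, fragment, default_isotopes, noise=NoiseModel(sigma=0.05), rng=rng)
    corrected = correct_mid(raw, cm, method="ols")
    assert corrected.clipped_mass >= 0.0
    assert corrected.fractions.min() >= 0.0
    assert corrected.fractions.sum() == pytest.approx(1.0, abs=1e-12)


def test_all_zero_areas_rejected(default_isotopes):
    fragment = FragmentSpec("toy", parse_formula("C2H4O"), n_carbons=2)
    cm = build_correction_matrix(fragment, default_isotopes)
    with pytest.raises(ValueError, match="all-zero"):
        correct_mid(RawMID("toy", np.zeros(3)), cm)


def test_rectangular_matrix_dialect(default_isotopes):
    """Extra measured masses above M+n enter as additional rows."""
    fragment = FragmentSpec("toy", parse_formula("C6H12O3Si"), n_carbons=2)
    cm = build_correction_matrix(fragment, default_isotopes, extra_rows=2)
    assert cm.matrix.shape == (5, 3)
    truth = np.array([0.5, 0.3, 0.2])
    corrected = correct_mid(RawMID("toy", cm.matrix @ truth), cm)
    assert np.allclose(corrected.fractions, truth, atol=1e-9)
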