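"""Natural-abundance (and tracer-purity) correction of mass distribution vectors.

The measured MID of a derivatized fragment mixes tracer-derived labeling
with naturally occurring heavy isotopes (¹³C, ²H, ¹⁵N, ¹⁷O/¹⁸O, ²⁹Si/³⁰Si)
contributed by every atom of the fragment, including the derivatization
groups.  Following the classic correction-matrix approach, column j of the
(n+1)×(n+1) matrix is the predicted measured distribution when exactly j of
the n tracer-accessible carbons carry label: the isotopologue distribution
of the fragment with those j carbons removed from the natural pool,
convolved with the binomial purity distribution of the j tracer atoms at
the substrate's stated enrichment (identity when no purity is declared).

The corrected MID is obtained by non-negative least squares rather than
plain matrix inversion, which avoids negative fractions on noisy data;
unconstrained inversion is available behind ``method="ols"`` for oracle
comparisons.  Corrected fractions are always renormalized to sum to 1; the
residual norm and the mass removed by the non-negativity constraint are
recorded for QC.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .chem_core import FragmentSpec, IsotopeTable, natural_distribution
from .peak_integration import RawMID

__all__ = [
    "CorrectedMID",
    "CorrectionMatrix",
    "TracerPurity",
    "build_correction_matrix",
    "correct_mid",
    "qc_report",
]

#: Residual norm (on MID fractions) above which a correction is flagged.
DEFAULT_RESIDUAL_THRESHOLD = 0.05


@dataclasses.dataclass(frozen=True)
class TracerPurity:
    """Isotopic enrichment per tracer atom, e.g. 0.99 for 99% ¹³C glucose."""

    enrichment: float

    def __post_init__(self) -> None:
        if not 0.5 < self.enrichment <= 1.0:
            raise ValueError(
                f"tracer enrichment must be in (0.5, 1], got {self.enrichment}"
            )


@dataclasses.dataclass(frozen=True)
class CorrectionMatrix:
    """Linear map from tracer-labeling space to measured-MID space.

    ``matrix[i, j]`` is the probability of observing nominal shift i when
    exactly j tracer carbons are labeled.  Square (n+1 rows) by default;
    optionally rectangular with extra measured masses above M+n.
    """

    fragment: FragmentSpec
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n1 = self.fragment.n_carbons + 1
        if m.ndim != 2 or m.shape[1] != n1 or m.shape[0] < n1:
            raise ValueError(
                f"{self.fragment.metabolite}: matrix shape {m.shape} incompatible with n={n1 - 1}"
            )
        if np.any(m < 0):
            raise ValueError(f"{self.fragment.metabolite}: negative matrix entries")
        colsums = m.sum(axis=0)
        if np.any(colsums > 1 + 1e-9) or np.any(colsums < 0.5):
            raise ValueError(
                f"{self.fragment.metabolite}: column sums {colsums} outside [0.5, 1]"
            )
        object.__setattr__(self, "matrix", m)


@dataclasses.dataclass(frozen=True)
class CorrectedMID:
    """Tracer-only mass distribution vector m0..mn with QC diagnostics."""

    metabolite: str
    fractions: np.ndarray
    residual_norm: float
    clipped_mass: float
    flagged: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.metabolite}: corrected fractions must be >= 0 and sum to 1"
            )
        object.__setattr__(self, "fractions", f)


def _purity_distribution(j: int, purity: TracerPurity | None) -> np.ndarray:
    """Shift distribution of j tracer atoms: delta at j, or Binomial(j, p)."""
    if purity is None or j == 0:
        out = np.zeros(j + 1)
        out[j] = 1.0
        return out
    return scipy.stats.binom.pmf(np.arange(j + 1), j, purity.enrichment)


def build_correction_matrix(
    fragment: FragmentSpec,
    isotopes: IsotopeTable | None = None,
    purity: TracerPurity | None = None,
    extra_rows: int = 0,
) -> CorrectionMatrix:
    """Build the natural-abundance (and optional purity) correction matrix.

    Column j is the convolution of (a) the natural isotopologue distribution
    of the fragment with j carbons removed from the natural pool and (b) the
    binomial purity distribution of the j tracer atoms, truncated to the
    measured mass range.  Deterministic.

    Parameters
    ----------
    fragment:
        Fragment specification; the formula must contain >= n_carbons carbons.
    isotopes:
        Abundance table (defaults to standard terrestrial values).
    purity:
        Tracer enrichment per atom; ``None`` disables purity correction
        (natural abundance only).
    extra_rows:
        Number of measured masses above M+n to include as additional rows
        (rectangular matrix dialect).
    """
    if isotopes is None:
        isotopes = IsotopeTable.default()
    n = fragment.n_carbons
    rows = n + 1 + extra_rows
    matrix = np.zeros((rows, n + 1))
    for j in range(n + 1):
        remainder = natural_distribution(
            fragment.fragment_formula.remove("C", j), isotopes
        )
        column = np.convolve(remainder, _purity_distribution(j, purity))
        upto = min(len(column), rows)
        matrix[:upto, j] = column[:upto]
    return CorrectionMatrix(fragment, matrix)


def correct_mid(
    raw: RawMID,
    cm: CorrectionMatrix,
    method: str = "nnls",
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
) -> CorrectedMID:
    """Solve for the tracer-only MID from measured areas.

    Areas are normalized to fractions, the system ``matrix · x ≈ measured``
    is solved (non-negative least squares by default; unconstrained
    ``"ols"`` clips negatives afterwards), and the solution is renormalized
    to sum to 1.  The residual norm and the mass removed by the
    non-negativity constraint are recorded; a residual above
    ``residual_threshold`` flags the result (not fatal).
    """
    total = float(raw.areas.sum())
    if total <= 0:
        raise ValueError(f"{raw.metabolite}: all-zero areas, MID undefined")
    measured = raw.areas / total
    if len(measured) != cm.matrix.shape[0]:
        raise ValueError(
            f"{raw.metabolite}: {len(measured)} measured masses vs "
            f"{cm.matrix.shape[0]} matrix rows"
        )
    unconstrained, *_ = np.linalg.lstsq(cm.matrix, measured, rcond=None)
    if method == "nnls":
        x, residual = scipy.optimize.nnls(cm.matrix, measured)
        clipped = float(-unconstrained[unconstrained < 0].sum())
    elif method == "ols":
        x = unconstrained
        clipped = float(-x[x < 0].sum())
        x = np.clip(x, 0.0, None)
        residual = float(np.linalg.norm(cm.matrix @ x - measured))
    else:
        raise ValueError(f"unknown method {method!r}")
    if x.sum() <= 0:
        raise ValueError(f"{raw.metabolite}: degenerate corrected MID (all zero)")
    fractions = x / x.sum()
    residual = float(residual)
    return CorrectedMID(
        metabolite=raw.metabolite,
        fractions=fractions,
        residual_norm=residual,
        clipped_mass=clipped,
        flagged=residual > residual_threshold,
    )


def qc_report(results: dict[tuple[str, str], CorrectedMID]) -> pd.DataFrame:
    """QC table (sample, metabolite, residual_norm, clipped_mass, flagged)."""
    rows = [
        {
            "sample": sample,
            "metabolite": metabolite,
            "residual_norm": mid.residual_norm,
            "clipped_mass": mid.clipped_mass,
            "flagged": mid.flagged,
        }
        for (sample, metabolite), mid in sorted(results.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "metabolite", "residual_norm", "clipped_mass", "flagged"])
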