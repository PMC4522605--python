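"""Size-exclusion chromatography calibration and oligomer stoichiometry.

The partition coefficient Kav = (Ve - Vo) / (Vt - Vo) is linear in
log10(molecular weight) on a calibrated column. Fitting that line over
standards of known mass lets an unknown's elution volume be converted to a
mass estimate; dividing by the theoretical subunit mass (computed from the
sequence) and snapping to a candidate subunit count yields the inferred
stoichiometry. SEC mass estimates carry up to ~10% error, so the default
candidate set holds only the even counts observed crystallographically for
this family and near-ties are flagged ambiguous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seq_core import ProteinRecord

#: Average residue masses (Da), monomer minus water, to 4 decimals.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528

DEFAULT_CANDIDATES = (2, 4, 6, 8, 10, 12)


@dataclass(frozen=True)
class ColumnGeometry:
    """Void volume and total bed volume of the column (mL)."""

    Vo: float
    Vt: float

    def __post_init__(self) -> None:
        if not self.Vt > self.Vo > 0:
            raise ValueError("require Vt > Vo > 0")


@dataclass(frozen=True)
class Standard:
    name: str
    mw: float  # Da
    Ve: float  # mL

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.name}: molecular weight must be positive")


@dataclass(frozen=True)
class SecCalibration:
    """Least-squares line Kav = slope*log10(mw) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    standards: tuple[Standard, ...]
    log_base: int = 10


@dataclass(frozen=True)
class SecEstimate:
    Kav: float | None
    mw_est: float
    subunit_mw: float
    n_inferred: int
    rel_error: float
    ambiguous: bool


def kav(Ve: float, geom: ColumnGeometry) -> float:
    """Partition coefficient (Ve - Vo) / (Vt - Vo); 0 at the void volume,
    1 at the total bed volume. Warns when Ve is outside the column limits."""
    value = (Ve - geom.Vo) / (geom.Vt - geom.Vo)
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"Ve={Ve} outside column limits [{geom.Vo}, {geom.Vt}]; "
            f"Kav={value:.3f}"
        )
    return value


def fit_calibration(standards: list[Standard],
                    geom: ColumnGeometry) -> SecCalibration:
    """Ordinary least squares of Kav on log10(mw) over the standards."""
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    if len({s.mw for s in standards}) < 2:
        raise ValueError("standards share a single molecular weight; "
                         "the fit is singular")
    for s in standards:
        if not geom.Vo <= s.Ve <= geom.Vt:
            raise ValueError(
                f"standard {s.name!r}: Ve={s.Ve} outside [{geom.Vo}, {geom.Vt}]"
            )
    x = np.log10([s.mw for s in standards])
    y = [kav(s.Ve, geom) for s in standards]
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        warnings.warn("calibration slope is non-negative; check the column")
    r2 = float(fit.rvalue**2) if not math.isnan(fit.rvalue) else 1.0
    return SecCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        standards=tuple(standards),
    )


def estimate_mw(calib: SecCalibration, Ve: float,
                geom: ColumnGeometry) -> float:
    """Invert the calibration line: mw = 10**((Kav - intercept)/slope)."""
    if calib.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    k = kav(Ve, geom)
    return float(10.0 ** ((k - calib.intercept) / calib.slope))


def sequence_mass(seq: ProteinRecord | str) -> float:
    """Average molecular mass (Da) of a protein sequence: sum of residue
    masses plus one water. Ambiguous residues (X) are an error."""
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    total = WATER_MASS
    for pos, res in enumerate(residues, start=1):
        try:
            total += RESIDUE_MASS[res]
        except KeyError:
            raise ValueError(
                f"cannot compute mass: unknown/ambiguous residue {res!r} "
                f"at position {pos}"
            ) from None
    return total


def infer_stoichiometry(
    mw_est: float,
    subunit_mw: float,
    candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
    tol: float = 0.10,
    Kav: float | None = None,
) -> SecEstimate:
    """Snap an SEC mass estimate to a candidate subunit count.

    The inferred count minimises \\|n * subunit_mw - mw_est\\|. The call is
    flagged ambiguous when two or more candidates land within ``tol``
    (relative to the estimate; default the ~10% SEC error) or when the best
    two candidates tie exactly.
    """
    if subunit_mw <= 0:
        raise ValueError("subunit mass must be positive")
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    diffs = {n: abs(n * subunit_mw - mw_est) for n in candidates}
    n_best = min(sorted(candidates), key=lambda n: diffs[n])
    within = [n for n in candidates if diffs[n] / mw_est <= tol]
    tied = [n for n in candidates
            if abs(diffs[n] - diffs[n_best]) <= 1e-9 * max(mw_est, 1.0)]
    return SecEstimate(
        Kav=Kav,
        mw_est=mw_est,
        subunit_mw=subunit_mw,
        n_inferred=n_best,
        rel_error=diffs[n_best] / mw_est,
        ambiguous=len(within) >= 2 or len(tied) >= 2,
    )


def estimate_stoichiometry_from_ve(
    calib: SecCalibration,
    Ve: float,
    geom: ColumnGeometry,
    subunit_mw: float,
    candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
    tol: float = 0.10,
) -> SecEstimate:
    """Full chain: elution volume -> Kav -> mass estimate -> stoichiometry."""
    mw = estimate_mw(calib, Ve, geom)
    return infer_stoichiometry(mw, subunit_mw, candidates, tol,
                               Kav=kav(Ve, geom))
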