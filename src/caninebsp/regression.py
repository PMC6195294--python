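"""Geometric regression of body segment parameters on morphometrics.

Two directions are covered:

* **Prediction** -- evaluate the 44 published equations (11 segment
  masses, 33 moments of inertia) on a morphometric record of a new dog.
  Each equation has the form ``value = β₀·a + β₁·G + β₂`` where ``a`` is
  whole-body mass (kg) and ``G`` a geometry regressor built from linear
  dimensions: a volume-like term for masses, a mass-weighted second-moment
  term (cylinder, frustum, ellipsoid, ...) for MoIs.

* **Refit** -- ordinary least squares of an observed quantity on
  ``[a, G, 1]`` for a cohort of dogs, with shape selection by R² among
  candidate geometry terms and a paired-t repeatability filter for the
  morphometric dimensions themselves.

The equation transcription ships as ``data/regression_equations.yaml``
(one entry per published row, including per-row provenance notes) and is
loaded, never hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
import yaml
from scipy import stats

from .bsp_reference import SEGMENT_NAMES

__all__ = [
    "MorphometricRecord",
    "RegressionEquation",
    "FitResult",
    "PredictedValue",
    "MissingDimensionError",
    "CollinearityError",
    "NonPhysicalWarning",
    "TERM_KINDS",
    "load_equations",
    "equations_for",
    "evaluate",
    "predict_all",
    "build_term",
    "fit",
    "select_shape",
    "repeatability_filter",
    "load_dimension_dictionary",
    "records_from_frame",
    "BODY_MASS_RANGE",
]

#: calibration range of the reference cohort (kg); outside it predictions
#: carry an extrapolation flag
BODY_MASS_RANGE = (34.29, 39.41)

#: geometry-term kinds and the number of dimension keys each consumes
TERM_KINDS: Mapping[str, int] = {
    "mass_only": 0,
    "cylinder_volume": 2,
    "frustum_volume": 3,
    "box_volume": 3,
    "transverse_cylinder": 2,
    "transverse_cylinder_circ": 2,
    "axial_frustum": 2,
    "axial_circ": 1,
    "ellipsoid_sum": 2,
}


class MissingDimensionError(KeyError):
    """A record lacks a dimension an equation needs; names the key."""


class CollinearityError(ValueError):
    """The regression design matrix is rank-deficient."""


class NonPhysicalWarning(UserWarning):
    """Prediction is non-positive or the dog is outside calibration."""


@dataclass(frozen=True)
class MorphometricRecord:
    """Whole-body mass plus named linear dimensions of one dog.

    ``dimensions`` maps ``"<segment>.<letter>"`` (e.g. ``"manus.c"``) to
    metres; letters follow the published data dictionary
    (``data/dimension_dictionary.yaml``).
    """

    body_mass: float
    dimensions: Mapping[str, float] = field(default_factory=dict)
    dog_id: str = ""

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        for k, v in self.dimensions.items():
            if v <= 0:
                raise ValueError(f"dimension {k} = {v} must be > 0")

    def get(self, key: str) -> float:
        try:
            return self.dimensions[key]
        except KeyError:
            raise MissingDimensionError(
                f"record lacks dimension {key!r}: {_dimension_definition(key)}"
            ) from None


@dataclass(frozen=True)
class RegressionEquation:
    """One published predictive equation: segment × quantity.

    ``value = a_coef·a + term_coef·G + intercept`` with ``G`` the
    ``term_kind`` regressor on ``dimension_keys`` (times body mass when
    ``geometry_times_mass``).  ``quantity`` is mass (kg) or I_xx/I_yy/I_zz
    (kg·m²); ``anatomical_axis`` names the rotation axis a MoI refers to.
    """

    segment: str
    quantity: str
    term_kind: str
    dimension_keys: tuple[str, ...]
    a_coef: float
    term_coef: float | None
    intercept: float
    r_squared: float
    geometry_times_mass: bool = False
    anatomical_axis: str | None = None
    note: str | None = None

    def __post_init__(self):
        if self.term_kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.term_kind!r}")
        if len(self.dimension_keys) != TERM_KINDS[self.term_kind]:
            raise ValueError(
                f"{self.segment} {self.quantity}: {self.term_kind} takes "
                f"{TERM_KINDS[self.term_kind]} keys, got {len(self.dimension_keys)}"
            )
        if (self.term_coef is None) != (self.term_kind == "mass_only"):
            raise ValueError("term_coef must be present iff there is a geometry term")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def n_coefficients(self) -> int:
        return 2 if self.term_kind == "mass_only" else 3


@dataclass(frozen=True)
class PredictedValue:
    """An evaluated equation with validity flags, value in SI units."""

    value: float
    physical: bool              # value > 0
    within_calibration: bool    # body mass inside the cohort range


@dataclass
class FitResult:
    """OLS refit of one quantity on [body mass, geometry term, intercept]."""

    term_kind: str
    dimension_keys: tuple[str, ...]
    coefficients: np.ndarray    # ordered (a_coef, [term_coef], intercept)
    std_errors: np.ndarray
    r_squared: float
    residuals: np.ndarray
    n: int


def _dimension_definition(key: str) -> str:
    dd = load_dimension_dictionary()
    seg, _, letter = key.partition(".")
    try:
        return dd[seg][letter]
    except KeyError:
        return "no published definition"


@lru_cache(maxsize=1)
def load_dimension_dictionary() -> dict:
    with resources.files("caninebsp.data").joinpath("dimension_dictionary.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=1)
def load_equations() -> tuple[RegressionEquation, ...]:
    """All 44 published equations, transcription checked on load."""
    with resources.files("caninebsp.data").joinpath("regression_equations.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    eqs = []
    for row in raw["equations"]:
        if row["segment"] not in SEGMENT_NAMES:
            raise ValueError(f"equation for unknown segment {row['segment']!r}")
        eqs.append(
            RegressionEquation(
                segment=row["segment"],
                quantity=row["quantity"],
                term_kind=row["term_kind"],
                dimension_keys=tuple(row["dimension_keys"]),
                a_coef=row["a_coef"],
                term_coef=row["term_coef"],
                intercept=row["intercept"],
                r_squared=row["r_squared"],
                geometry_times_mass=row["geometry_times_mass"],
                anatomical_axis=row.get("anatomical_axis"),
                note=row.get("note"),
            )
        )
    return tuple(eqs)


def equations_for(segment: str, quantity: str | None = None):
    out = [e for e in load_equations() if e.segment == segment]
    if quantity is not None:
        out = [e for e in out if e.quantity == quantity]
    return out


def build_term(term_kind: str, values: Sequence[float]) -> float:
    """Evaluate a geometry regressor on raw dimension values (metres).

    The transverse forms encode a cylinder's through-CoM second moment:
    ``0.076 ≈ 3/(4π²)`` turns a circumference ``c`` into ``3r²`` with
    ``r = c/(2π)``, paired with the squared length; ``(c/π)²`` is the
    diameter-squared variant.  The axial frustum term
    ``(c⁵−d⁵)/(c³−d³)`` is continuous at c = d with limit (5/3)c².
    """
    k = TERM_KINDS[term_kind]
    if len(values) != k:
        raise ValueError(f"{term_kind} takes {k} values, got {len(values)}")
    v = [float(x) for x in values]
    if term_kind == "mass_only":
        return 0.0
    if term_kind == "cylinder_volume":
        return v[0] * v[1] ** 2
    if term_kind == "frustum_volume":
        return v[0] * (v[1] ** 2 + v[1] * v[2] + v[2] ** 2)
    if term_kind == "box_volume":
        return v[0] * v[1] * v[2]
    if term_kind == "transverse_cylinder":
        return 0.076 * v[0] ** 2 + v[1] ** 2
    if term_kind == "transverse_cylinder_circ":
        return (v[0] / np.pi) ** 2 + v[1] ** 2
    if term_kind == "axial_frustum":
        c, d = v
        if np.isclose(c, d, rtol=1e-9, atol=1e-12):
            return 5.0 / 3.0 * c * c
        return (c**5 - d**5) / (c**3 - d**3)
    if term_kind == "axial_circ":
        return v[0] ** 2
    return v[0] ** 2 + v[1] ** 2  # ellipsoid_sum


def _regressor(eq_or_kind, rec: MorphometricRecord, keys, segment, times_mass) -> float:
    vals = [rec.get(f"{segment}.{k}") for k in keys]
    g = build_term(eq_or_kind, vals)
    return g * rec.body_mass if times_mass else g


def evaluate(eq: RegressionEquation, rec: MorphometricRecord) -> PredictedValue:
    """Literal evaluation of one published equation on a record."""
    value = eq.a_coef * rec.body_mass + eq.intercept
    if eq.term_kind != "mass_only":
        value += eq.term_coef * _regressor(
            eq.term_kind, rec, eq.dimension_keys, eq.segment, eq.geometry_times_mass
        )
    lo, hi = BODY_MASS_RANGE
    within = lo <= rec.body_mass <= hi
    physical = value > 0.0
    if not physical:
        warnings.warn(
            f"{eq.segment} {eq.quantity}: predicted {value:.4g} is non-physical",
            NonPhysicalWarning, stacklevel=2,
        )
    if not within:
        warnings.warn(
            f"body mass {rec.body_mass} kg outside calibration range {BODY_MASS_RANGE}",
            NonPhysicalWarning, stacklevel=2,
        )
    return PredictedValue(value=float(value), physical=physical, within_calibration=within)


def predict_all(
    rec: MorphometricRecord, segments: Iterable[str] = SEGMENT_NAMES
) -> tuple[dict[str, dict[str, PredictedValue]], list[str]]:
    """Apply every applicable equation to a record.

    Returns ``(predictions, missing)`` where ``predictions`` maps segment
    -> quantity -> :class:`PredictedValue` (MoIs keyed by anatomical axis
    as well as box axis) and ``missing`` lists the equations skipped for
    lack of a dimension, as ``"segment.quantity (needs segment.letter)"``.
    """
    predictions: dict[str, dict[str, PredictedValue]] = {}
    missing: list[str] = []
    for seg in segments:
        for eq in equations_for(seg):
            try:
                pv = evaluate(eq, rec)
            except MissingDimensionError as err:
                missing.append(f"{seg}.{eq.quantity} ({err.args[0]})")
                continue
            bucket = predictions.setdefault(seg, {})
            bucket[eq.quantity] = pv
            if eq.anatomical_axis:
                bucket[eq.anatomical_axis] = pv
    return predictions, missing


def _design(
    records: Sequence[MorphometricRecord],
    term_kind: str,
    dimension_keys: Sequence[str],
    segment: str,
    times_mass: bool,
) -> np.ndarray:
    a = np.array([r.body_mass for r in records])
    cols = [a]
    if term_kind != "mass_only":
        cols.append(
            np.array(
                [_regressor(term_kind, r, dimension_keys, segment, times_mass)
                 for r in records]
            )
        )
    cols.append(np.ones_like(a))
    return np.column_stack(cols)


def fit(
    cohort: Sequence[tuple[MorphometricRecord, float]],
    term_kind: str,
    dimension_keys: Sequence[str],
    segment: str,
    geometry_times_mass: bool = True,
) -> FitResult:
    """OLS of an observed quantity on [body mass, geometry term, intercept].

    Mirrors the published model family exactly; requires n ≥ 4 dogs
    (sides counted separately) and a full-rank design.
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 observations")
    records = [rc for rc, _ in cohort]
    y = np.array([v for _, v in cohort], dtype=float)
    X = _design(records, term_kind, dimension_keys, segment, geometry_times_mass)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"design for {term_kind} on {dimension_keys} is rank-deficient"
        )
    res = sm.OLS(y, X).fit()
    return FitResult(
        term_kind=term_kind,
        dimension_keys=tuple(dimension_keys),
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        n=len(cohort),
    )


def select_shape(
    cohort: Sequence[tuple[MorphometricRecord, float]],
    candidates: Sequence[tuple[str, Sequence[str]]],
    segment: str,
    geometry_times_mass: bool = True,
) -> tuple[FitResult, list[FitResult]]:
    """Fit every candidate geometry term and pick the best by R².

    ``candidates`` is a sequence of ``(term_kind, dimension_keys)``.
    Ties break toward fewer coefficients, then lexically by term kind.
    Returns ``(best, full_ranking)``; candidates whose design is
    collinear are dropped from the ranking.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    results = []
    for kind, keys in candidates:
        try:
            results.append(fit(cohort, kind, keys, segment, geometry_times_mass))
        except CollinearityError:
            continue
    if not results:
        raise CollinearityError("every candidate design was rank-deficient")
    ranking = sorted(
        results, key=lambda r: (-r.r_squared, len(r.coefficients), r.term_kind)
    )
    return ranking[0], ranking


def repeatability_filter(
    set1: Sequence[float], set2: Sequence[float], alpha: float = 0.05
) -> tuple[bool, float]:
    """Paired two-sided t-test deciding whether a measure is repeatable.

    Dimensions re-measured a week apart are kept only when the paired
    test finds no significant shift.  Computed from first principles:
    ``t = mean(d) / (sd(d)/√n)`` with ``d = set1 − set2`` and p from the
    t(n−1) distribution.  Returns ``(include, p_value)``; include is
    False iff p < alpha.  Zero-variance differences give p = 1 when the
    mean difference is also zero (identical sets) and p = 0 otherwise.
    """
    x1 = np.asarray(set1, dtype=float)
    x2 = np.asarray(set2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size < 3:
        raise ValueError("need two equal-length 1-D sets with n >= 3")
    d = x1 - x2
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        p = 1.0 if d.mean() == 0.0 else 0.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return p >= alpha, float(p)


def records_from_frame(frame) -> list[MorphometricRecord]:
    """Build records from a DataFrame with ``body_mass_kg`` plus
    ``<segment>.<letter>`` columns (the CSV dialect of the CLI)."""
    records = []
    for idx, row in frame.iterrows():
        dims = {
            c: float(row[c])
            for c in frame.columns
            if c != "body_mass_kg" and c != "dog_id" and not np.isnan(row[c])
        }
        records.append(
            MorphometricRecord(
                body_mass=float(row["body_mass_kg"]),
                dimensions=dims,
                dog_id=str(row.get("dog_id", idx)),
            )
        )
    return records
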