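"""The clinical worked example: transplant patients, blood-chemistry
time-courses, and the "Likely Rejecter" class cascade.

The domain models a renal-transplant cohort.  Each patient carries
time-courses of serum creatinine and blood urea nitrogen (BUN).  A *Likely
Rejecter* is defined — deliberately controversially, as one clinical
perspective among several — as a patient whose creatinine collection is
*elevated*, where elevated means the collection's fitted linear-regression
model is *increasing* (strictly positive slope):

    LikelyRejecter  ≡ Patient ⊓ ∃hasCreatinineCollection.ElevatedLevels
    ElevatedLevels  ≡ MeasurementCollection ⊓ ∃hasRegressionModel.IncreasingModel
    IncreasingModel ≡ LinearRegressionModel ⊓ ∃slope.(xsd:decimal > 0)

A blood-chemistry time-course is declared a subclass of generic X-Y
coordinate data, which is what lets a generic regression service apply to
it.  "Increasing" is read strictly (slope > 0, a minExclusive facet): a
flat series is not increasing, making the zero-slope boundary testable.

Three annotation services operate over this domain:

* a **linear-regression service** consuming X-Y coordinate data and
  attaching ``hasRegressionModel`` (an ordinary-least-squares fit);
* two **latest-value services** attaching ``latestCreatinine`` /
  ``latestBUN`` — "latest" is the value at the maximum time offset, ties
  broken by lexicographically greatest measurement IRI.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

from .rdf_core import (
    Graph,
    IRI,
    Literal,
    RDF_TYPE,
    Triple,
    XSD,
    decimal_literal,
    graph_of,
)
from .ontology_core import (
    IntersectionOf,
    NamedClass,
    NumericRange,
    Ontology,
    SomeValuesFrom,
    ontology_to_turtle,
)
from .service_model import ServiceDescription

__all__ = [
    "PAT",
    "PRED",
    "SVC_NS",
    "LinearRegressionModel",
    "NotFittable",
    "ols_fit",
    "demo_ontology",
    "demo_ontology_turtle",
    "regression_service",
    "latest_value_service",
    "demo_services",
]

PAT = "http://sadiframework.org/ontologies/patients.owl#"
PRED = "http://sadiframework.org/ontologies/predicates.owl#"
SVC_NS = "http://owlflow.example.org/services#"

XSD_DECIMAL = IRI(XSD + "decimal")


def _pat(local: str) -> IRI:
    return IRI(PAT + local)


def _pred(local: str) -> IRI:
    return IRI(PRED + local)


# classes
PATIENT = _pat("Patient")
MEASUREMENT = _pat("Measurement")
MEASUREMENT_COLLECTION = _pat("MeasurementCollection")
BLOOD_CHEMISTRY_TIME_COURSE = _pat("BloodChemistryTimeCourse")
XY_COORDINATE_DATA = _pat("XYCoordinateData")
LINEAR_REGRESSION_MODEL = _pat("LinearRegressionModel")
LIKELY_REJECTER = _pat("LikelyRejecter")
ELEVATED_LEVELS = _pat("ElevatedLevels")
INCREASING_MODEL = _pat("IncreasingModel")
REGRESSION_ANNOTATED_DATA = _pat("RegressionAnnotatedData")
PATIENT_WITH_CREATININE_SERIES = _pat("PatientWithCreatinineSeries")
PATIENT_WITH_BUN_SERIES = _pat("PatientWithBUNSeries")
PATIENT_WITH_LATEST_CREATININE = _pat("PatientWithLatestCreatinine")
PATIENT_WITH_LATEST_BUN = _pat("PatientWithLatestBUN")

# properties
HAS_CREATININE_COLLECTION = _pred("hasCreatinineCollection")
HAS_BUN_COLLECTION = _pred("hasBUNCollection")
HAS_MEASUREMENT = _pred("hasMeasurement")
HAS_REGRESSION_MODEL = _pred("hasRegressionModel")
SLOPE = _pred("slope")
INTERCEPT = _pred("intercept")
X_OFFSET = _pred("x")
Y_VALUE = _pred("y")
LATEST_BUN = _pred("latestBUN")
LATEST_CREATININE = _pred("latestCreatinine")
LATEST_MEASUREMENT = _pred("latestMeasurement")

_ANALYTE_COLLECTION = {
    "creatinine": HAS_CREATININE_COLLECTION,
    "BUN": HAS_BUN_COLLECTION,
}
_ANALYTE_LATEST = {"creatinine": LATEST_CREATININE, "BUN": LATEST_BUN}


def demo_ontology() -> Ontology:
    """The demo ontology: the Likely Rejecter cascade plus service I/O classes."""
    any_decimal = NumericRange(XSD_DECIMAL)
    positive = NumericRange.of(XSD_DECIMAL, minExclusive=0)
    has_series = lambda link: IntersectionOf(
        (
            NamedClass(PATIENT),
            SomeValuesFrom(
                link,
                IntersectionOf(
                    (
                        NamedClass(MEASUREMENT_COLLECTION),
                        SomeValuesFrom(HAS_MEASUREMENT, NamedClass(MEASUREMENT)),
                    )
                ),
            ),
        )
    )
    definitions = {
        LIKELY_REJECTER: IntersectionOf(
            (
                NamedClass(PATIENT),
                SomeValuesFrom(HAS_CREATININE_COLLECTION, NamedClass(ELEVATED_LEVELS)),
            )
        ),
        ELEVATED_LEVELS: IntersectionOf(
            (
                NamedClass(MEASUREMENT_COLLECTION),
                SomeValuesFrom(HAS_REGRESSION_MODEL, NamedClass(INCREASING_MODEL)),
            )
        ),
        INCREASING_MODEL: IntersectionOf(
            (NamedClass(LINEAR_REGRESSION_MODEL), SomeValuesFrom(SLOPE, positive))
        ),
        REGRESSION_ANNOTATED_DATA: IntersectionOf(
            (
                NamedClass(XY_COORDINATE_DATA),
                SomeValuesFrom(HAS_REGRESSION_MODEL, NamedClass(LINEAR_REGRESSION_MODEL)),
            )
        ),
        PATIENT_WITH_CREATININE_SERIES: has_series(HAS_CREATININE_COLLECTION),
        PATIENT_WITH_BUN_SERIES: has_series(HAS_BUN_COLLECTION),
        PATIENT_WITH_LATEST_CREATININE: IntersectionOf(
            (NamedClass(PATIENT), SomeValuesFrom(LATEST_CREATININE, any_decimal))
        ),
        PATIENT_WITH_LATEST_BUN: IntersectionOf(
            (NamedClass(PATIENT), SomeValuesFrom(LATEST_BUN, any_decimal))
        ),
    }
    subclass = {(BLOOD_CHEMISTRY_TIME_COURSE, XY_COORDINATE_DATA)}
    subproperty = {
        (LATEST_CREATININE, LATEST_MEASUREMENT),
        (LATEST_BUN, LATEST_MEASUREMENT),
    }
    return Ontology(definitions, subclass, subproperty)


def demo_ontology_turtle() -> str:
    """The demo ontology rendered in standard OWL Turtle (shippable file)."""
    return ontology_to_turtle(demo_ontology())


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------


class NotFittable(ValueError):
    """Raised when a series has fewer than 2 distinct x values."""


@dataclass(frozen=True)
class LinearRegressionModel:
    """Slope and intercept of an OLS line fit to X-Y coordinate data.

    slope is in analyte units per day, intercept in analyte units at x=0.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("regression coefficients must be finite")


def ols_fit(points: Sequence[Tuple[float, float]]) -> LinearRegressionModel:
    """Ordinary least squares: slope = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)²,
    intercept = ȳ − slope·x̄.  Exact for collinear input.

    Requires at least two distinct x values; otherwise the normal equations
    are singular and :class:`NotFittable` is raised.
    """
    xs = [float(x) for x, _ in points]
    ys = [float(y) for _, y in points]
    if len(set(xs)) < 2:
        raise NotFittable(
            f"need >= 2 distinct x values to fit a line, got {len(set(xs))}"
        )
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return LinearRegressionModel(slope=slope, intercept=ybar - slope * xbar)


# ---------------------------------------------------------------------------
# Demo services
# ---------------------------------------------------------------------------


def _series_points(g: Graph, collection: IRI) -> List[Tuple[IRI, float, float]]:
    """(measurement IRI, x, y) for every complete measurement of a collection."""
    out = []
    for m in g.objects(collection, HAS_MEASUREMENT):
        if not isinstance(m, IRI):
            continue
        x = g.value(m, X_OFFSET)
        y = g.value(m, Y_VALUE)
        if isinstance(x, Literal) and isinstance(y, Literal):
            xd, yd = x.as_decimal(), y.as_decimal()
            if xd is not None and yd is not None:
                out.append((m, float(xd), float(yd)))
    return out


def model_iri_for(collection: IRI) -> IRI:
    """Deterministic IRI for the regression-model node of a collection
    (hash suffix of the collection IRI, so re-runs mint the same node)."""
    digest = hashlib.sha1(collection.value.encode()).hexdigest()[:10]
    return IRI(f"{collection.value}-model-{digest}")


def _regression_impl(g: Graph, subjects: Set[IRI]) -> Graph:
    added = set()
    for coll in sorted(subjects):
        points = _series_points(g, coll)
        model = ols_fit([(x, y) for _, x, y in points])  # NotFittable propagates
        node = model_iri_for(coll)
        added.update(
            [
                Triple(coll, HAS_REGRESSION_MODEL, node),
                Triple(node, RDF_TYPE, LINEAR_REGRESSION_MODEL),
                Triple(node, SLOPE, decimal_literal(model.slope)),
                Triple(node, INTERCEPT, decimal_literal(model.intercept)),
            ]
        )
    return graph_of(added)


def regression_service() -> ServiceDescription:
    """The linear-regression annotation service.

    Consumes any X-Y coordinate data collection; attaches one regression
    model node (slope + intercept literals) per collection via
    ``hasRegressionModel``.
    """
    return ServiceDescription(
        iri=IRI(SVC_NS + "linear-regression"),
        name="linear regression over X-Y coordinate data",
        input_class=XY_COORDINATE_DATA,
        output_class=REGRESSION_ANNOTATED_DATA,
        implementation=_regression_impl,
    )


def latest_value(g: Graph, patient: IRI, analyte: str) -> Literal:
    """The y value of the maximum-x measurement of the patient's series for
    ``analyte``; ties on x broken by lexicographically greatest measurement
    IRI.  Raises ValueError when the patient has no usable measurement."""
    link = _ANALYTE_COLLECTION[analyte]
    best = None
    for coll in g.objects(patient, link):
        if not isinstance(coll, IRI):
            continue
        for m, x, y in _series_points(g, coll):
            key = (x, m.value)
            if best is None or key > best[0]:
                best = (key, y)
    if best is None:
        raise ValueError(f"patient {patient.value} has no {analyte} measurements")
    return decimal_literal(best[1])


def latest_value_service(analyte: str) -> ServiceDescription:
    """Latest-measurement lookup service for one analyte ('creatinine' or 'BUN')."""
    if analyte not in _ANALYTE_LATEST:
        raise ValueError(f"unknown analyte {analyte!r}")
    predicate = _ANALYTE_LATEST[analyte]
    input_cls = (
        PATIENT_WITH_CREATININE_SERIES
        if analyte == "creatinine"
        else PATIENT_WITH_BUN_SERIES
    )
    output_cls = (
        PATIENT_WITH_LATEST_CREATININE
        if analyte == "creatinine"
        else PATIENT_WITH_LATEST_BUN
    )

    def impl(g: Graph, subjects: Set[IRI]) -> Graph:
        added = set()
        for patient in sorted(subjects):
            added.add(Triple(patient, predicate, latest_value(g, patient, analyte)))
        return graph_of(added)

    return ServiceDescription(
        iri=IRI(SVC_NS + f"latest-{analyte.lower()}"),
        name=f"latest {analyte} level",
        input_class=input_cls,
        output_class=output_cls,
        implementation=impl,
    )


def demo_services() -> List[ServiceDescription]:
    """The three demo services: regression, latest creatinine, latest BUN."""
    return [
        regression_service(),
        latest_value_service("creatinine"),
        latest_value_service("BUN"),
    ]
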