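"""Synthetic patient cohorts with controllable trend structure and noise.

Emulates a clinical instance-data file: a cohort of renal-transplant
patients, each with creatinine and BUN measurement time-courses, typed per
the demo ontology.  A controllable fraction of patients is generated with
an increasing creatinine trend (the intended "rejecters"); the rest get a
non-positive trend.  Values are base + slope·days + Gaussian noise.

Two labels are emitted per patient:

* ``intended`` — the generating condition (which slope regime the patient
  was drawn from);
* ``oracle`` — the sign of an *independently computed* OLS slope over the
  realized (noisy) series, via numpy's least-squares fit.

Ground truth for the query engine is the **oracle** label: it is defined
by the data that actually exists, so noisy borderline patients remain
exactly checkable rather than flaky.  The two labels coincide whenever the
generating slope dominates the noise-induced slope error (with the default
margins they always do in the noiseless case, by construction).

Each patient draws from a dedicated pseudo-random stream (seed, index), so
enlarging a cohort never shifts the earlier patients' data.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import yaml

from .rdf_core import Graph, IRI, RDF_TYPE, Triple, decimal_literal, graph_of, load_graph, save_graph
from . import demo_domain as dd

__all__ = ["CohortSpec", "PatientTruth", "GroundTruth", "generate_cohort", "write_fixture", "read_fixture"]

COHORT_NS = "http://owlflow.example.org/cohort/"

#: analyte → (collection-link predicate, base level used for the second analyte)
_BASE_BUN = 15.0
_BUN_SLOPE_RANGE = (-0.1, 0.1)


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Defaults describe a small, clinically plausible cohort: creatinine
    around 1.0 mg/dL sampled weekly over five visits; rejecters trend up at
    0.05 mg/dL/day, non-rejecters drift down slightly; measurement noise of
    0.05 mg/dL.
    """

    n_patients: int = 10
    fraction_rejecter: float = 0.4
    n_timepoints: int = 5
    interval_days: float = 7.0
    base_creatinine: float = 1.0
    slope_rejecter: float = 0.05
    slope_non: float = -0.02
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_patients < 0:
            problems.append("n_patients must be >= 0")
        if not 0.0 <= self.fraction_rejecter <= 1.0:
            problems.append("fraction_rejecter must be in [0, 1]")
        if self.n_timepoints < 2:
            problems.append("n_timepoints must be >= 2")
        if self.interval_days <= 0:
            problems.append("interval_days must be > 0")
        if self.slope_rejecter <= 0:
            problems.append("slope_rejecter must be > 0")
        if self.slope_non > 0:
            problems.append("slope_non must be <= 0")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))

    @property
    def n_rejecters(self) -> int:
        return round(self.n_patients * self.fraction_rejecter)

    @property
    def expected_triple_count(self) -> int:
        """Closed-form accounting of the generated graph size.

        Per patient: 1 type triple, plus per analyte collection 3 triples
        (link + two types) and 4 per measurement (link, type, x, y)."""
        per_collection = 3 + 4 * self.n_timepoints
        return self.n_patients * (1 + 2 * per_collection)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PatientTruth:
    patient: IRI
    intended: str  # "rejecter" | "non"
    oracle: str  # sign of the oracle OLS slope on the realized series

    @property
    def is_oracle_rejecter(self) -> bool:
        return self.oracle == "rejecter"


@dataclass
class GroundTruth:
    patients: List[PatientTruth] = field(default_factory=list)

    def oracle_rejecters(self) -> Set[IRI]:
        return {p.patient for p in self.patients if p.oracle == "rejecter"}

    def intended_rejecters(self) -> Set[IRI]:
        return {p.patient for p in self.patients if p.intended == "rejecter"}

    def __len__(self) -> int:
        return len(self.patients)


def oracle_slope(xs, ys) -> float:
    """Independent OLS slope via numpy least squares (the ground-truth
    oracle — deliberately not the package's own fitting routine)."""
    A = np.vstack([np.asarray(xs, dtype=float), np.ones(len(xs))]).T
    coef, *_ = np.linalg.lstsq(A, np.asarray(ys, dtype=float), rcond=None)
    return float(coef[0])


def _series(
    rng: np.random.Generator, base: float, slope: float, xs: np.ndarray, noise_sd: float
) -> np.ndarray:
    ys = base + slope * xs + rng.normal(0.0, noise_sd, size=len(xs))
    # analyte concentrations are physically positive
    return np.maximum(ys, 0.01)


def _series_triples(
    patient: IRI, link: IRI, series_name: str, xs, ys
) -> List[Triple]:
    coll = IRI(f"{patient.value}/{series_name}")
    out = [
        Triple(patient, link, coll),
        Triple(coll, RDF_TYPE, dd.MEASUREMENT_COLLECTION),
        Triple(coll, RDF_TYPE, dd.BLOOD_CHEMISTRY_TIME_COURSE),
    ]
    for t, (x, y) in enumerate(zip(xs, ys)):
        m = IRI(f"{coll.value}/m{t}")
        out += [
            Triple(coll, dd.HAS_MEASUREMENT, m),
            Triple(m, RDF_TYPE, dd.MEASUREMENT),
            Triple(m, dd.X_OFFSET, decimal_literal(round(float(x), 6))),
            Triple(m, dd.Y_VALUE, decimal_literal(round(float(y), 6))),
        ]
    return out


def generate_cohort(spec: CohortSpec) -> Tuple[Graph, GroundTruth]:
    """Generate a cohort graph plus its ground truth.

    Deterministic under the spec's seed; the first
    ``round(n_patients * fraction_rejecter)`` patients are the intended
    rejecters.  The oracle label is recomputed from the realized series.
    """
    spec.validate()
    triples: List[Triple] = []
    truth = GroundTruth()
    xs = np.arange(spec.n_timepoints, dtype=float) * spec.interval_days
    for i in range(spec.n_patients):
        rng = np.random.default_rng([abs(spec.seed) % (2**31), i])
        patient = IRI(f"{COHORT_NS}patient{i:03d}")
        intended = "rejecter" if i < spec.n_rejecters else "non"
        creat_slope = spec.slope_rejecter if intended == "rejecter" else spec.slope_non
        creat = _series(rng, spec.base_creatinine, creat_slope, xs, spec.noise_sd)
        bun_slope = rng.uniform(*_BUN_SLOPE_RANGE)
        bun = _series(rng, _BASE_BUN, bun_slope, xs, spec.noise_sd)

        triples.append(Triple(patient, RDF_TYPE, dd.PATIENT))
        # ground truth from the values as serialized (rounded), so the graph
        # and the oracle see byte-identical data
        creat_r = [round(float(v), 6) for v in creat]
        bun_r = [round(float(v), 6) for v in bun]
        triples += _series_triples(
            patient, dd.HAS_CREATININE_COLLECTION, "creatinine-series", xs, creat_r
        )
        triples += _series_triples(patient, dd.HAS_BUN_COLLECTION, "bun-series", xs, bun_r)
        slope_hat = oracle_slope(xs, creat_r)
        truth.patients.append(
            PatientTruth(patient, intended, "rejecter" if slope_hat > 0 else "non")
        )
    return graph_of(triples), truth


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def _truth_csv(truth: GroundTruth) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["patient", "intended", "oracle"])
    for p in truth.patients:
        w.writerow([p.patient.value, p.intended, p.oracle])
    return buf.getvalue()


def _truth_from_csv(text: str) -> GroundTruth:
    rows = list(csv.reader(io.StringIO(text)))
    truth = GroundTruth()
    for patient, intended, oracle in rows[1:]:
        truth.patients.append(PatientTruth(IRI(patient), intended, oracle))
    return truth


def write_fixture(
    g: Graph, truth: GroundTruth, path, spec: Optional[CohortSpec] = None
) -> Dict[str, Path]:
    """Write ``cohort.ttl`` (deterministic Turtle), ``truth.csv`` and, when
    the spec is given, a ``spec.yaml`` echo.  Same seed ⇒ identical bytes."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    files = {"cohort": root / "cohort.ttl", "truth": root / "truth.csv"}
    files["cohort"].write_text(save_graph(g, "turtle"))
    files["truth"].write_text(_truth_csv(truth))
    if spec is not None:
        files["spec"] = root / "spec.yaml"
        files["spec"].write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))
    return files


def read_fixture(path) -> Tuple[Graph, GroundTruth]:
    """Reload a written fixture; round-trips exactly."""
    root = Path(path)
    g = load_graph(root / "cohort.ttl", "turtle")
    truth = _truth_from_csv((root / "truth.csv").read_text())
    return g, truth
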