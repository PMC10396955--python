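"""Scaffold comparison tables and physicochemical deltas.

The geometric side compares exit-vector parameter sets across scaffolds
with a weighted, scaled Euclidean score; the scale constants map one
"unit" of difference to roughly the spread that is chemically
meaningful for each parameter (0.1 Å in r, 0.5 Å in d, 10° in the plane
angles, 30° in |theta| — on the |theta| axis about 70° separates a flat
aromatic ring from a three-dimensional cage).

The physicochemical side consumes a packaged table of
literature-reported measurements (kinetic solubility, clogP, logD,
microsomal intrinsic clearance) for fluxapyroxad, boscalid,
phthalylsulfathiazole, lomitapide and their saturated analogues, and
recomputes the headline fold-changes and lipophilicity reductions from
it; nothing in the report layer is hard-coded.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .evp_core import EVPParameters
from .exceptions import PackagingError, ValidationError

#: per-parameter scale constants (denominators) for the distance score
SCALE_CONSTANTS: dict[str, float] = {
    "r": 0.1,       # Å; ~0.2 Å in r is a "longer" scaffold edge
    "d": 0.5,       # Å; ~0.5 Å in d is a "longer" substituent gap
    "phi1": 10.0,   # degrees
    "phi2": 10.0,   # degrees
    "abs_theta": 30.0,  # degrees; ~70° separates flat from 3D
}

_PARAM_KEYS = tuple(SCALE_CONSTANTS)


@dataclass(frozen=True)
class PhysChemRecord:
    """Measured properties of one compound (missing logD stays None,
    never imputed)."""

    compound: str
    parent: str
    role: str  # parent | carbocycle | oxa
    solubility_um: float
    clogp: float
    logd: float | None
    clint: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.solubility_um < 0:
            raise ValidationError(f"{self.compound}: solubility must be >= 0")
        if self.clint < 0:
            raise ValidationError(f"{self.compound}: CLint must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-parameter differences (p minus q) and the weighted score for
    one pair of parameter sets."""

    pair: tuple[str, str]
    deltas: dict[str, float]
    score: float


def _param_vector(p: EVPParameters) -> np.ndarray:
    return np.array([p.r, p.d, p.phi1, p.phi2, p.abs_theta])


def evp_distance(
    p: EVPParameters,
    q: EVPParameters,
    weights: dict[str, float] | None = None,
    scales: dict[str, float] | None = None,
) -> float:
    """Weighted scaled Euclidean distance over (r, d, phi1, phi2, |theta|).

    score = sqrt( sum_k w_k ((p_k - q_k) / s_k)^2 ), default weights 1.
    """
    scales = {**SCALE_CONSTANTS, **(scales or {})}
    weights = {k: 1.0 for k in _PARAM_KEYS} | (weights or {})
    w = np.array([weights[k] for k in _PARAM_KEYS], dtype=float)
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValidationError("at least one weight must be positive")
    s = np.array([scales[k] for k in _PARAM_KEYS], dtype=float)
    diff = (_param_vector(p) - _param_vector(q)) / s
    return float(np.sqrt(np.sum(w * diff**2)))


def compare_pair(
    name_p: str,
    p: EVPParameters,
    name_q: str,
    q: EVPParameters,
    weights: dict[str, float] | None = None,
) -> ComparisonResult:
    """Differences and score for one named pair."""
    vp, vq = _param_vector(p), _param_vector(q)
    deltas = {k: float(vp[i] - vq[i]) for i, k in enumerate(_PARAM_KEYS)}
    return ComparisonResult(
        pair=(name_p, name_q), deltas=deltas, score=evp_distance(p, q, weights)
    )


def compare_table(
    parameter_sets: list[tuple[str, EVPParameters]],
    weights: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate named parameter sets plus their pairwise score matrix.

    Returns ``(params, scores)``: one row per structure (input order,
    presentation rounding — 0.01 Å, 1°) and the symmetric score matrix
    (full precision).
    """
    if len(parameter_sets) < 2:
        raise ValidationError("compare_table needs at least two parameter sets")
    names = [name for name, _ in parameter_sets]
    rows = []
    for name, p in parameter_sets:
        rounded = p.rounded()
        rows.append(
            {
                "name": name,
                "r": rounded["r"],
                "d": rounded["d"],
                "phi1": rounded["phi1"],
                "phi2": rounded["phi2"],
                "abs_theta": rounded["abs_theta"],
            }
        )
    params = pd.DataFrame(rows).set_index("name")
    n = len(parameter_sets)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = evp_distance(
                parameter_sets[i][1], parameter_sets[j][1], weights
            )
    scores = pd.DataFrame(matrix, index=names, columns=names)
    return params, scores


# ---------------------------------------------------------------------------
# packaged physicochemical reference data


def load_physchem_reference() -> list[PhysChemRecord]:
    """The packaged table of literature-reported measurements: 12
    compounds in 4 parent/carbocycle/oxa triples."""
    try:
        text = (
            resources.files("evpkit")
            .joinpath("data/physchem_reference.csv")
            .read_text()
        )
    except FileNotFoundError:
        raise PackagingError(
            "packaged data file physchem_reference.csv is missing"
        ) from None
    body = "\n".join(
        line for line in text.splitlines() if not line.startswith("#")
    )
    df = pd.read_csv(io.StringIO(body))
    expected = {
        "compound", "parent", "role", "solubility_um", "clogp", "logd",
        "clint", "provenance",
    }
    if set(df.columns) != expected:
        raise PackagingError(
            f"physchem_reference.csv has unexpected columns: {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        logd = None if (isinstance(row.logd, float) and math.isnan(row.logd)) else float(row.logd)
        records.append(
            PhysChemRecord(
                compound=str(row.compound),
                parent=str(row.parent),
                role=str(row.role),
                solubility_um=float(row.solubility_um),
                clogp=float(row.clogp),
                logd=logd,
                clint=float(row.clint),
                provenance=str(row.provenance),
            )
        )
    names = [r.compound for r in records]
    if len(set(names)) != len(names):
        raise PackagingError("physchem_reference.csv: duplicate compound names")
    if len(records) != 12:
        raise PackagingError(
            f"physchem_reference.csv: expected 12 records, found {len(records)}"
        )
    return records


_PROPERTIES = ("solubility_um", "clogp", "logd", "clint")


def fold_change(
    records: list[PhysChemRecord],
    property_name: str,
    numerator: str,
    denominator: str,
) -> float:
    """Exact ratio of one property between two compounds (no rounding)."""
    if property_name not in _PROPERTIES:
        raise ValidationError(
            f"unknown property {property_name!r}; expected one of {_PROPERTIES}"
        )
    by_name = {r.compound: r for r in records}
    try:
        num = getattr(by_name[numerator], property_name)
        den = getattr(by_name[denominator], property_name)
    except KeyError as exc:
        raise ValidationError(f"unknown compound {exc.args[0]!r}") from None
    if num is None or den is None:
        raise ValidationError(
            f"{property_name} is not defined for both compounds"
        )
    if den == 0:
        raise ValidationError(
            f"{property_name} of {denominator!r} is zero; fold change undefined"
        )
    return float(num) / float(den)


def lipophilicity_deltas(records: list[PhysChemRecord]) -> pd.DataFrame:
    """Lipophilicity reduction (parent minus oxa analogue) per triple.

    Computed separately for clogP and — where both values are inside
    the reliable assay window — logD; missing logD yields NaN, never an
    imputed number.
    """
    parents = {r.compound: r for r in records if r.role == "parent"}
    rows = []
    for r in records:
        if r.role != "oxa":
            continue
        parent = parents[r.parent]
        logd_drop = (
            parent.logd - r.logd
            if parent.logd is not None and r.logd is not None
            else float("nan")
        )
        rows.append(
            {
                "parent": parent.compound,
                "oxa_analogue": r.compound,
                "clogp_reduction": parent.clogp - r.clogp,
                "logd_reduction": logd_drop,
            }
        )
    return pd.DataFrame(rows)


def solubility_fold_changes(records: list[PhysChemRecord]) -> pd.DataFrame:
    """Solubility ratio oxa analogue / parent per triple (one decimal is
    applied only at presentation)."""
    rows = []
    for r in records:
        if r.role != "oxa":
            continue
        rows.append(
            {
                "parent": r.parent,
                "oxa_analogue": r.compound,
                "fold_change": fold_change(
                    records, "solubility_um", r.compound, r.parent
                ),
            }
        )
    return pd.DataFrame(rows)


def physchem_report(records: list[PhysChemRecord] | None = None) -> pd.DataFrame:
    """Joined per-triple report: solubility fold-change plus clogP/logD
    reductions, all recomputed from the packaged table."""
    records = records if records is not None else load_physchem_reference()
    folds = solubility_fold_changes(records)
    drops = lipophilicity_deltas(records)
    return folds.merge(drops, on=["parent", "oxa_analogue"])
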