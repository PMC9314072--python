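"""Matrix population models: data model, I/O, admissibility checks and eigen-analysis.

A matrix population model (MPM) is a square nonnegative matrix ``A`` projecting
a stage- (or age-, or size-) structured abundance vector one time step forward,
``n_{t+1} = A n_t``.  ``A`` decomposes into a survival-and-development part ``U``,
a sexual-reproduction part ``F`` and, for clonal organisms, a clonality part
``C``, with ``A = U + F + C``.  Columns index the stage an average individual is
in at time ``t``; rows index the stage its contributions land in at ``t + 1``.

Downstream transient ("demographic resilience") analyses require each matrix to
describe a complete, well-behaved life cycle: *irreducible* (every stage can
reach every other through the life-cycle graph), *primitive* (irreducible and
aperiodic, so the population structure converges) and *ergodic* (the long-run
growth rate is reached from any nonnegative starting structure; operationally,
the left dominant eigenvector is strictly positive).  :func:`validate_mpm`
implements those screens and :func:`filter_collection` applies them together
with the study-design filters (wild, unmanipulated, annual-projection records).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MPMRecord",
    "MPMCollection",
    "ValidationReport",
    "EigenSystem",
    "NormalizedMPM",
    "FilterConfig",
    "read_collection",
    "write_collection",
    "mean_matrix",
    "validate_mpm",
    "filter_collection",
    "eigen_analysis",
    "normalize",
]

#: Consistency tolerance for A == U + F + C.
PART_TOL = 1e-8

#: Default positivity tolerance for graph edges and eigenvector positivity.
POSITIVITY_TOL = 1e-12

_KINGDOMS = {"animal", "plant"}
_STATE_VARIABLES = {"age", "stage", "size"}
_TREATMENTS = {"unmanipulated", "manipulated"}


class MPMError(ValueError):
    """Raised for malformed or inconsistent matrix population model inputs."""


def _as_matrix(x, name: str, population_id: str | None = None) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    who = f" (population {population_id!r})" if population_id else ""
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MPMError(f"{name} must be a square matrix{who}; got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise MPMError(f"{name} contains non-finite entries{who}")
    if np.any(m < 0):
        raise MPMError(f"{name} contains negative entries{who}")
    return m


@dataclass
class MPMRecord:
    """One population's projection matrix with its decomposition and metadata.

    ``mat_A`` is authoritative when given; if absent it is reconstructed as
    ``U + F + C`` (missing parts treated as zero only when at least U and F
    are present).  When both A and all parts are given, consistency is
    checked to :data:`PART_TOL` but A is not overwritten.
    """

    species_name: str
    population_id: str
    kingdom: str
    mat_A: np.ndarray | None = None
    mat_U: np.ndarray | None = None
    mat_F: np.ndarray | None = None
    mat_C: np.ndarray | None = None
    state_variable: str = "stage"
    periodicity_years: float = 1.0
    captive: bool = False
    treatment: str = "unmanipulated"
    is_mean_matrix: bool = False

    def __post_init__(self) -> None:
        if self.kingdom not in _KINGDOMS:
            raise MPMError(f"kingdom must be one of {_KINGDOMS}; got {self.kingdom!r}")
        if self.state_variable not in _STATE_VARIABLES:
            raise MPMError(
                f"state_variable must be one of {_STATE_VARIABLES}; got {self.state_variable!r}"
            )
        if self.treatment not in _TREATMENTS:
            raise MPMError(f"treatment must be one of {_TREATMENTS}; got {self.treatment!r}")
        if not self.periodicity_years > 0:
            raise MPMError("periodicity_years must be positive")

        parts = {}
        for name in ("mat_U", "mat_F", "mat_C"):
            m = getattr(self, name)
            if m is not None:
                parts[name] = _as_matrix(m, name, self.population_id)
                setattr(self, name, parts[name])

        if self.mat_A is None:
            if "mat_U" not in parts or "mat_F" not in parts:
                raise MPMError(
                    f"record {self.population_id!r}: mat_A absent and U/F parts "
                    "incomplete; cannot reconstruct A"
                )
            dims = {m.shape[0] for m in parts.values()}
            if len(dims) != 1:
                raise MPMError(f"record {self.population_id!r}: U/F/C dimensions differ")
            self.mat_A = sum(parts.values())
        else:
            self.mat_A = _as_matrix(self.mat_A, "mat_A", self.population_id)

        s = self.mat_A.shape[0]
        for name, m in parts.items():
            if m.shape[0] != s:
                raise MPMError(
                    f"record {self.population_id!r}: {name} dimension {m.shape[0]} "
                    f"!= A dimension {s}"
                )
        if all(k in parts for k in ("mat_U", "mat_F", "mat_C")):
            resid = np.abs(self.mat_A - (self.mat_U + self.mat_F + self.mat_C)).max()
            if resid > PART_TOL:
                raise MPMError(
                    f"record {self.population_id!r}: A != U + F + C "
                    f"(max abs deviation {resid:.3g})"
                )

    @property
    def dim(self) -> int:
        """Matrix dimension s (number of stages)."""
        return self.mat_A.shape[0]

    @property
    def pooled_state_variable(self) -> str:
        """State-variable category used as the models' random factor.

        Age- and stage-classified models are pooled as ``"stage"`` (size-and-
        stage combinations are recorded as ``"stage"`` upstream); size-based
        models remain ``"size"``.
        """
        return "stage" if self.state_variable in ("age", "stage") else "size"

    def to_dict(self) -> dict:
        d = {
            "species_name": self.species_name,
            "population_id": self.population_id,
            "kingdom": self.kingdom,
            "mat_A": self.mat_A.tolist(),
            "state_variable": self.state_variable,
            "periodicity_years": self.periodicity_years,
            "captive": self.captive,
            "treatment": self.treatment,
            "is_mean_matrix": self.is_mean_matrix,
        }
        for name in ("mat_U", "mat_F", "mat_C"):
            m = getattr(self, name)
            if m is not None:
                d[name] = m.tolist()
        return d


@dataclass
class MPMCollection:
    """An ordered set of :class:`MPMRecord` with unique population ids."""

    records: list[MPMRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.population_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise MPMError(f"duplicate population_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


@dataclass(frozen=True)
class ValidationReport:
    irreducible: bool
    primitive: bool
    ergodic: bool
    reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return self.irreducible and self.primitive and self.ergodic


@dataclass(frozen=True)
class EigenSystem:
    """Dominant eigenstructure of a projection matrix.

    ``lambda1`` is the spectral radius (asymptotic growth rate), ``w`` the
    stable structure (right eigenvector, summing to 1), ``v`` the reproductive
    values (left eigenvector, scaled so v.w = 1).  ``lambda2_mod`` is the
    modulus of the largest subdominant eigenvalue (None for 1x1 matrices) and
    ``damping_ratio`` is lambda1 / lambda2_mod, the geometric rate at which
    transient structure decays.
    """

    lambda1: float
    lambda2_mod: float | None
    damping_ratio: float | None
    w: np.ndarray
    v: np.ndarray


@dataclass(frozen=True)
class NormalizedMPM:
    """A projection matrix rescaled so its dominant eigenvalue is 1."""

    mat_A_hat: np.ndarray
    source: MPMRecord


@dataclass
class FilterConfig:
    """Retention criteria for :func:`filter_collection`."""

    require_wild: bool = True
    require_unmanipulated: bool = True
    require_annual: bool = True
    require_valid: bool = True
    tol: float = POSITIVITY_TOL


# ---------------------------------------------------------------------------
# I/O


def _record_from_dict(d: dict) -> MPMRecord:
    kwargs = dict(d)
    for name in ("mat_A", "mat_U", "mat_F", "mat_C"):
        if name in kwargs and kwargs[name] is not None:
            kwargs[name] = np.asarray(kwargs[name], dtype=float)
    return MPMRecord(**kwargs)


def read_collection(path: str | Path, format: str = "json") -> MPMCollection:
    """Read an MPM collection from the plain-text exchange format.

    ``json``: one document holding a top-level list of record objects, with
    matrices as row-major nested arrays.  ``csv-bundle``: a directory holding
    ``metadata.csv`` (one row per record) and ``matrices.csv`` in long format
    with columns ``population_id,part,row,col,value`` (0-based indices,
    ``part`` in {A,U,F,C}).
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise MPMError("exchange JSON must be a top-level list of records")
        records = [_record_from_dict(d) for d in raw]
        return MPMCollection(records=records, provenance=str(path))
    if format == "csv-bundle":
        meta = pd.read_csv(path / "metadata.csv")
        mats = pd.read_csv(path / "matrices.csv")
        records = []
        for _, row in meta.iterrows():
            d = row.to_dict()
            pid = d["population_id"]
            sub = mats[mats["population_id"] == pid]
            if sub.empty:
                raise MPMError(f"no matrix rows for population {pid!r}")
            s = int(max(sub["row"].max(), sub["col"].max())) + 1
            for part, key in (("A", "mat_A"), ("U", "mat_U"), ("F", "mat_F"), ("C", "mat_C")):
                p = sub[sub["part"] == part]
                if p.empty:
                    continue
                m = np.zeros((s, s))
                m[p["row"].to_numpy(int), p["col"].to_numpy(int)] = p["value"].to_numpy(float)
                d[key] = m
            records.append(_record_from_dict(d))
        return MPMCollection(records=records, provenance=str(path))
    raise MPMError(f"unknown format {format!r}")


def write_collection(collection: MPMCollection, path: str | Path) -> None:
    """Write a collection to the exchange JSON format."""
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in collection.records], fh, indent=1)


# ---------------------------------------------------------------------------
# Operations


def mean_matrix(records: Sequence[MPMRecord]) -> MPMRecord:
    """Elementwise arithmetic mean of a population's matrices.

    U, F and C are averaged only when every input supplies them; the result is
    flagged ``is_mean_matrix``.  Metadata is taken from the first record.
    """
    if len(records) == 0:
        raise MPMError("mean_matrix requires at least one record")
    dims = {r.dim for r in records}
    if len(dims) != 1:
        raise MPMError(f"mean_matrix: dimension mismatch {sorted(dims)}")
    first = records[0]
    out = {"mat_A": np.mean([r.mat_A for r in records], axis=0)}
    for name in ("mat_U", "mat_F", "mat_C"):
        parts = [getattr(r, name) for r in records]
        out[name] = np.mean(parts, axis=0) if all(p is not None for p in parts) else None
    return replace(first, is_mean_matrix=True, **out)


def life_cycle_graph(A: np.ndarray, tol: float = POSITIVITY_TOL) -> nx.DiGraph:
    """Directed life-cycle graph: edge j -> i whenever A[i, j] > tol."""
    g = nx.DiGraph()
    s = A.shape[0]
    g.add_nodes_from(range(s))
    rows, cols = np.nonzero(A > tol)
    g.add_edges_from(zip(cols.tolist(), rows.tolist()))
    return g


def validate_mpm(record: MPMRecord, tol: float = POSITIVITY_TOL) -> ValidationReport:
    """Screen a matrix for irreducibility, primitivity and ergodicity.

    Irreducibility is strong connectivity of the life-cycle graph; primitivity
    additionally requires the gcd of directed cycle lengths to be 1
    (aperiodicity); ergodicity requires a strictly positive left dominant
    eigenvector (every stage has nonzero reproductive value).
    """
    A = record.mat_A
    reasons: list[str] = []
    if not np.any(A > tol):
        return ValidationReport(False, False, False, ("zero matrix",))

    g = life_cycle_graph(A, tol)
    irreducible = nx.is_strongly_connected(g)
    if not irreducible:
        reasons.append("life-cycle graph is not strongly connected (reducible)")

    primitive = irreducible and nx.is_aperiodic(g)
    if irreducible and not primitive:
        reasons.append("cycle lengths share a common divisor > 1 (imprimitive)")

    eig = eigen_analysis(record)
    v = eig.v / eig.v.sum() if eig.v.sum() > 0 else eig.v
    ergodic = bool(np.all(v > tol))
    if not ergodic:
        reasons.append("left dominant eigenvector has non-positive entries (non-ergodic)")

    return ValidationReport(irreducible, primitive, ergodic, tuple(reasons))


def eigen_analysis(record: MPMRecord | np.ndarray) -> EigenSystem:
    """Dominant and subdominant eigenstructure of A.

    For a nonnegative matrix the spectral radius is itself an eigenvalue
    (Perron-Frobenius); ``w`` and ``v`` are the associated right/left
    eigenvectors made nonnegative and normalized (sum(w) = 1, v.w = 1).
    ``lambda2_mod`` is the largest modulus among the remaining eigenvalues —
    complex pairs and ties are handled by modulus alone.
    """
    A = record.mat_A if isinstance(record, MPMRecord) else np.asarray(record, float)
    if not np.any(A != 0):
        raise MPMError("eigen_analysis: zero matrix has no dominant eigenstructure")
    s = A.shape[0]
    eigvals, right = np.linalg.eig(A)
    moduli = np.abs(eigvals)
    k = int(np.argmax(moduli))
    lambda1 = float(moduli[k])

    w = np.real(right[:, k])
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    eigvalsT, left = np.linalg.eig(A.T)
    kT = int(np.argmax(np.abs(eigvalsT)))
    v = np.real(left[:, kT])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    vw = float(v @ w)
    if vw > 0:
        v = v / vw

    if s == 1:
        return EigenSystem(lambda1, None, None, w, v)

    rest = np.delete(moduli, k)
    lambda2_mod = float(rest.max())
    damping = lambda1 / lambda2_mod if lambda2_mod > 0 else None
    return EigenSystem(lambda1, lambda2_mod, damping, w, v)


def normalize(record: MPMRecord) -> NormalizedMPM:
    """Scale A by its dominant eigenvalue so the result has lambda1 = 1.

    Working on the normalized matrix isolates the component of short-term
    growth attributable to a disturbed structure from the stationary growth
    rate, making transient metrics comparable across populations with
    different asymptotic growth.
    """
    eig = eigen_analysis(record)
    if eig.lambda1 <= 0:
        raise MPMError("normalize: dominant eigenvalue is not positive")
    return NormalizedMPM(mat_A_hat=record.mat_A / eig.lambda1, source=record)


def filter_collection(
    collection: MPMCollection, criteria: FilterConfig | None = None
) -> tuple[MPMCollection, pd.DataFrame]:
    """Apply the study-design and admissibility screens.

    Retains records that are wild (non-captive), unmanipulated, describe
    annual dynamics (``periodicity_years == 1``) and pass
    :func:`validate_mpm`.  Population replicates may be encoded by a ``"|"``
    separator in ``population_id`` (e.g. ``"popA|1999"``, ``"popA|mean"``);
    within each ``(species, population)`` group, individual (non-mean)
    records are preferred — multiple individual records are collapsed to
    their arithmetic mean matrix — and stored mean matrices are used only
    when no individual record survives the screens.

    Returns the filtered collection and an exclusion log with one row per
    dropped record (columns ``population_id``, ``reason``).
    """
    criteria = criteria or FilterConfig()
    exclusions: list[dict] = []
    surviving: list[MPMRecord] = []
    for r in collection:
        reason = None
        if criteria.require_wild and r.captive:
            reason = "captive population"
        elif criteria.require_unmanipulated and r.treatment != "unmanipulated":
            reason = f"treatment is {r.treatment!r}"
        elif criteria.require_annual and abs(r.periodicity_years - 1.0) > 1e-12:
            reason = f"non-annual periodicity ({r.periodicity_years} years)"
        elif criteria.require_valid:
            report = validate_mpm(r, criteria.tol)
            if not report.passed:
                reason = "; ".join(report.reasons) or "failed admissibility screens"
        if reason is None:
            surviving.append(r)
        else:
            exclusions.append({"population_id": r.population_id, "reason": reason})

    # group replicates of one population; prefer individual over mean matrices
    groups: dict[tuple[str, str], list[MPMRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in surviving:
        key = (r.species_name, r.population_id.split("|", 1)[0])
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    retained: list[MPMRecord] = []
    for key in order:
        members = groups[key]
        individual = [r for r in members if not r.is_mean_matrix]
        means = [r for r in members if r.is_mean_matrix]
        if individual:
            if len(individual) == 1:
                chosen = individual[0]
            else:
                chosen = mean_matrix(individual)
                chosen = replace(chosen, population_id=key[1])
            for m in means:
                exclusions.append(
                    {
                        "population_id": m.population_id,
                        "reason": "mean matrix superseded by individual record(s)",
                    }
                )
        else:
            chosen = means[0]
            for m in means[1:]:
                exclusions.append(
                    {"population_id": m.population_id, "reason": "duplicate mean matrix"}
                )
        retained.append(chosen)

    log = pd.DataFrame(exclusions, columns=["population_id", "reason"])
    return MPMCollection(records=retained, provenance=collection.provenance), log
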