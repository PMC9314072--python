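"""Life-history traits from the U/F decomposition of a projection matrix.

* ``R0``, the net reproductive rate: mean lifetime offspring production,
  the dominant eigenvalue of ``F (I - U)^-1`` (the fundamental matrix
  ``N = (I - U)^-1`` counts expected visits to each stage before death).
* ``T``, generation time: ``log(R0) / log(lambda1)``, the mean age of
  reproductive individuals; undefined when ``lambda1 = 1`` or ``R0 = 0``.
* ``phi``, mean reproductive output: per-stage sexual reproduction
  (column sums of ``F``) weighted by the stable stage structure ``w``.

Clonal reproduction (C) never enters these traits.
"""

from __future__ import annotations

from math import log

import numpy as np
import pandas as pd

from .mpm import EigenSystem, MPMCollection, MPMError, MPMRecord, eigen_analysis

__all__ = [
    "net_reproductive_rate",
    "generation_time",
    "mean_reproductive_output",
    "compute_traits",
]

_LAMBDA1_TOL = 1e-10


def net_reproductive_rate(U: np.ndarray, F: np.ndarray) -> float:
    """Dominant eigenvalue of F (I - U)^-1.

    Requires a dissipative survival matrix (spectral radius of U < 1, i.e.
    individuals do not survive forever).
    """
    if F is None:
        raise MPMError("net_reproductive_rate: F matrix is required")
    U = np.asarray(U, float)
    F = np.asarray(F, float)
    rho_U = float(np.abs(np.linalg.eigvals(U)).max()) if U.size else 0.0
    if rho_U >= 1.0 - 1e-10:
        raise MPMError(
            f"non-dissipative survival matrix (spectral radius {rho_U:.6f} >= 1)"
        )
    N = np.linalg.inv(np.eye(U.shape[0]) - U)
    R = F @ N
    return float(np.abs(np.linalg.eigvals(R)).max())


def generation_time(record: MPMRecord, eig: EigenSystem | None = None) -> float | None:
    """log(R0) / log(lambda1); None when undefined.

    Undefined when lambda1 = 1 within tolerance (stationary population:
    division by zero) or R0 = 0 (no sexual reproduction).
    """
    if record.mat_U is None or record.mat_F is None:
        raise MPMError(
            f"record {record.population_id!r}: generation time needs the U/F split"
        )
    eig = eig or eigen_analysis(record)
    r0 = net_reproductive_rate(record.mat_U, record.mat_F)
    if r0 <= 0.0 or abs(eig.lambda1 - 1.0) <= _LAMBDA1_TOL:
        return None
    return log(r0) / log(eig.lambda1)


def mean_reproductive_output(record: MPMRecord, eig: EigenSystem | None = None) -> float:
    """Stable-stage-weighted total sexual reproduction, phi = sum_j colsum(F)_j w_j."""
    if record.mat_F is None:
        raise MPMError(f"record {record.population_id!r}: F matrix is required for phi")
    eig = eig or eigen_analysis(record)
    return float(record.mat_F.sum(axis=0) @ eig.w)


def compute_traits(collection: MPMCollection) -> pd.DataFrame:
    """Trait table for every record carrying a U/F split.

    Records lacking the split get NaN traits and a ``no_uf_split`` flag (they
    remain usable for resilience-only outputs); undefined generation times
    are NaN with a flag.
    """
    rows = []
    for record in collection:
        row = {
            "population_id": record.population_id,
            "generation_time": np.nan,
            "net_reproductive_rate": np.nan,
            "mean_reproductive_output": np.nan,
            "matrix_dimension": record.dim,
        }
        flags = []
        if record.mat_U is None or record.mat_F is None:
            flags.append("no_uf_split")
        else:
            eig = eigen_analysis(record)
            try:
                row["net_reproductive_rate"] = net_reproductive_rate(
                    record.mat_U, record.mat_F
                )
            except MPMError:
                flags.append("non_dissipative_U")
            else:
                t = generation_time(record, eig)
                if t is None:
                    flags.append("generation_time_undefined")
                else:
                    row["generation_time"] = t
            row["mean_reproductive_output"] = mean_reproductive_output(record, eig)
        row["flags"] = ";".join(flags)
        rows.append(row)
    columns = [
        "population_id",
        "generation_time",
        "net_reproductive_rate",
        "mean_reproductive_output",
        "matrix_dimension",
        "flags",
    ]
    return pd.DataFrame(rows, columns=columns)
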