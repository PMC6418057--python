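"""Inverse remodelling: optimal load-history estimation from SED fields.

The loading history of a bone is modelled as ``n`` discrete posture load
cases acting with magnitudes ``α_i`` for ``m_i`` load cycles.  Under the
remodelling law "bone is added or removed unless the local mechanical
stimulus equals the equilibrium stimulus Ũ", the most probable history
minimizes, over combined scaling factors ``s_i = α_i² · m_i/m_tot ≥ 0``,

    Σ_x [ Ũ − Σ_i s_i · U_i(x) ]²

where ``U_i(x)`` is the strain energy density of unit load case ``i`` at
trabecular element ``x``.  The problem is a non-negative least squares
(NNLS) fit; with a constant number of load cycles per case the magnitudes
follow as ``α_i = sqrt(n · s_i)`` and the mean joint load vector is
``F̄ = 1/n · Σ α_i F_i``.

Only trabecular-bone elements enter the fit: the thick diaphyseal cortex
would otherwise dominate the objective and couple the result to the model
length.  The prediction quality is quantified by the coefficient of
variation (CoV) of the combined stimulus field — 0% means perfectly
homogeneous tissue loading, i.e. whole-bone remodelling equilibrium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from .errors import EmptyMaskError, InvalidArgumentError, UndefinedMetricError
from .fe import LoadCase, SEDField
from .voxel import VoxelImage

__all__ = [
    "EQUILIBRIUM_STIMULUS_MPA",
    "StimulusMatrix",
    "LoadingHistory",
    "assemble_stimulus_matrix",
    "optimize_history",
    "magnitudes",
    "mean_load_vector",
    "stimulus_field",
    "cov_stimulus",
    "quality_report",
    "predict_loading_history",
]

#: remodelling equilibrium stimulus Ũ (MPa)
EQUILIBRIUM_STIMULUS_MPA = 0.02


@dataclass
class StimulusMatrix:
    """Per-element unit-load SEDs: one row per trabecular element, one
    column per load case (MPa)."""

    A: np.ndarray
    elem_idx: np.ndarray          # (m, 3) voxel indices of the rows
    angles_deg: np.ndarray        # (n,) load-case angles, column order

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise InvalidArgumentError("stimulus matrix must be 2-D")
        if (self.A < 0).any():
            raise InvalidArgumentError("SED entries must be non-negative")

    @property
    def n_elements(self) -> int:
        return self.A.shape[0]

    @property
    def n_load_cases(self) -> int:
        return self.A.shape[1]


@dataclass
class LoadingHistory:
    """Recovered loading history and its quality metrics."""

    s: np.ndarray
    alpha: np.ndarray
    mean_vector_N: np.ndarray
    cov_init_pct: float
    cov_opt_pct: float
    equilibrium_stimulus_MPa: float = EQUILIBRIUM_STIMULUS_MPA
    angles_deg: np.ndarray | None = None
    #: the per-case number of load cycles m_i is assumed constant, so the
    #: combined factors resolve to magnitudes via alpha = sqrt(n * s)
    m_assumption: str = "equal load cycles for all load cases"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.mean_vector_N = np.asarray(self.mean_vector_N, dtype=float)
        if (self.s < 0).any() or (self.alpha < 0).any():
            raise InvalidArgumentError("scaling factors must be non-negative")
        n = len(self.s)
        if not np.allclose(self.alpha, np.sqrt(n * self.s), atol=1e-9):
            raise InvalidArgumentError("alpha must equal sqrt(n * s)")

    @property
    def dominant_index(self) -> int:
        """0-based index of the load case with the largest magnitude."""
        return int(np.argmax(self.alpha))

    def to_dict(self) -> dict:
        return {
            "s": self.s.tolist(),
            "alpha": self.alpha.tolist(),
            "mean_vector_N": self.mean_vector_N.tolist(),
            "cov_init_pct": self.cov_init_pct,
            "cov_opt_pct": self.cov_opt_pct,
            "equilibrium_stimulus_MPa": self.equilibrium_stimulus_MPa,
            "angles_deg": None if self.angles_deg is None else list(self.angles_deg),
            "m_assumption": self.m_assumption,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "LoadingHistory":
        return cls(
            s=np.asarray(d["s"]),
            alpha=np.asarray(d["alpha"]),
            mean_vector_N=np.asarray(d["mean_vector_N"]),
            cov_init_pct=d["cov_init_pct"],
            cov_opt_pct=d["cov_opt_pct"],
            equilibrium_stimulus_MPa=d.get(
                "equilibrium_stimulus_MPa", EQUILIBRIUM_STIMULUS_MPA),
            angles_deg=None if d.get("angles_deg") is None else np.asarray(d["angles_deg"]),
        )


def assemble_stimulus_matrix(
    sed_fields: list[SEDField],
    trabecular_mask: VoxelImage,
) -> StimulusMatrix:
    """Stack per-load-case SED fields into the stimulus matrix.

    Rows are restricted to elements inside the trabecular mask; columns
    follow the load-case order of ``sed_fields``.
    """
    if not sed_fields:
        raise InvalidArgumentError("no SED fields given")
    ref = sed_fields[0].elem_idx
    for f in sed_fields[1:]:
        if f.elem_idx.shape != ref.shape or not np.array_equal(f.elem_idx, ref):
            raise InvalidArgumentError("SED fields do not share an element map")
    mask = trabecular_mask.data.astype(bool)
    inside = mask[ref[:, 0], ref[:, 1], ref[:, 2]]
    if not inside.any():
        raise EmptyMaskError("no elements inside the trabecular mask")
    A = np.column_stack([f.values[inside] for f in sed_fields])
    return StimulusMatrix(
        A=A,
        elem_idx=ref[inside],
        angles_deg=np.array([f.angle_deg for f in sed_fields]),
    )


def optimize_history(
    A: StimulusMatrix | np.ndarray,
    u_tilde: float = EQUILIBRIUM_STIMULUS_MPA,
) -> np.ndarray:
    """Combined scaling factors ``s = argmin_{s≥0} ‖Ũ·1 − A·s‖²`` (NNLS)."""
    mat = A.A if isinstance(A, StimulusMatrix) else np.asarray(A, dtype=float)
    if mat.size == 0:
        raise InvalidArgumentError("empty stimulus matrix")
    if u_tilde <= 0:
        raise InvalidArgumentError("equilibrium stimulus must be positive")
    if not mat.any():
        raise InvalidArgumentError(
            "all SEDs are zero: no load case transfers load to the trabecular bone"
        )
    b = np.full(mat.shape[0], u_tilde)
    s, _ = optimize.nnls(mat, b)
    return s


def magnitudes(s: np.ndarray, n: int | None = None) -> np.ndarray:
    """Load magnitudes ``α_i = sqrt(n · s_i)`` (equal-load-cycle assumption)."""
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise InvalidArgumentError("combined scaling factors must be non-negative")
    if n is None:
        n = len(s)
    return np.sqrt(n * s)


def mean_load_vector(alpha: np.ndarray, load_cases: list[LoadCase]) -> np.ndarray:
    """Mean joint load vector ``F̄ = 1/n · Σ α_i F_i`` (N)."""
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) != len(load_cases):
        raise InvalidArgumentError("alpha and load cases length mismatch")
    F = np.stack([lc.resultant_N for lc in load_cases])
    return (alpha[:, None] * F).sum(axis=0) / len(load_cases)


def stimulus_field(A: StimulusMatrix | np.ndarray, s: np.ndarray) -> np.ndarray:
    """Combined per-element stimulus ``U = A·s`` (MPa)."""
    mat = A.A if isinstance(A, StimulusMatrix) else np.asarray(A, dtype=float)
    return mat @ np.asarray(s, dtype=float)


def cov_stimulus(U: np.ndarray, ddof: int = 0) -> float:
    """Coefficient of variation of the stimulus field, in percent.

    Population standard deviation by default (``ddof=0``); the element set
    is the full population of trabecular elements, not a sample.
    """
    U = np.asarray(U, dtype=float)
    if U.size == 0:
        raise UndefinedMetricError("empty stimulus field")
    mean = U.mean()
    if mean <= 0:
        raise UndefinedMetricError("stimulus field has non-positive mean")
    return 100.0 * float(U.std(ddof=ddof)) / float(mean)


def quality_report(
    A: StimulusMatrix | np.ndarray,
    s_opt: np.ndarray,
    drop_zero_rows: bool = False,
) -> tuple[float, float]:
    """CoV of the stimulus before (uniform scaling) and after optimization.

    The initial history weights every load case equally; CoV is invariant
    under a common rescaling of those weights, so unit weights are used.
    Elements with zero SED in every column penalize homogeneity and are
    retained unless ``drop_zero_rows`` is set.
    """
    mat = A.A if isinstance(A, StimulusMatrix) else np.asarray(A, dtype=float)
    if drop_zero_rows:
        mat = mat[mat.any(axis=1)]
    cov_init = cov_stimulus(mat @ np.ones(mat.shape[1]))
    cov_opt = cov_stimulus(mat @ np.asarray(s_opt, dtype=float))
    return cov_init, cov_opt


def predict_loading_history(
    sed_fields: list[SEDField],
    trabecular_mask: VoxelImage,
    load_cases: list[LoadCase],
    u_tilde: float = EQUILIBRIUM_STIMULUS_MPA,
) -> LoadingHistory:
    """Full inverse step: stimulus matrix → NNLS → magnitudes → F̄ → CoV."""
    A = assemble_stimulus_matrix(sed_fields, trabecular_mask)
    s = optimize_history(A, u_tilde=u_tilde)
    alpha = magnitudes(s)
    fbar = mean_load_vector(alpha, load_cases)
    cov_init, cov_opt = quality_report(A, s)
    return LoadingHistory(
        s=s,
        alpha=alpha,
        mean_vector_N=fbar,
        cov_init_pct=cov_init,
        cov_opt_pct=cov_opt,
        equilibrium_stimulus_MPa=u_tilde,
        angles_deg=A.angles_deg,
    )
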