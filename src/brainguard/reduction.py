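"""Feature-space construction for high-dimensional strain fields.

A snapshot matrix ``zeta`` (J points x M samples) of full-field von Mises
strain is centred and decomposed with a truncated singular value
decomposition.  The retained left singular vectors form an orthonormal
reduced basis; projecting a field onto it yields the "features" (principal
component coefficients) that the Gaussian-process layer regresses on, and
the inverse map reconstructs a full field from predicted coefficients.

Conventions
-----------
All data matrices are column-per-sample: inputs are ``(I, M)``, output
snapshots ``(J, M)``, coefficient matrices ``(m, n)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "SnapshotDataset",
    "FeatureBasis",
    "fit_basis",
    "encode",
    "decode",
    "spectrum_report",
    "save_dataset",
    "load_dataset",
    "save_dataset_csv",
    "load_dataset_csv",
    "save_basis",
    "load_basis",
]


@dataclass
class SnapshotDataset:
    """Paired input/output snapshot data.

    Parameters
    ----------
    inputs : (I, M) array
        One input vector per column (material parameters in kPa and
        micromotion amplitudes/displacements in micrometres).
    outputs : (J, M) array
        Full-field von Mises strain (dimensionless), one field per column,
        column-aligned with ``inputs``.
    point_coords : (J, 3) array
        Measurement-point positions in millimetres.
    sample_ids : list of str
        One label per column.
    meta : dict
        Provenance: generator seed, mode, scene parameters, noise spec.
    """

    inputs: np.ndarray
    outputs: np.ndarray
    point_coords: np.ndarray
    sample_ids: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        self.point_coords = np.asarray(self.point_coords, dtype=float)
        if self.inputs.ndim != 2 or self.outputs.ndim != 2:
            raise ValueError("inputs and outputs must be 2-D matrices")
        if self.inputs.shape[1] != self.outputs.shape[1]:
            raise ValueError(
                "inputs and outputs must share the sample axis: "
                f"{self.inputs.shape[1]} != {self.outputs.shape[1]}"
            )
        if self.outputs.shape[1] < 2:
            raise ValueError("need at least two samples (M >= 2)")
        if self.outputs.shape[0] < 1:
            raise ValueError("need at least one measurement point (J >= 1)")
        if not np.all(np.isfinite(self.inputs)):
            raise ValueError("non-finite entries in inputs")
        if not np.all(np.isfinite(self.outputs)):
            raise ValueError("non-finite entries in outputs")
        if self.point_coords.shape != (self.outputs.shape[0], 3):
            raise ValueError("point_coords must be (J, 3)")
        if len(self.sample_ids) != self.inputs.shape[1]:
            raise ValueError("one sample_id per column required")
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_points(self) -> int:
        return self.outputs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[1]


@dataclass
class FeatureBasis:
    """Truncated orthonormal basis of the centred snapshot matrix.

    ``mean_field`` is the arithmetic mean of the snapshots, ``basis`` the
    retained left singular vectors (J x m), ``singular_values`` their
    singular values (non-increasing) and ``energy_ratios`` each value's
    share sigma_i^2 / sum(sigma^2) of the total snapshot energy.
    ``spectrum`` keeps the full singular-value sequence so that discarded
    energy remains reportable after truncation.
    """

    mean_field: np.ndarray
    basis: np.ndarray
    singular_values: np.ndarray
    energy_ratios: np.ndarray
    m: int
    truncation_threshold: float
    spectrum: np.ndarray

    @property
    def n_points(self) -> int:
        return self.basis.shape[0]


def _optimal_threshold_coefficient(beta: float) -> float:
    """Gavish-Donoho coefficient omega(beta) for the median-based optimal
    hard threshold of singular values under white additive noise."""
    return 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43


def fit_basis(
    outputs: np.ndarray,
    truncation_threshold: float = 1e-10,
    max_components: int | None = None,
    noise_cutoff: str | None = None,
) -> FeatureBasis:
    """Centre the snapshot matrix and fit a truncated SVD basis.

    The retained dimension ``m`` is the smallest integer for which the
    discarded energy ratio ``sum_{i>m} sigma_i^2 / sum_i sigma_i^2`` falls
    below ``truncation_threshold``; ``max_components`` optionally caps it.

    With additive measurement noise on the snapshots the tail of the
    spectrum is a noise bulk that the energy rule would retain almost in
    full; ``noise_cutoff="auto"`` additionally discards singular values
    below the median-based optimal hard threshold (Gavish-Donoho), i.e.
    modes indistinguishable from white noise.  On noise-free data the
    spectrum's median sits at the numerical-rank floor and the cutoff is
    inactive.

    The sign of each retained singular vector is fixed by making its
    largest-magnitude entry positive, so the basis is reproducible across
    linear-algebra backends.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 2:
        raise ValueError("outputs must be a (J, M) matrix")
    J, M = outputs.shape
    if M < 2:
        raise ValueError("need at least two snapshots (M >= 2)")
    if not np.all(np.isfinite(outputs)):
        raise ValueError("non-finite entries in outputs")
    if not (0.0 < truncation_threshold < 1.0):
        raise ValueError("truncation_threshold must lie in (0, 1)")

    mean_field = outputs.mean(axis=1)
    Z = outputs - mean_field[:, None]

    if J > 4 * M:
        # Thin SVD via the M x M Gram problem; exact and cheap when J >> M.
        G = Z.T @ Z
        w, V = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        s = np.sqrt(w)
        V = V[:, order]
        nonzero = s > s[0] * 1e-14 if s[0] > 0 else np.zeros_like(s, bool)
        U = np.zeros((J, M))
        if nonzero.any():
            U[:, nonzero] = (Z @ V[:, nonzero]) / s[nonzero]
    else:
        U, s, _ = np.linalg.svd(Z, full_matrices=False)

    total = float(np.sum(s**2))
    if total == 0.0:
        warnings.warn(
            "zero-variance snapshot matrix: all centred singular values "
            "vanish; clamping to a single degenerate component",
            RuntimeWarning,
        )
        basis = np.zeros((J, 1))
        basis[0, 0] = 1.0
        return FeatureBasis(
            mean_field=mean_field,
            basis=basis,
            singular_values=np.zeros(1),
            energy_ratios=np.zeros(1),
            m=1,
            truncation_threshold=truncation_threshold,
            spectrum=s.copy(),
        )

    ratios = s**2 / total
    # discarded[k] = energy dropped when retaining the first k components
    discarded = 1.0 - np.cumsum(ratios)
    m = int(np.searchsorted(-discarded, -truncation_threshold, side="right") + 1)
    m = min(m, len(s))
    if m < 1:
        m = 1
    if max_components is not None:
        m = min(m, int(max_components))
    if noise_cutoff == "auto" and len(s) >= 10:
        beta = min(J, M) / max(J, M)
        tau = _optimal_threshold_coefficient(beta) * float(np.median(s))
        m_signal = int(np.sum(s > tau))
        if 1 <= m_signal < m:
            m = m_signal
    elif noise_cutoff not in (None, "auto"):
        raise ValueError("noise_cutoff must be None or 'auto'")

    U = U[:, :m].copy()
    # deterministic sign: largest-magnitude entry of each column positive
    flip = U[np.argmax(np.abs(U), axis=0), np.arange(m)] < 0
    U[:, flip] *= -1.0

    return FeatureBasis(
        mean_field=mean_field,
        basis=U,
        singular_values=s[:m].copy(),
        energy_ratios=ratios[:m].copy(),
        m=m,
        truncation_threshold=truncation_threshold,
        spectrum=s.copy(),
    )


def encode(basis: FeatureBasis, fields: np.ndarray) -> np.ndarray:
    """Project fields onto the reduced basis: ``beta = Phi^T (xi - mu)``.

    ``fields`` may be a single length-J vector or a (J, n) matrix; the
    result is (m,) or (m, n) accordingly.
    """
    fields = np.asarray(fields, dtype=float)
    single = fields.ndim == 1
    F = fields[:, None] if single else fields
    if F.shape[0] != basis.n_points:
        raise ValueError(
            f"field has {F.shape[0]} rows, basis expects {basis.n_points}"
        )
    beta = basis.basis.T @ (F - basis.mean_field[:, None])
    return beta[:, 0] if single else beta


def decode(basis: FeatureBasis, coeffs: np.ndarray) -> np.ndarray:
    """Reconstruct fields from coefficients: ``xi = mu + Phi beta``."""
    coeffs = np.asarray(coeffs, dtype=float)
    single = coeffs.ndim == 1
    B = coeffs[:, None] if single else coeffs
    if B.shape[0] != basis.m:
        raise ValueError(
            f"coefficients have {B.shape[0]} components, basis has {basis.m}"
        )
    F = basis.mean_field[:, None] + basis.basis @ B
    return F[:, 0] if single else F


def spectrum_report(basis: FeatureBasis) -> list[tuple[int, float]]:
    """Energy ratio of every singular value, including discarded ones.

    Returns ``[(index, sigma_i^2 / sum sigma^2), ...]`` in descending
    order; the ratios sum to 1 over the full spectrum.
    """
    total = float(np.sum(basis.spectrum**2))
    if total == 0.0:
        return [(i, 0.0) for i in range(len(basis.spectrum))]
    return [
        (i, float(r)) for i, r in enumerate(basis.spectrum**2 / total)
    ]


# ---------------------------------------------------------------------------
# on-disk layout


def save_dataset(dataset: SnapshotDataset, directory) -> Path:
    """Write a dataset directory: ``manifest.json`` + ``data.h5``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "I": dataset.n_inputs,
        "J": dataset.n_points,
        "M": dataset.n_samples,
        "units": {
            "inputs": "kPa / um",
            "outputs": "dimensionless strain",
            "coords": "mm",
        },
        "meta": dataset.meta,
    }
    tmp = directory / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.rename(directory / "manifest.json")
    h5tmp = directory / "data.h5.tmp"
    with h5py.File(h5tmp, "w") as f:
        f.create_dataset("inputs", data=dataset.inputs, dtype="f8")
        f.create_dataset("outputs", data=dataset.outputs, dtype="f8")
        f.create_dataset("coords", data=dataset.point_coords, dtype="f8")
        f.create_dataset(
            "sample_ids",
            data=np.array(dataset.sample_ids, dtype=h5py.string_dtype()),
        )
    h5tmp.rename(directory / "data.h5")
    return directory


def load_dataset(directory) -> SnapshotDataset:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    with h5py.File(directory / "data.h5", "r") as f:
        inputs = f["inputs"][...]
        outputs = f["outputs"][...]
        coords = f["coords"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][...]]
    return SnapshotDataset(
        inputs=inputs,
        outputs=outputs,
        point_coords=coords,
        sample_ids=ids,
        meta=manifest.get("meta", {}),
    )


def save_dataset_csv(dataset: SnapshotDataset, directory) -> Path:
    """CSV alternative for small datasets: one file per array, header row."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "I": dataset.n_inputs, "J": dataset.n_points, "M": dataset.n_samples,
        "meta": dataset.meta,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    header = ",".join(dataset.sample_ids)
    np.savetxt(directory / "inputs.csv", dataset.inputs, delimiter=",",
               header=header, comments="")
    np.savetxt(directory / "outputs.csv", dataset.outputs, delimiter=",",
               header=header, comments="")
    np.savetxt(directory / "coords.csv", dataset.point_coords, delimiter=",",
               header="x_mm,y_mm,z_mm", comments="")
    return directory


def load_dataset_csv(directory) -> SnapshotDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    with open(directory / "inputs.csv") as f:
        sample_ids = f.readline().strip().split(",")
    inputs = np.loadtxt(directory / "inputs.csv", delimiter=",", skiprows=1,
                        ndmin=2)
    outputs = np.loadtxt(directory / "outputs.csv", delimiter=",", skiprows=1,
                         ndmin=2)
    coords = np.loadtxt(directory / "coords.csv", delimiter=",", skiprows=1,
                        ndmin=2)
    return SnapshotDataset(
        inputs=inputs, outputs=outputs, point_coords=coords,
        sample_ids=sample_ids, meta=manifest.get("meta", {}),
    )


def save_basis(basis: FeatureBasis, path) -> Path:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with h5py.File(tmp, "w") as f:
        f.create_dataset("mean", data=basis.mean_field, dtype="f8")
        f.create_dataset("basis", data=basis.basis, dtype="f8")
        f.create_dataset("singular_values", data=basis.singular_values, dtype="f8")
        f.create_dataset("energy_ratios", data=basis.energy_ratios, dtype="f8")
        f.create_dataset("spectrum", data=basis.spectrum, dtype="f8")
        f.attrs["truncation_threshold"] = basis.truncation_threshold
        f.attrs["m"] = basis.m
    tmp.rename(path)
    return path


def load_basis(path) -> FeatureBasis:
    with h5py.File(path, "r") as f:
        return FeatureBasis(
            mean_field=f["mean"][...],
            basis=f["basis"][...],
            singular_values=f["singular_values"][...],
            energy_ratios=f["energy_ratios"][...],
            m=int(f.attrs["m"]),
            truncation_threshold=float(f.attrs["truncation_threshold"]),
            spectrum=f["spectrum"][...],
        )
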