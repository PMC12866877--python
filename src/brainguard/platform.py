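"""Emulator training, full-field prediction, evaluation, and device selection.

The emulator chains the feature basis (``reduction``) with one scalar GP
per retained coefficient (``gp``): inputs are z-scored with statistics
fitted on the training design, snapshots are encoded to coefficients, one
GP is fitted per coefficient, and predictions are decoded back to fields.
The evaluation metric is the normalized relative error

    err_j = | S_pred,j / max|S_pred|  -  S_ref,j / max|S_ref| |,

i.e. both fields are scaled by their own maximum before differencing, so
the metric is invariant to a uniform rescaling of either field.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from . import gp as gpmod
from .gp import ComponentGP, GPFitOptions, GPHyperparameters, PosteriorPrediction
from .reduction import FeatureBasis, SnapshotDataset, decode, encode, fit_basis

__all__ = [
    "TrainConfig",
    "Emulator",
    "FieldPrediction",
    "EvaluationReport",
    "DeviceCandidate",
    "OptimalChoice",
    "MonitorStep",
    "train_emulator",
    "predict_field",
    "relative_error_field",
    "evaluate",
    "select_optimal_device",
    "monitor_stream",
    "save_emulator",
    "load_emulator",
]

DEFAULT_BIN_EDGES = (0.0, 0.005, 0.010, 0.015, 0.020, 0.025, np.inf)


@dataclass(frozen=True)
class TrainConfig:
    """Training settings.

    ``truncation_threshold`` bounds the discarded snapshot energy of the
    feature basis; ``max_components`` caps the basis size, and
    ``noise_cutoff="auto"`` drops basis directions whose singular values
    sit below the optimal hard threshold for white noise (noisy training
    snapshots otherwise flood the basis with pure-noise directions whose
    GPs predict ~0 at cubic cost each).  ``seed`` drives the optimizer's
    restart draws, one child seed per component.
    """

    truncation_threshold: float = 1e-10
    max_components: int | None = 40
    noise_cutoff: str | None = "auto"
    gp_options: GPFitOptions = field(default_factory=GPFitOptions)
    seed: int = 0


@dataclass
class Emulator:
    """Trained feature-based predictor/monitor."""

    input_mean: np.ndarray  # (I,)
    input_std: np.ndarray  # (I,)
    basis: FeatureBasis
    components: list[ComponentGP]
    mode: str
    training_meta: dict = field(default_factory=dict)
    point_coords: np.ndarray | None = None  # (J, 3), mm; for field export

    @property
    def n_inputs(self) -> int:
        return self.input_mean.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def normalize(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.asarray(inputs, dtype=float)
        single = inputs.ndim == 1
        X = inputs[:, None] if single else inputs
        if X.shape[0] != self.n_inputs:
            raise ValueError(
                f"input has dimension {X.shape[0]}, emulator expects {self.n_inputs}"
            )
        Xn = (X - self.input_mean[:, None]) / self.input_std[:, None]
        return Xn[:, 0] if single else Xn


@dataclass
class FieldPrediction:
    """Full-field posterior mean and variance plus the raw coefficients."""

    mean_field: np.ndarray
    variance_field: np.ndarray
    coefficients: list[PosteriorPrediction]


@dataclass
class EvaluationReport:
    """Error summary of an emulator against reference snapshots.

    ``per_point_error`` is the full (J, n2) matrix of normalized relative
    errors; ``mean_error_field`` averages it over test samples (the
    per-point mean absolute error map, whose maximum is the headline
    full-field accuracy figure); ``per_sample_mean_error`` averages it
    over points; ``max_error`` is the worst single point of any single
    sample.
    """

    per_point_error: np.ndarray  # (J, n2)
    per_sample_mean_error: np.ndarray  # (n2,)
    mean_error_field: np.ndarray  # (J,)
    max_error: float
    max_mean_error: float  # max over points of the sample-averaged map
    bin_edges: tuple
    bin_counts: np.ndarray
    fraction_below: dict

    def to_dict(self) -> dict:
        return {
            "max_error": self.max_error,
            "max_mean_error": self.max_mean_error,
            "per_sample_mean_error": self.per_sample_mean_error.tolist(),
            "bin_edges": [e if np.isfinite(e) else "inf" for e in self.bin_edges],
            "bin_counts": self.bin_counts.tolist(),
            "fraction_below": {str(k): v for k, v in self.fraction_below.items()},
        }


@dataclass(frozen=True)
class DeviceCandidate:
    """A candidate implant: label plus probe material properties."""

    label: str
    e_probe_kpa: float
    nu_probe: float = 0.49


@dataclass
class OptimalChoice:
    candidate: DeviceCandidate
    patient_props: dict
    injury_scores: dict  # label -> {regime: score, "overall": score}


@dataclass
class MonitorStep:
    index: int
    prediction: FieldPrediction
    max_strain: float
    exceeds_threshold: bool


def _dataset_digest(dataset: SnapshotDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.inputs).tobytes())
    h.update(np.ascontiguousarray(dataset.outputs).tobytes())
    return h.hexdigest()[:16]


def train_emulator(train: SnapshotDataset, config: TrainConfig | None = None,
                   mode: str | None = None) -> Emulator:
    """Fit the feature basis and one GP per retained coefficient."""
    config = config or TrainConfig()
    if train.n_samples < 10:
        raise ValueError("need at least 10 training samples")
    basis = fit_basis(
        train.outputs,
        truncation_threshold=config.truncation_threshold,
        max_components=config.max_components,
        noise_cutoff=config.noise_cutoff,
    )
    coeffs = encode(basis, train.outputs)  # (m, M)

    input_mean = train.inputs.mean(axis=1)
    input_std = train.inputs.std(axis=1)
    input_std = np.where(input_std > 0, input_std, 1.0)
    Xn = (train.inputs - input_mean[:, None]) / input_std[:, None]

    child_seeds = np.random.SeedSequence(config.seed).spawn(basis.m)
    components = []
    for k in range(basis.m):
        y = coeffs[k]
        opts = replace(
            config.gp_options,
            seed=int(child_seeds[k].generate_state(1)[0] % (2**31)),
        )
        if float(np.max(np.abs(y - y.mean()))) == 0.0:
            # constant coefficient (degenerate snapshots): no signal to
            # regress on; pin a tiny-amplitude GP that predicts ~0
            warnings.warn(
                f"component {k} has constant coefficients; fitting a "
                "degenerate near-zero GP",
                RuntimeWarning,
            )
            scale = max(float(np.max(np.abs(y))), 1e-12)
            hyper = GPHyperparameters(
                signal_std=scale, length_scale=1.0, noise_std=0.0
            )
            components.append(gpmod.fit_component(Xn, y, opts, hyper=hyper))
        else:
            components.append(gpmod.fit_component(Xn, y, opts))

    meta = {
        "seed": config.seed,
        "truncation_threshold": config.truncation_threshold,
        "max_components": config.max_components,
        "dataset_digest": _dataset_digest(train),
        "dataset_meta": train.meta,
    }
    return Emulator(
        input_mean=input_mean,
        input_std=input_std,
        basis=basis,
        components=components,
        mode=mode or train.meta.get("mode", "unknown"),
        training_meta=meta,
        point_coords=train.point_coords.copy(),
    )


def _predict_coefficients(emulator: Emulator, inputs: np.ndarray):
    """Per-component posterior at one or more (columns of) inputs."""
    Xn = emulator.normalize(inputs)
    if Xn.ndim == 1:
        Xn = Xn[:, None]
    return [gpmod.posterior_predict(c, Xn) for c in emulator.components]


def predict_field(emulator: Emulator, new_input: np.ndarray) -> FieldPrediction:
    """Predict the full strain field for one input vector.

    The mean field is ``mu + Phi E[beta]``; the variance field uses the
    independence of the component GPs:
    ``var_j = sum_k Phi_jk^2 var(beta_k)``.
    """
    new_input = np.asarray(new_input, dtype=float).ravel()
    posts = _predict_coefficients(emulator, new_input)
    means = np.array([p.mean[0] for p in posts])
    variances = np.array([p.variance[0] for p in posts])
    mean_field = decode(emulator.basis, means)
    variance_field = (emulator.basis.basis**2) @ variances
    return FieldPrediction(
        mean_field=mean_field, variance_field=variance_field, coefficients=posts
    )


def predict_fields(emulator: Emulator, inputs: np.ndarray) -> np.ndarray:
    """Batch posterior-mean fields, one column per input column."""
    posts = _predict_coefficients(emulator, inputs)
    means = np.vstack([p.mean for p in posts])  # (m, n)
    return decode(emulator.basis, means)


def relative_error_field(pred_field: np.ndarray, ref_field: np.ndarray,
                         signed: bool = False) -> np.ndarray:
    """Normalized relative error per point (both fields scaled by their max).

    Works columnwise on (J, n) matrices: each sample's fields are
    normalized by their own maxima.
    """
    pred = np.asarray(pred_field, dtype=float)
    ref = np.asarray(ref_field, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference fields must share a shape")
    single = pred.ndim == 1
    P = pred[:, None] if single else pred
    R = ref[:, None] if single else ref
    p_max = np.max(np.abs(P), axis=0)
    r_max = np.max(np.abs(R), axis=0)
    if np.any(r_max == 0):
        raise ValueError("all-zero reference field: relative error undefined")
    if np.any(p_max == 0):
        raise ValueError("all-zero predicted field: relative error undefined")
    err = P / p_max - R / r_max
    if not signed:
        err = np.abs(err)
    return err[:, 0] if single else err


def evaluate(emulator: Emulator, test: SnapshotDataset,
             bin_edges: tuple = DEFAULT_BIN_EDGES) -> EvaluationReport:
    """Error report of the emulator on a held-out dataset.

    Per-sample mean errors are binned over ``bin_edges``;
    ``fraction_below[t]`` is the fraction of samples with mean error
    strictly below t for each interior edge.
    """
    if test.n_samples < 1:
        raise ValueError("empty test set")
    if test.n_points != emulator.basis.n_points:
        raise ValueError("test set has a different number of measurement points")
    pred = predict_fields(emulator, test.inputs)
    per_point = relative_error_field(pred, test.outputs)
    per_sample = per_point.mean(axis=0)
    counts, _ = np.histogram(per_sample, bins=np.asarray(bin_edges))
    fraction_below = {
        float(t): float(np.mean(per_sample < t))
        for t in bin_edges
        if 0.0 < t < np.inf
    }
    mean_error_field = per_point.mean(axis=1)
    return EvaluationReport(
        per_point_error=per_point,
        per_sample_mean_error=per_sample,
        mean_error_field=mean_error_field,
        max_error=float(np.max(per_point)),
        max_mean_error=float(np.max(mean_error_field)),
        bin_edges=tuple(bin_edges),
        bin_counts=counts,
        fraction_below=fraction_below,
    )


_SCORE_FUNCS = {
    "max": lambda f: float(np.max(f)),
    "mean": lambda f: float(np.mean(f)),
}


def _injury_score(field_values: np.ndarray, score: str, threshold: float) -> float:
    if score == "fraction_above":
        return float(np.mean(field_values > threshold))
    try:
        return _SCORE_FUNCS[score](field_values)
    except KeyError:
        raise ValueError(f"unknown injury score {score!r}") from None


def select_optimal_device(
    emulator_resp: Emulator,
    emulator_vasc: Emulator,
    patient_props: dict,
    candidates: list[DeviceCandidate],
    score: str = "max",
    score_threshold: float = 0.0,
) -> OptimalChoice:
    """Rank candidate devices by predicted injury and pick the least harmful.

    For each candidate, both physiological-regime predictors are queried
    with (patient brain modulus, candidate probe modulus, regime
    micromotion amplitude); the candidate's injury score is the worse of
    the two regime aggregates and the argmin wins (ties break to the
    first candidate in input order).
    """
    if not candidates:
        raise ValueError("need at least one device candidate")
    e_brain = float(patient_props["e_brain_kpa"])
    amp_resp = float(patient_props.get("respiration_amplitude_um", 60.0))
    amp_vasc = float(patient_props.get("vascular_amplitude_um", 20.0))
    scores = {}
    best = None
    best_score = np.inf
    for cand in candidates:
        x_resp = np.array([e_brain, cand.e_probe_kpa, amp_resp])
        x_vasc = np.array([e_brain, cand.e_probe_kpa, amp_vasc])
        s_resp = _injury_score(
            predict_field(emulator_resp, x_resp).mean_field, score, score_threshold
        )
        s_vasc = _injury_score(
            predict_field(emulator_vasc, x_vasc).mean_field, score, score_threshold
        )
        overall = max(s_resp, s_vasc)
        scores[cand.label] = {
            "respiration": s_resp, "vascular": s_vasc, "overall": overall
        }
        if overall < best_score:  # strict: ties keep the earlier candidate
            best_score = overall
            best = cand
    return OptimalChoice(
        candidate=best, patient_props=dict(patient_props), injury_scores=scores
    )


def monitor_stream(
    emulator: Emulator,
    displacement_sequence,
    threshold: float | None = None,
):
    """Stateless per-step monitoring of a displacement stream.

    Yields a :class:`MonitorStep` per valid 3-vector step (um) with the
    predicted maximum strain and, if ``threshold`` is set, an exceedance
    flag.  Malformed steps are logged and skipped; the stream continues.
    """
    results = []
    for i, u in enumerate(displacement_sequence):
        try:
            u = np.asarray(u, dtype=float).ravel()
            if u.shape[0] != emulator.n_inputs or not np.all(np.isfinite(u)):
                raise ValueError(f"malformed displacement at step {i}")
            pred = predict_field(emulator, u)
        except (ValueError, TypeError) as exc:
            warnings.warn(f"skipping stream step {i}: {exc}", RuntimeWarning)
            continue
        max_strain = float(np.max(pred.mean_field))
        results.append(
            MonitorStep(
                index=i,
                prediction=pred,
                max_strain=max_strain,
                exceeds_threshold=(
                    threshold is not None and max_strain > threshold
                ),
            )
        )
    return results


# ---------------------------------------------------------------------------
# serialization


def save_emulator(emulator: Emulator, path) -> Path:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with h5py.File(tmp, "w") as f:
        f.attrs["mode"] = emulator.mode
        f.attrs["training_meta"] = json.dumps(emulator.training_meta, sort_keys=True)
        f.create_dataset("input_mean", data=emulator.input_mean, dtype="f8")
        f.create_dataset("input_std", data=emulator.input_std, dtype="f8")
        if emulator.point_coords is not None:
            f.create_dataset("point_coords", data=emulator.point_coords, dtype="f8")
        b = f.create_group("basis")
        b.create_dataset("mean", data=emulator.basis.mean_field, dtype="f8")
        b.create_dataset("basis", data=emulator.basis.basis, dtype="f8")
        b.create_dataset("singular_values", data=emulator.basis.singular_values, dtype="f8")
        b.create_dataset("energy_ratios", data=emulator.basis.energy_ratios, dtype="f8")
        b.create_dataset("spectrum", data=emulator.basis.spectrum, dtype="f8")
        b.attrs["m"] = emulator.basis.m
        b.attrs["truncation_threshold"] = emulator.basis.truncation_threshold
        comps = f.create_group("components")
        for k, c in enumerate(emulator.components):
            g = comps.create_group(f"{k:04d}")
            g.attrs["signal_std"] = c.hyper.signal_std
            g.attrs["length_scale"] = c.hyper.length_scale
            g.attrs["noise_std"] = c.hyper.noise_std
            g.attrs["jitter"] = c.jitter
            g.attrs["nlml"] = c.nlml_value
            g.attrs["converged"] = c.converged
            g.attrs["n_iter"] = c.n_iter
            g.create_dataset("train_inputs", data=c.train_inputs, dtype="f8")
            g.create_dataset("train_targets", data=c.train_targets, dtype="f8")
            g.create_dataset("weights", data=c.weights, dtype="f8")
            g.create_dataset("chol_lower", data=c.chol_lower, dtype="f8")
    tmp.rename(path)
    return path


def load_emulator(path) -> Emulator:
    with h5py.File(path, "r") as f:
        basis = FeatureBasis(
            mean_field=f["basis/mean"][...],
            basis=f["basis/basis"][...],
            singular_values=f["basis/singular_values"][...],
            energy_ratios=f["basis/energy_ratios"][...],
            m=int(f["basis"].attrs["m"]),
            truncation_threshold=float(f["basis"].attrs["truncation_threshold"]),
            spectrum=f["basis/spectrum"][...],
        )
        components = []
        for key in sorted(f["components"]):
            g = f["components"][key]
            components.append(
                ComponentGP(
                    hyper=GPHyperparameters(
                        signal_std=float(g.attrs["signal_std"]),
                        length_scale=float(g.attrs["length_scale"]),
                        noise_std=float(g.attrs["noise_std"]),
                    ),
                    train_inputs=g["train_inputs"][...],
                    train_targets=g["train_targets"][...],
                    chol_lower=g["chol_lower"][...],
                    weights=g["weights"][...],
                    jitter=float(g.attrs["jitter"]),
                    nlml_value=float(g.attrs["nlml"]),
                    converged=bool(g.attrs["converged"]),
                    n_iter=int(g.attrs["n_iter"]),
                )
            )
        return Emulator(
            input_mean=f["input_mean"][...],
            input_std=f["input_std"][...],
            basis=basis,
            components=components,
            mode=str(f.attrs["mode"]),
            training_meta=json.loads(f.attrs["training_meta"]),
            point_coords=(
                f["point_coords"][...] if "point_coords" in f else None
            ),
        )
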