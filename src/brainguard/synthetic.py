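"""Synthetic digital-brain forward model and dataset generator.

This module emulates the statistical design of a high-fidelity
finite-element data-generation campaign for implant-micromotion brain
strain, at desk scale: a hemispherical point cloud with a 5x5 probe array
implanted at its crown, material/micromotion sampling distributions
(brain modulus 9 kPa, probe modulus 16.5 kPa, both with coefficient of
variation 0.2; micromotion displacements Gaussian with zero mean and
100 um std per axis), an analytic probe--tissue strain surrogate in place
of the nonlinear finite-element solve, 900-sample / 80-20 split dataset
assembly, and SNR-controlled Gaussian noise injection with optional bias.

The forward model is a stand-in, not a mechanical solve: it produces
smooth strain fields concentrated around the probe tips, with a smooth
nonlinear dependence on the micromotion magnitude and a directional
modulation, which preserves the structure (low effective rank, smooth
parametric dependence, probe-localised gradients) that the emulator
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.stats import qmc

from .reduction import SnapshotDataset

__all__ = [
    "SceneConfig",
    "MaterialSample",
    "NoiseSpec",
    "sample_inputs",
    "forward_field",
    "generate_dataset",
    "inject_noise",
    "MODES",
]

MODES = ("predictor-respiration", "predictor-vascular", "monitor")

# population defaults (kPa / dimensionless / micrometres)
E_BRAIN_MEAN = 9.0
E_BRAIN_COV = 0.2
NU_BRAIN = 0.45
E_PROBE_MEAN = 16.5
E_PROBE_COV = 0.2
NU_PROBE = 0.49
E_TRUNC_KPA = 0.5
MICROMOTION_STD_UM = 100.0
# nominal micromotion amplitudes per physiological regime (um): respiration
# drives larger skull-brain excursions than vascular pulsation
RESP_AMP_MEAN_UM = 60.0
VASC_AMP_MEAN_UM = 20.0
REGIME_AMP_COV = 0.2
REGIME_DIRECTION = {
    "predictor-respiration": np.array([0.0, 0.0, -1.0]),
    "predictor-vascular": np.array([1.0, 0.0, 0.0]),
}


@dataclass(frozen=True)
class MaterialSample:
    """One sampled condition: tissue/probe elasticity plus micromotion."""

    e_brain_kpa: float
    nu_brain: float
    e_probe_kpa: float
    nu_probe: float
    displacement_um: np.ndarray  # 3-vector

    def __post_init__(self):
        if self.e_brain_kpa <= 0 or self.e_probe_kpa <= 0:
            raise ValueError("elastic moduli must be positive")
        if not (0 < self.nu_brain < 0.5 and 0 < self.nu_probe < 0.5):
            raise ValueError("Poisson ratios must lie in (0, 0.5)")
        u = np.asarray(self.displacement_um, dtype=float)
        if u.shape != (3,) or not np.all(np.isfinite(u)):
            raise ValueError("displacement must be a finite 3-vector")
        object.__setattr__(self, "displacement_um", u)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: SNR in dB plus an optional mean bias.

    ``bias_mean`` is expressed in normalized strain units (fractions of
    the dataset's mean absolute strain).
    """

    snr_db: float | None = None
    bias_mean: float = 0.0
    rng_seed: int = 0


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of the synthetic measurement scene.

    A hemispherical brain domain of radius ``hemisphere_radius_mm`` with a
    5x5 probe array implanted vertically at the crown (tips at depth
    ``tip_depth_mm``, lateral pitch ``probe_pitch_um``).  ``n_points``
    measurement points are placed deterministically given ``rng_seed``:
    a fraction clusters around the probe tips (mimicking adaptive mesh
    refinement at the implantation site), the rest fills the hemisphere
    with a scrambled low-discrepancy sequence.
    """

    n_points: int = 5000
    hemisphere_radius_mm: float = 80.0
    probe_pitch_um: float = 400.0
    tip_depth_mm: float = 2.0
    influence_radius_um: float = 300.0
    rng_seed: int = 0
    implant_fraction: float = 0.4
    near_field_fraction: float = 0.2

    def __post_init__(self):
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")
        if self.influence_radius_um <= 0:
            raise ValueError("influence radius must be positive")
        if self.tip_depth_mm >= self.hemisphere_radius_mm:
            raise ValueError("probe tips must lie inside the hemisphere")

    @cached_property
    def probe_positions_mm(self) -> np.ndarray:
        """(25, 3) probe-tip positions, grid centred on the crown."""
        pitch = self.probe_pitch_um / 1000.0
        offsets = (np.arange(5) - 2.0) * pitch
        gx, gy = np.meshgrid(offsets, offsets, indexing="ij")
        z = self.hemisphere_radius_mm - self.tip_depth_mm
        return np.column_stack([gx.ravel(), gy.ravel(), np.full(25, z)])

    @cached_property
    def point_coords_mm(self) -> np.ndarray:
        """(J, 3) measurement points (mm), deterministic given rng_seed."""
        rng = np.random.default_rng(self.rng_seed)
        rho = self.influence_radius_um / 1000.0
        n_implant = int(round(self.implant_fraction * self.n_points))
        n_near = int(round(self.near_field_fraction * self.n_points))
        n_far = self.n_points - n_implant - n_near
        probes = self.probe_positions_mm

        # dense cloud at the tissue-probe interface: Gaussian clusters of
        # width rho around each tip, probes visited round-robin
        which = np.arange(n_implant) % probes.shape[0]
        implant = probes[which] + rng.normal(0.0, rho, size=(n_implant, 3))

        # near field: uniform ball (radius 10*rho) around the array centre
        centre = probes.mean(axis=0)
        d = rng.normal(size=(n_near, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = 10.0 * rho * rng.random(n_near) ** (1.0 / 3.0)
        near = centre + d * r[:, None]

        # far field: scrambled Halton points mapped into the hemisphere
        halton = qmc.Halton(d=3, scramble=True, seed=self.rng_seed)
        u = halton.random(n_far)
        rad = self.hemisphere_radius_mm * u[:, 0] ** (1.0 / 3.0)
        cos_t = u[:, 1]  # z >= 0 half
        sin_t = np.sqrt(1.0 - cos_t**2)
        phi = 2.0 * np.pi * u[:, 2]
        far = np.column_stack([
            rad * sin_t * np.cos(phi),
            rad * sin_t * np.sin(phi),
            rad * cos_t,
        ])
        pts = np.vstack([implant, near, far])
        # clip any cluster stragglers back inside the domain hull
        norms = np.linalg.norm(pts, axis=1)
        outside = norms > self.hemisphere_radius_mm
        pts[outside] *= (self.hemisphere_radius_mm / norms[outside])[:, None]
        return pts

    @cached_property
    def _static_fields(self) -> tuple[np.ndarray, np.ndarray]:
        """Geometry-only factors of the forward model.

        Returns ``(F0, H)`` with ``F0_j = sum_i g_ij`` and
        ``H_j = sum_i g_ij (x_j - p_i) / (r_ij + rho/10)`` where
        ``g_ij = exp(-r_ij^2 / (2 rho^2))``.
        """
        rho = self.influence_radius_um / 1000.0
        X = self.point_coords_mm  # (J, 3)
        P = self.probe_positions_mm  # (25, 3)
        diff = X[:, None, :] - P[None, :, :]  # (J, 25, 3)
        r = np.linalg.norm(diff, axis=2)  # (J, 25)
        g = np.exp(-(r**2) / (2.0 * rho**2))
        F0 = g.sum(axis=1)
        H = np.einsum("ji,jik->jk", g / (r + rho / 10.0), diff)
        return F0, H

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "hemisphere_radius_mm": self.hemisphere_radius_mm,
            "probe_pitch_um": self.probe_pitch_um,
            "tip_depth_mm": self.tip_depth_mm,
            "influence_radius_um": self.influence_radius_um,
            "rng_seed": self.rng_seed,
            "implant_fraction": self.implant_fraction,
            "near_field_fraction": self.near_field_fraction,
        }


def _truncated_normal(rng, mean, std, lower, n):
    """Redraw-until-accepted truncated normal (vectorised)."""
    out = rng.normal(mean, std, size=n)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, std, size=int(bad.sum()))
        bad = out <= lower
    return out


def sample_inputs(mode: str, n: int, seed: int = 0):
    """Draw ``n`` input conditions for the given workflow mode.

    Returns ``(inputs, samples)``: an ``(I, n)`` input matrix plus the
    matching :class:`MaterialSample` list.

    * ``monitor``: inputs are 3-D probe displacements (um), i.i.d.
      Gaussian with zero mean and 100 um std per axis; materials fixed at
      the population means (the patient-specific "optimal choice").
    * ``predictor-respiration`` / ``predictor-vascular``: inputs are
      (E_brain, E_probe, micromotion amplitude); moduli are truncated
      normals with CoV 0.2, the amplitude a truncated normal at the
      regime's nominal level, applied along the regime's fixed direction.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    if mode == "monitor":
        U = rng.normal(0.0, MICROMOTION_STD_UM, size=(3, n))
        samples = [
            MaterialSample(
                e_brain_kpa=E_BRAIN_MEAN,
                nu_brain=NU_BRAIN,
                e_probe_kpa=E_PROBE_MEAN,
                nu_probe=NU_PROBE,
                displacement_um=U[:, j],
            )
            for j in range(n)
        ]
        return U.copy(), samples

    e_brain = _truncated_normal(
        rng, E_BRAIN_MEAN, E_BRAIN_COV * E_BRAIN_MEAN, E_TRUNC_KPA, n
    )
    e_probe = _truncated_normal(
        rng, E_PROBE_MEAN, E_PROBE_COV * E_PROBE_MEAN, E_TRUNC_KPA, n
    )
    amp_mean = (
        RESP_AMP_MEAN_UM if mode == "predictor-respiration" else VASC_AMP_MEAN_UM
    )
    amp = _truncated_normal(
        rng, amp_mean, REGIME_AMP_COV * amp_mean, 1.0, n
    )
    direction = REGIME_DIRECTION[mode]
    inputs = np.vstack([e_brain, e_probe, amp])
    samples = [
        MaterialSample(
            e_brain_kpa=e_brain[j],
            nu_brain=NU_BRAIN,
            e_probe_kpa=e_probe[j],
            nu_probe=NU_PROBE,
            displacement_um=amp[j] * direction,
        )
        for j in range(n)
    ]
    return inputs, samples


def forward_field(scene: SceneConfig, sample: MaterialSample) -> np.ndarray:
    """Analytic probe--tissue strain surrogate.

    s_j = sum_i A exp(-|x_j - p_i|^2 / (2 rho^2))
              * (1 + 0.3 (u_hat . (x_j - p_i)) / (|x_j - p_i| + rho/10))

    with amplitude A = E_probe/(E_probe + E_brain) * |u|/rho
    * (1 + 0.5 tanh(|u| / 200 um)), smooth and nonlinear in the
    micromotion magnitude |u|; the field vanishes identically at u = 0.
    """
    u_mm = sample.displacement_um / 1000.0
    u_norm = float(np.linalg.norm(u_mm))
    J = scene.n_points
    if u_norm == 0.0:
        return np.zeros(J)
    rho = scene.influence_radius_um / 1000.0
    stiffness = sample.e_probe_kpa / (sample.e_probe_kpa + sample.e_brain_kpa)
    A = stiffness * (u_norm / rho) * (1.0 + 0.5 * np.tanh(u_norm / 0.2))
    F0, H = scene._static_fields
    u_hat = u_mm / u_norm
    return A * (F0 + 0.3 * (H @ u_hat))


def generate_dataset(
    scene: SceneConfig,
    mode: str,
    n: int = 900,
    split: float = 0.8,
    seed: int = 0,
) -> tuple[SnapshotDataset, SnapshotDataset]:
    """Generate a (train, test) pair of snapshot datasets.

    ``n`` conditions are sampled, pushed through the forward model, and
    assigned to the train/test split by a seeded uniform shuffle with
    ``round(split * n)`` training columns.
    """
    if not (0.0 < split < 1.0):
        raise ValueError("split must lie in (0, 1)")
    n_train = int(round(split * n))
    n_test = n - n_train
    if min(n_train, n_test) < 2:
        raise ValueError("split leaves fewer than two samples on one side")

    ss = np.random.SeedSequence(seed)
    seed_inputs, seed_split = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    inputs, samples = sample_inputs(mode, n, seed=seed_inputs)
    outputs = np.empty((scene.n_points, n))
    for j, sample in enumerate(samples):
        outputs[:, j] = forward_field(scene, sample)

    perm = np.random.default_rng(seed_split).permutation(n)
    idx_train, idx_test = perm[:n_train], perm[n_train:]
    ids = np.array([f"s{j:04d}" for j in range(n)])
    meta = {
        "generator_seed": seed,
        "mode": mode,
        "n_total": n,
        "split": split,
        "scene": scene.to_dict(),
        "noise": None,
    }

    def _subset(idx, role):
        m = dict(meta, role=role)
        return SnapshotDataset(
            inputs=inputs[:, idx],
            outputs=outputs[:, idx],
            point_coords=scene.point_coords_mm,
            sample_ids=list(ids[idx]),
            meta=m,
        )

    return _subset(idx_train, "train"), _subset(idx_test, "test")


def inject_noise(dataset: SnapshotDataset, spec: NoiseSpec) -> SnapshotDataset:
    """Return a copy with additive Gaussian noise on the output fields.

    The noise variance is set from the signal power
    ``P = mean((outputs - per-point mean)^2)`` as
    ``sigma_n^2 = P / 10^(snr_db / 10)``; the bias term adds
    ``bias_mean * mean(|outputs|)`` uniformly (bias is specified in
    normalized strain units and scaled back to field units).
    """
    outputs = dataset.outputs
    if spec.snr_db is None and spec.bias_mean == 0.0:
        noisy = outputs.copy()
    else:
        noisy = outputs.copy()
        s_bar = float(np.mean(np.abs(outputs)))
        if spec.bias_mean != 0.0:
            noisy += spec.bias_mean * s_bar
        if spec.snr_db is not None:
            centred = outputs - outputs.mean(axis=1, keepdims=True)
            p_signal = float(np.mean(centred**2))
            sigma_n = np.sqrt(p_signal / 10.0 ** (spec.snr_db / 10.0))
            rng = np.random.default_rng(spec.rng_seed)
            noisy += rng.normal(0.0, sigma_n, size=outputs.shape)
    meta = dict(dataset.meta)
    meta["noise"] = {
        "snr_db": spec.snr_db,
        "bias_mean": spec.bias_mean,
        "rng_seed": spec.rng_seed,
    }
    return SnapshotDataset(
        inputs=dataset.inputs.copy(),
        outputs=noisy,
        point_coords=dataset.point_coords.copy(),
        sample_ids=list(dataset.sample_ids),
        meta=meta,
    )
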