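"""Digital DSC perfusion phantom with known ground truth.

Generates a synthetic 4D perfusion series that mimics a gadolinium
first-pass acquisition: healthy tissue follows a gamma-variate bolus
concentration curve converted to T2* signal loss, while an embedded lesion
receives a delayed, dispersed and/or decreased bolus passage.  Per-voxel
variation of healthy tissue is purely affine in signal space (gain and
offset), so in the noise-free limit every healthy voxel correlates perfectly
with every other — which is exactly the property temporal-similarity mapping
exploits.  Ground truth (lesion mask, per-voxel delay/dispersion/amplitude
fields, applied motion) is returned alongside the series so downstream
stages can be scored without patient data.

Defaults reproduce a typical stroke-protocol DSC acquisition: 80x80 matrix,
20 slices, 80 dynamics, TR = 1 s, TE = 24 ms, voxel 0.9375 x 0.9375 x 7 mm3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .errors import GeometryError, ParameterError
from .ingest import DynamicSeries, RigidTransform, apply_rigid

__all__ = [
    "BolusParams",
    "LesionModel",
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "gamma_variate_concentration",
    "concentration_to_signal",
    "generate_phantom",
    "save_spec",
    "load_spec",
]


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate bolus kinetics for one tissue class.

    The concentration curve is peak-normalised: with recirculation off the
    maximum value ``amplitude`` is reached at ``t0 + alpha * beta`` seconds.

    Attributes
    ----------
    s0 : baseline (pre-contrast) signal, a.u.
    t0 : bolus arrival time, s.
    alpha : gamma shape (dimensionless, > 0); larger = more symmetric peak.
    beta : gamma scale, s (> 0); larger = more dispersed (wider) bolus.
    amplitude : peak concentration, a.u. (>= 0).
    recirculation_fraction : relative size of a single recirculation pass
        (>= 0, < 1); 0 disables it.
    recirculation_delay : lag of the recirculation pass, s (> 0).
    """

    s0: float = 1000.0
    t0: float = 20.0
    alpha: float = 3.0
    beta: float = 1.5
    amplitude: float = 1.0
    recirculation_fraction: float = 0.12
    recirculation_delay: float = 20.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError(f"alpha and beta must be > 0 (got {self.alpha}, {self.beta})")
        if self.s0 <= 0:
            raise ParameterError(f"baseline signal s0 must be > 0 (got {self.s0})")
        if self.amplitude < 0:
            raise ParameterError(f"amplitude must be >= 0 (got {self.amplitude})")
        if not 0 <= self.recirculation_fraction < 1:
            raise ParameterError("recirculation_fraction must be in [0, 1)")
        if self.recirculation_delay <= 0:
            raise ParameterError("recirculation_delay must be > 0")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid region in voxel coordinates."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semiaxes
        if min(ax, ay, az) <= 0:
            raise GeometryError(f"ellipsoid semiaxes must be positive: {self.semiaxes}")
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class LesionModel:
    """How the lesion's bolus passage differs from healthy tissue.

    ``delay_shift`` (s) adds to the arrival time, ``dispersion_factor``
    (>= 1) multiplies the gamma scale beta, ``amplitude_factor`` ((0, 1])
    scales the peak concentration.  The identity model (0, 1, 1) produces
    curves identical to healthy tissue.  ``geometry`` is an
    :class:`Ellipsoid` or an explicit boolean voxel mask; ``None`` places a
    default ellipsoid in one hemisphere.
    """

    delay_shift: float = 5.0
    dispersion_factor: float = 2.0
    amplitude_factor: float = 0.7
    geometry: object = None

    def __post_init__(self):
        if self.delay_shift < 0:
            raise ParameterError("delay_shift must be >= 0")
        if self.dispersion_factor < 1:
            raise ParameterError("dispersion_factor must be >= 1")
        if not 0 < self.amplitude_factor <= 1:
            raise ParameterError("amplitude_factor must be in (0, 1]")

    def apply_to(self, bolus: BolusParams) -> BolusParams:
        return replace(bolus,
                       t0=bolus.t0 + self.delay_shift,
                       beta=bolus.beta * self.dispersion_factor,
                       amplitude=bolus.amplitude * self.amplitude_factor)


@dataclass
class PhantomSpec:
    """Full parameterisation of one synthetic DSC dataset.

    The same spec (including ``rng_seed``) always produces bit-identical
    output.  ``noise_sigma`` is expressed as a fraction of the healthy
    baseline signal ``bolus.s0``.  ``motion`` is an optional per-volume list
    of rigid transforms (length ``n_dynamics``); ``None`` means no motion.
    """

    shape: tuple[int, int, int] = (80, 80, 20)
    n_dynamics: int = 80
    tr: float = 1.0
    te: float = 24.0
    voxel_dims: tuple[float, float, float] = (0.9375, 0.9375, 7.0)
    bolus: BolusParams = field(default_factory=BolusParams)
    relaxivity: float = 0.02
    gain_range: tuple[float, float] = (0.85, 1.15)
    offset_range: tuple[float, float] = (-0.02, 0.02)  # fraction of s0
    lesion: LesionModel | None = field(default_factory=LesionModel)
    noise_model: str = "gaussian"
    noise_sigma: float = 0.02  # fraction of s0
    motion: list[RigidTransform] | None = None
    brain_region: Ellipsoid | None = None
    ventricle_region: Ellipsoid | None = None
    signal_loss_region: object = None  # Ellipsoid, boolean mask, or None
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_model not in ("gaussian", "rician"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ParameterError(f"grid shape must be 3D with all dims >= 4: {self.shape}")
        if self.n_dynamics < 2 or self.tr <= 0 or self.te <= 0:
            raise ParameterError("need n_dynamics >= 2, tr > 0, te > 0")
        if self.motion is not None and len(self.motion) != self.n_dynamics:
            raise ParameterError("motion schedule must have one transform per dynamic")


@dataclass
class GroundTruth:
    """Everything the phantom knows that a real scan would not tell you."""

    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    ventricle_mask: np.ndarray
    signal_loss_mask: np.ndarray
    delay_field: np.ndarray        # s per voxel
    dispersion_field: np.ndarray   # multiplicative, 1 = healthy
    amplitude_field: np.ndarray    # multiplicative, 1 = healthy
    motion: list[RigidTransform]
    healthy_curve: np.ndarray      # noise-free template signal, length n_dynamics
    lesion_curve: np.ndarray


def gamma_variate_concentration(t, p: BolusParams) -> np.ndarray:
    """Peak-normalised gamma-variate contrast concentration at times ``t`` (s).

    C(t) = A * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta) for
    t > t0 and 0 otherwise, plus an optional recirculation pass
    ``recirculation_fraction * C0(t - recirculation_delay)``.  With
    recirculation off, C peaks at exactly ``t0 + alpha*beta`` with value
    ``amplitude``.
    """
    t = np.asarray(t, dtype=float)
    c = _gamma_variate_base(t, p.t0, p.alpha, p.beta, p.amplitude)
    if p.recirculation_fraction > 0:
        c = c + p.recirculation_fraction * _gamma_variate_base(
            t, p.t0 + p.recirculation_delay, p.alpha, p.beta, p.amplitude)
    return c


def _gamma_variate_base(t, t0, alpha, beta, amplitude):
    c = np.zeros_like(t, dtype=float)
    m = t > t0
    x = (t[m] - t0) / (alpha * beta)
    c[m] = amplitude * x ** alpha * np.exp(alpha - (t[m] - t0) / beta)
    return c


def concentration_to_signal(concentration, s0: float, te: float, k: float = 0.02) -> np.ndarray:
    """Mono-exponential T2* susceptibility signal: S(t) = s0 * exp(-k*TE*C(t)).

    ``te`` in ms, ``k`` the effective relaxivity (a.u.).  Strictly decreasing
    in concentration; equals ``s0`` wherever the concentration is zero.
    """
    if s0 <= 0 or k <= 0 or te <= 0:
        raise ParameterError(f"s0, te, k must all be > 0 (got {s0}, {te}, {k})")
    return s0 * np.exp(-k * te * np.asarray(concentration, dtype=float))


def _region_mask(region, shape, name: str) -> np.ndarray:
    if region is None:
        return np.zeros(shape, dtype=bool)
    if isinstance(region, Ellipsoid):
        m = region.mask(shape)
        if not m.any():
            raise GeometryError(f"{name} ellipsoid lies entirely outside the grid")
        return m
    m = np.asarray(region, dtype=bool)
    if m.shape != tuple(shape):
        raise GeometryError(f"{name} mask shape {m.shape} does not match grid {tuple(shape)}")
    return m


def _default_brain(shape) -> Ellipsoid:
    nx, ny, nz = shape
    return Ellipsoid(center=((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2),
                     semiaxes=(0.42 * nx, 0.42 * ny, 0.48 * nz))


def _default_ventricles(shape) -> Ellipsoid:
    nx, ny, nz = shape
    return Ellipsoid(center=((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2),
                     semiaxes=(max(2.0, 0.06 * nx), max(2.0, 0.12 * ny), max(1.5, 0.15 * nz)))


def _default_lesion(shape) -> Ellipsoid:
    nx, ny, nz = shape
    return Ellipsoid(center=(0.70 * nx, 0.45 * ny, 0.5 * (nz - 1)),
                     semiaxes=(max(2.0, 0.125 * nx), max(2.0, 0.125 * ny), max(1.5, 0.2 * nz)))


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, GroundTruth]:
    """Generate a synthetic DSC series and its ground truth.

    Healthy brain voxels receive per-voxel affine (gain/offset) copies of the
    healthy template signal curve; lesion voxels the same treatment of the
    lesion template; ventricles a flat low-amplitude profile; signal-loss
    voxels near-zero signal; background is empty.  Noise and per-volume
    rigid motion are applied last.  Deterministic in ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape)
    nt = spec.n_dynamics
    t = np.arange(nt) * spec.tr
    s0 = spec.bolus.s0

    brain = _region_mask(spec.brain_region or _default_brain(shape), shape, "brain")
    ventricle = _region_mask(spec.ventricle_region or _default_ventricles(shape),
                             shape, "ventricle") & brain
    signal_loss = _region_mask(spec.signal_loss_region, shape, "signal-loss") & brain

    if spec.lesion is not None:
        geometry = spec.lesion.geometry if spec.lesion.geometry is not None \
            else _default_lesion(shape)
        lesion = _region_mask(geometry, shape, "lesion")
        if not (lesion <= brain).all():
            lesion = lesion & brain
        if not lesion.any():
            raise GeometryError("lesion geometry does not intersect the brain region")
        lesion = lesion & ~ventricle & ~signal_loss
        lesion_bolus = spec.lesion.apply_to(spec.bolus)
    else:
        lesion = np.zeros(shape, dtype=bool)
        lesion_bolus = spec.bolus

    healthy_curve = concentration_to_signal(
        gamma_variate_concentration(t, spec.bolus), s0, spec.te, spec.relaxivity)
    lesion_curve = concentration_to_signal(
        gamma_variate_concentration(t, lesion_bolus), s0, spec.te, spec.relaxivity)

    gain = rng.uniform(*spec.gain_range, size=shape)
    offset = rng.uniform(*spec.offset_range, size=shape) * s0

    data = np.zeros(shape + (nt,), dtype=np.float64)
    healthy = brain & ~lesion & ~ventricle & ~signal_loss
    data[healthy] = gain[healthy, None] * healthy_curve + offset[healthy, None]
    data[lesion] = gain[lesion, None] * lesion_curve + offset[lesion, None]
    data[ventricle] = 0.6 * s0  # flat, low-contrast CSF-like profile
    data[signal_loss] = 0.02 * s0  # susceptibility dropout

    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * s0
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, sigma, size=data.shape)
        else:  # rician: magnitude of a complex signal with iid gaussian channels
            data = np.hypot(data + rng.normal(0.0, sigma, size=data.shape),
                            rng.normal(0.0, sigma, size=data.shape))
    np.clip(data, 0.0, None, out=data)

    motion = spec.motion if spec.motion is not None else [RigidTransform()] * nt
    if spec.motion is not None:
        for i, tf in enumerate(motion):
            if not tf.is_identity():
                data[..., i] = np.clip(apply_rigid(data[..., i], tf), 0.0, None)

    delay_field = np.zeros(shape)
    dispersion_field = np.ones(shape)
    amplitude_field = np.ones(shape)
    if spec.lesion is not None:
        delay_field[lesion] = spec.lesion.delay_shift
        dispersion_field[lesion] = spec.lesion.dispersion_factor
        amplitude_field[lesion] = spec.lesion.amplitude_factor

    series = DynamicSeries(data=data, tr=spec.tr, te=spec.te, voxel_dims=spec.voxel_dims)
    gt = GroundTruth(brain_mask=brain, lesion_mask=lesion, ventricle_mask=ventricle,
                     signal_loss_mask=signal_loss, delay_field=delay_field,
                     dispersion_field=dispersion_field, amplitude_field=amplitude_field,
                     motion=list(motion), healthy_curve=healthy_curve,
                     lesion_curve=lesion_curve)
    return series, gt


# --------------------------------------------------------------------------
# Spec round-trip through a plain-text YAML config
#
# Schema: top-level keys mirror PhantomSpec fields; `bolus` and `lesion` are
# nested mappings of their dataclass fields; regions are mappings
# {center: [x,y,z], semiaxes: [a,b,c]}; `motion` is a list of
# {rotations_deg: [...], translation_vox: [...]}; `lesion: null` disables the
# lesion.  Explicit boolean-mask regions are not serialisable (use
# ellipsoids in configs).


def save_spec(spec: PhantomSpec, path) -> None:
    """Write a PhantomSpec to a YAML config file (documented schema above)."""
    d = {
        "shape": list(spec.shape),
        "n_dynamics": spec.n_dynamics,
        "tr": spec.tr,
        "te": spec.te,
        "voxel_dims": list(spec.voxel_dims),
        "bolus": asdict(spec.bolus),
        "relaxivity": spec.relaxivity,
        "gain_range": list(spec.gain_range),
        "offset_range": list(spec.offset_range),
        "lesion": _lesion_to_dict(spec.lesion),
        "noise_model": spec.noise_model,
        "noise_sigma": spec.noise_sigma,
        "motion": None if spec.motion is None else [
            {"rotations_deg": list(tf.rotations_deg),
             "translation_vox": list(tf.translation_vox)} for tf in spec.motion],
        "brain_region": _ellipsoid_to_dict(spec.brain_region),
        "ventricle_region": _ellipsoid_to_dict(spec.ventricle_region),
        "signal_loss_region": _ellipsoid_to_dict(spec.signal_loss_region),
        "rng_seed": spec.rng_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_spec(path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PhantomSpec(
        shape=tuple(d["shape"]),
        n_dynamics=int(d["n_dynamics"]),
        tr=float(d["tr"]),
        te=float(d["te"]),
        voxel_dims=tuple(d["voxel_dims"]),
        bolus=BolusParams(**d["bolus"]),
        relaxivity=float(d["relaxivity"]),
        gain_range=tuple(d["gain_range"]),
        offset_range=tuple(d["offset_range"]),
        lesion=_lesion_from_dict(d["lesion"]),
        noise_model=d["noise_model"],
        noise_sigma=float(d["noise_sigma"]),
        motion=None if d["motion"] is None else [
            RigidTransform(tuple(m["rotations_deg"]), tuple(m["translation_vox"]))
            for m in d["motion"]],
        brain_region=_ellipsoid_from_dict(d["brain_region"]),
        ventricle_region=_ellipsoid_from_dict(d["ventricle_region"]),
        signal_loss_region=_ellipsoid_from_dict(d["signal_loss_region"]),
        rng_seed=int(d["rng_seed"]),
    )


def _ellipsoid_to_dict(region):
    if region is None:
        return None
    if not isinstance(region, Ellipsoid):
        raise ParameterError("only ellipsoid regions can be written to a config file")
    return {"center": list(region.center), "semiaxes": list(region.semiaxes)}


def _ellipsoid_from_dict(d):
    if d is None:
        return None
    return Ellipsoid(center=tuple(d["center"]), semiaxes=tuple(d["semiaxes"]))


def _lesion_to_dict(lesion: LesionModel | None):
    if lesion is None:
        return None
    return {"delay_shift": lesion.delay_shift,
            "dispersion_factor": lesion.dispersion_factor,
            "amplitude_factor": lesion.amplitude_factor,
            "geometry": _ellipsoid_to_dict(lesion.geometry)}


def _lesion_from_dict(d) -> LesionModel | None:
    if d is None:
        return None
    return LesionModel(delay_shift=float(d["delay_shift"]),
                       dispersion_factor=float(d["dispersion_factor"]),
                       amplitude_factor=float(d["amplitude_factor"]),
                       geometry=_ellipsoid_from_dict(d["geometry"]))
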