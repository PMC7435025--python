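"""Synthetic exercise-stimulated DCE-MRI studies.

Real calf DCE-MRI of this kind is acquired after plantar-flexion
exercise: the contrast bolus arrives while the muscle is hyperemic, so
voxel perfusion spans almost two orders of magnitude within one slice,
and harder exercise both raises perfusion and — through increased
cardiac output — *shrinks* the first-pass area of the arterial input
function.  The generator emulates exactly those features:

* gamma-variate first-pass AIF with an exponential recirculation tail,
  whose first-pass area scales as ``1/cardiac_output_factor``;
* per-voxel tissue curves from the adiabatic tissue-homogeneity forward
  model plus additive Gaussian concentration noise at a chosen SNR;
* cohorts of studies whose pooled true-perfusion distributions are
  calibrated to the two training groups of the human study this mirrors:
  a "diverse" group (mixed subject types and exercise loads, pooled
  mean/median ≈ 107/81 ml·min⁻¹·100g⁻¹, heavy right tail) and a
  "homogeneous" group (one subject type, one load, ≈ 92/63, thin tail).

Three cohort presets ship with the package (``diverse``, ``homogeneous``,
``testing``); every study is bit-reproducible from its (preset, seed).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .kinetics import Curve, IRFParams, forward_model, irf_samples, convolution_matrix

__all__ = [
    "AIFSpec",
    "CohortSpec",
    "SimulatedStudy",
    "generate_aif",
    "generate_voxel_tc",
    "generate_cohort",
    "sample_voxel_params",
    "load_preset",
    "region_label_map",
    "PIPELINE_QUADRATURE",
]

#: quadrature used consistently by the simulator and the fitting pipeline
PIPELINE_QUADRATURE = "integrated"

DEFAULT_NUISANCE_RANGES = {
    "t0": (1.5, 6.5),
    "minTT": (3.0, 10.0),
    "E": (0.2, 0.6),
    "k": (0.05, 0.3),
}


@dataclass(frozen=True)
class AIFSpec:
    """Parameters of one simulated arterial input function.

    The first pass is the gamma variate
    ``A_eff * ((t-ta)/(alpha*beta))**alpha * exp(alpha - (t-ta)/beta)``
    (peak ``A_eff`` at ``t = ta + alpha*beta``), with
    ``A_eff = peak_amplitude / cardiac_output_factor`` so that the
    first-pass area scales inversely with exercise-driven cardiac
    output.  A recirculation tail (first pass convolved with an
    exponential of time constant ``recirc_tau``) is added, scaled by
    ``recirculation_fraction``.
    """

    peak_amplitude: float = 6.0
    arrival_time: float = 3.0
    shape_alpha: float = 3.0
    shape_beta: float = 1.5
    recirculation_fraction: float = 0.15
    cardiac_output_factor: float = 1.0
    recirc_tau: float = 10.0

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0")
        if self.arrival_time < 0:
            raise ValueError("arrival_time must be >= 0")
        if self.shape_alpha <= 0 or self.shape_beta <= 0:
            raise ValueError("gamma-variate shape parameters must be > 0")
        if not 0.0 <= self.recirculation_fraction < 1.0:
            raise ValueError("recirculation_fraction must be in [0, 1)")
        if self.cardiac_output_factor <= 0:
            raise ValueError("cardiac_output_factor must be > 0")
        if self.recirc_tau <= 0:
            raise ValueError("recirc_tau must be > 0")


def generate_aif(spec: AIFSpec, n: int = 40, dt: float = 1.0, rng=None) -> Curve:
    """Simulate an AIF on ``n`` frames at interval ``dt`` (deterministic).

    ``rng`` is accepted for interface symmetry with the other generators
    but unused: AIF variability is expressed through :class:`AIFSpec`.
    """
    t = np.arange(n) * dt
    a_eff = spec.peak_amplitude / spec.cardiac_output_factor
    x = t - spec.arrival_time
    scale = spec.shape_alpha * spec.shape_beta
    with np.errstate(invalid="ignore"):
        fp = np.where(
            x > 0,
            a_eff * (np.maximum(x, 0.0) / scale) ** spec.shape_alpha
            * np.exp(spec.shape_alpha - np.maximum(x, 0.0) / spec.shape_beta),
            0.0,
        )
    tail = np.zeros(n)
    if spec.recirculation_fraction > 0:
        kernel = np.exp(-t / spec.recirc_tau) / spec.recirc_tau
        tail = spec.recirculation_fraction * np.convolve(fp, kernel)[:n] * dt
    return Curve(values=fp + tail, dt=dt)


def first_pass_area(spec: AIFSpec, dt: float = 0.01, horizon: float = 120.0) -> float:
    """Numerically integrated area under the first pass (no recirculation)."""
    bare = dataclasses.replace(spec, recirculation_fraction=0.0)
    n = int(horizon / dt)
    return float(np.trapezoid(generate_aif(bare, n=n, dt=dt).values, dx=dt))


def generate_voxel_tc(params: IRFParams, aif: Curve, snr: float = np.inf,
                      rng=None, quadrature: str = PIPELINE_QUADRATURE) -> Curve:
    """Tissue curve for one voxel: forward model plus Gaussian noise.

    Noise standard deviation is ``max(clean)/snr``; ``snr=inf`` returns
    the noiseless model curve.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0 (np.inf for noiseless)")
    clean = forward_model(params, aif, quadrature=quadrature).values
    if np.isinf(snr):
        return Curve(values=clean, dt=aif.dt)
    rng = np.random.default_rng(rng)
    sigma = float(np.max(clean)) / snr
    return Curve(values=clean + rng.normal(0.0, sigma, clean.shape), dt=aif.dt)


def sample_voxel_params(n: int, rng, f_range=(20.0, 380.0),
                        nuisance_ranges=None) -> np.ndarray:
    """Draw ``n`` voxel parameter rows (F, t0, minTT, E, k).

    F is uniform over ``f_range``; the nuisance parameters are uniform
    over physiology-bracketing ranges (arrival 1.5–6.5 s, transit
    3–10 s, extraction 0.2–0.6, excretion 0.05–0.3 s⁻¹ by default).
    """
    rng = np.random.default_rng(rng)
    nr = {**DEFAULT_NUISANCE_RANGES, **(nuisance_ranges or {})}
    cols = [
        rng.uniform(*f_range, n),
        rng.uniform(*nr["t0"], n),
        rng.uniform(*nr["minTT"], n),
        rng.uniform(*nr["E"], n),
        rng.uniform(*nr["k"], n),
    ]
    return np.column_stack(cols)


# ----------------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Recipe for a cohort of simulated studies.

    Each entry of ``datasets`` is a dict with keys ``subject``, ``load``,
    ``subject_factor`` and ``load_factor``; the product of the two
    factors scales the per-region median perfusion of that study, and
    the load factor also drives cardiac output (hence AIF first-pass
    area) up with exercise intensity.
    """

    name: str
    datasets: list
    rng_seed: int = 0
    map_shape: tuple = (64, 64)
    voxels_per_dataset: int = 2000
    snr: float = 20.0
    region_base_medians: tuple = (45.0, 75.0, 120.0)
    sigma_log: float = 0.75
    dataset_jitter: float = 0.12
    f_clip: tuple = (3.0, 420.0)
    nuisance_ranges: dict = field(default_factory=lambda: dict(DEFAULT_NUISANCE_RANGES))
    aif: dict = field(default_factory=lambda: {
        "peak_base": 6.0,
        "arrival": (2.0, 4.0),
        "alpha": (2.5, 4.0),
        "beta": (1.2, 2.2),
        "recirculation_fraction": 0.15,
        "recirc_tau": 10.0,
    })
    n_frames: int = 40
    dt: float = 1.0

    def __post_init__(self) -> None:
        if len(self.datasets) < 1:
            raise ValueError("a cohort needs at least one dataset")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if self.voxels_per_dataset < 1:
            raise ValueError("voxels_per_dataset must be >= 1")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if not all(m > 0 for m in self.region_base_medians):
            raise ValueError("region medians must be > 0")

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("map_shape", "region_base_medians", "f_clip"):
            if key in d:
                d[key] = tuple(d[key])
        if "nuisance_ranges" in d:
            d["nuisance_ranges"] = {k: tuple(v) for k, v in d["nuisance_ranges"].items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["map_shape"] = list(self.map_shape)
        return d


def load_preset(name: str, **overrides) -> CohortSpec:
    """Load a bundled cohort preset (``diverse``, ``homogeneous``, ``testing``).

    Keyword overrides replace preset fields, e.g.
    ``load_preset('diverse', rng_seed=7, voxels_per_dataset=500)``.
    """
    ref = resources.files("muscleperf.presets").joinpath(f"{name}.json")
    try:
        d = json.loads(ref.read_text())
    except FileNotFoundError as exc:
        raise ValueError(f"unknown cohort preset {name!r}") from exc
    d.update(overrides)
    return CohortSpec.from_dict(d)


def region_label_map(shape) -> np.ndarray:
    """Elliptical three-region layout standing in for a calf cross-section.

    Two posterior ellipses and one anterior ellipse, labelled 0..2;
    -1 outside.  Synthetic geometry: it exercises map I/O and regional
    perfusion contrast, it does not match anatomy.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = (yy + 0.5) / h, (xx + 0.5) / w
    ellipses = [
        (0.35, 0.30, 0.30, 0.24),
        (0.35, 0.70, 0.30, 0.24),
        (0.72, 0.50, 0.22, 0.32),
    ]
    labels = np.full(shape, -1, dtype=np.int32)
    for r, (cy, cx, ay, ax) in enumerate(ellipses):
        inside = ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
        labels[(labels == -1) & inside] = r
    return labels


@dataclass
class SimulatedStudy:
    """One synthetic DCE-MRI study with full ground truth."""

    cohort: str
    study_id: int
    seed: int
    aif: Curve
    tc: np.ndarray                  # (H, W, T) concentration, mM
    mask: np.ndarray                # (H, W) bool
    region_map: np.ndarray          # (H, W) int, -1 outside mask
    truth: dict                     # param name -> (H, W) map, NaN outside
    metadata: dict

    @property
    def masked_tc(self) -> np.ndarray:
        """Tissue curves of masked voxels, (n_voxels, T), row-major order."""
        return self.tc[self.mask]

    @property
    def truth_perfusion(self) -> np.ndarray:
        """True F of masked voxels, row-major order."""
        return self.truth["F"][self.mask]


def _study_rng(cohort_name: str, cohort_seed: int, study_id: int) -> np.random.Generator:
    # include the cohort name so cohorts sharing a seed stay decorrelated
    name_key = zlib.crc32(cohort_name.encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(name_key), int(cohort_seed), int(study_id)])
    )


def _build_mask(spec: CohortSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    labels = region_label_map(spec.map_shape)
    available = int((labels >= 0).sum())
    target = spec.voxels_per_dataset
    if target > available:
        raise ValueError(
            f"voxels_per_dataset={target} exceeds the {available} voxels of the "
            f"elliptical layout on a {spec.map_shape} map"
        )
    # subsample each region proportionally so all three survive
    flat = labels.ravel()
    keep = np.zeros(flat.size, dtype=bool)
    region_idx = [np.flatnonzero(flat == r) for r in range(3)]
    quotas = [int(round(target * len(ix) / available)) for ix in region_idx]
    while sum(quotas) != target:  # rounding drift
        quotas[int(np.argmax(quotas))] += int(np.sign(target - sum(quotas)))
    for ix, q in zip(region_idx, quotas):
        keep[rng.choice(ix, size=q, replace=False)] = True
    mask = keep.reshape(spec.map_shape)
    labels = np.where(mask, labels, -1)
    return mask, labels


def generate_study(spec: CohortSpec, study_id: int) -> SimulatedStudy:
    """Generate one study of a cohort, reproducible from (spec, study_id)."""
    entry = spec.datasets[study_id]
    rng = _study_rng(spec.name, spec.rng_seed, study_id)
    mask, labels = _build_mask(spec, rng)

    scale = entry["load_factor"] * entry["subject_factor"]
    scale *= float(np.exp(rng.normal(0.0, spec.dataset_jitter)))

    a = spec.aif
    aif_spec = AIFSpec(
        peak_amplitude=a["peak_base"],
        arrival_time=float(rng.uniform(*a["arrival"])),
        shape_alpha=float(rng.uniform(*a["alpha"])),
        shape_beta=float(rng.uniform(*a["beta"])),
        recirculation_fraction=a["recirculation_fraction"],
        # cardiac output rises roughly in proportion to exercise intensity,
        # spanning ~2.5-3x from light load to exhaustion
        cardiac_output_factor=entry["load_factor"],
        recirc_tau=a["recirc_tau"],
    )
    aif = generate_aif(aif_spec, n=spec.n_frames, dt=spec.dt)

    n_vox = int(mask.sum())
    region_of_voxel = labels[mask]
    medians = np.asarray(spec.region_base_medians)[region_of_voxel] * scale
    F = np.clip(
        np.exp(np.log(medians) + rng.normal(0.0, spec.sigma_log, n_vox)),
        *spec.f_clip,
    )
    nr = spec.nuisance_ranges
    params = np.column_stack([
        F,
        rng.uniform(*nr["t0"], n_vox),
        rng.uniform(*nr["minTT"], n_vox),
        rng.uniform(*nr["E"], n_vox),
        rng.uniform(*nr["k"], n_vox),
    ])

    # batched forward model: IRF samples per voxel @ AIF convolution matrix
    lags = np.arange(spec.n_frames) * spec.dt
    irf = irf_samples(
        (params[:, 0], params[:, 1], params[:, 2], params[:, 3], params[:, 4]),
        lags, spec.dt, PIPELINE_QUADRATURE,
    )
    clean = irf @ convolution_matrix(aif, quadrature=PIPELINE_QUADRATURE).T
    if np.isfinite(spec.snr):
        sigma = clean.max(axis=1, keepdims=True) / spec.snr
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * sigma
    else:
        noisy = clean

    h, w = spec.map_shape
    tc = np.zeros((h, w, spec.n_frames))
    tc[mask] = noisy
    truth = {}
    for p, name in enumerate(("F", "t0", "minTT", "E", "k")):
        m = np.full((h, w), np.nan)
        m[mask] = params[:, p]
        truth[name] = m

    return SimulatedStudy(
        cohort=spec.name,
        study_id=study_id,
        seed=int(spec.rng_seed),
        aif=aif,
        tc=tc,
        mask=mask,
        region_map=labels,
        truth=truth,
        metadata={
            "subject": entry.get("subject", "unknown"),
            "load": entry.get("load", "unknown"),
            "scale": scale,
            "snr": spec.snr,
            "aif_spec": dataclasses.asdict(aif_spec),
        },
    )


def generate_cohort(spec: CohortSpec) -> list[SimulatedStudy]:
    """Generate every study of a cohort; exactly reproducible from the spec."""
    return [generate_study(spec, i) for i in range(spec.n_datasets)]
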