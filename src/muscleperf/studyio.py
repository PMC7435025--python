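"""File-format adapters: NIfTI series and maps, AIF CSV, study manifests.

A *study directory* bundles everything one perfusion mapping needs:

========================  ====================================================
``dynamic.nii.gz``        (H, W, T) dynamic signal series (float)
``proton_density.nii.gz`` (H, W) proton-density image from the long-TR scan
``mask.nii.gz``           (H, W) integer ROI mask (nonzero = muscle)
``aif.csv``               two columns ``time_s, concentration_mM`` with header
``manifest.json``         acquisition parameters, provenance, seeds
``truth_*.nii.gz``        optional ground-truth parameter maps (simulated data)
========================  ====================================================

Signals are stored (not concentrations): loading converts voxel signals
to tracer concentration with the proton-density image and the
saturation-recovery model, so the full conversion pipeline is exercised
on every import.  The AIF CSV already holds concentration — arterial
conversion happens upstream when the artery is sampled.

Only the first 40 frames are used; longer series are truncated with a
logged warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import AcquisitionParams, Curve, concentration_to_signal, signal_to_concentration
from .simulate import SimulatedStudy

__all__ = ["StudyData", "load_study", "export_study", "save_map", "load_map",
           "N_FRAMES_USED", "DEFAULT_PROTON_DENSITY"]

logger = logging.getLogger("muscleperf")

N_FRAMES_USED = 40
#: arbitrary but fixed proton-density level written for simulated studies
DEFAULT_PROTON_DENSITY = 1000.0


@dataclass
class StudyData:
    """An in-memory study: concentration curves, mask, acquisition, truth."""

    tc: np.ndarray                # (H, W, T) concentration, mM
    mask: np.ndarray              # (H, W) bool
    aif: Curve
    acquisition: AcquisitionParams
    manifest: dict
    truth: dict | None = None     # param name -> (H, W) map, if shipped

    @property
    def masked_tc(self) -> np.ndarray:
        return self.tc[self.mask]


def _nifti(arr: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr), affine=np.eye(4))


def save_map(arr: np.ndarray, path) -> None:
    """Write a float32 parameter map as NIfTI (NaN outside the mask)."""
    nib.save(_nifti(np.asarray(arr, dtype=np.float32)), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def export_study(study: SimulatedStudy, directory,
                 acq: AcquisitionParams | None = None,
                 proton_density: float = DEFAULT_PROTON_DENSITY) -> Path:
    """Write a :class:`~muscleperf.simulate.SimulatedStudy` as a study directory.

    The dynamic series is stored as *signal* via the saturation-recovery
    forward conversion, so re-importing runs the inverse conversion;
    round-trip agreement is limited only by float64 storage.
    """
    acq = acq or AcquisitionParams()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    signal = concentration_to_signal(np.clip(study.tc, 0.0, None), proton_density, acq)
    nib.save(_nifti(signal.astype(np.float64)), str(directory / "dynamic.nii.gz"))
    pd_img = np.full(study.mask.shape, float(proton_density))
    nib.save(_nifti(pd_img), str(directory / "proton_density.nii.gz"))
    nib.save(_nifti(study.mask.astype(np.uint8)), str(directory / "mask.nii.gz"))
    for name, m in study.truth.items():
        save_map(m, directory / f"truth_{name}.nii.gz")

    pd.DataFrame({
        "time_s": study.aif.times,
        "concentration_mM": study.aif.values,
    }).to_csv(directory / "aif.csv", index=False)

    manifest = {
        "format": "muscleperf-study",
        "version": 1,
        "cohort": study.cohort,
        "study_id": int(study.study_id),
        "seed": int(study.seed),
        "n_frames": int(study.tc.shape[2]),
        "dt": float(study.aif.dt),
        "proton_density": float(proton_density),
        "acquisition": dataclasses.asdict(acq),
        "metadata": study.metadata,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_study(directory) -> StudyData:
    """Load a study directory and convert voxel signals to concentration.

    Raises ``FileNotFoundError`` for missing files, ``ValueError`` for
    shape mismatches, and :class:`~muscleperf.kinetics.SaturationError`
    for signals at or above the proton-density ceiling.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    acq = AcquisitionParams(**manifest.get("acquisition", {}))

    signal = np.asarray(nib.load(str(directory / "dynamic.nii.gz")).get_fdata())
    pd_img = np.asarray(nib.load(str(directory / "proton_density.nii.gz")).get_fdata())
    mask = np.asarray(nib.load(str(directory / "mask.nii.gz")).get_fdata()) > 0

    if signal.ndim != 3:
        raise ValueError("dynamic series must be 3-D (H, W, T)")
    if mask.shape != signal.shape[:2] or pd_img.shape != signal.shape[:2]:
        raise ValueError("mask / proton-density shape does not match the series")
    if signal.shape[2] < N_FRAMES_USED:
        raise ValueError(
            f"dynamic series has {signal.shape[2]} frames; {N_FRAMES_USED} required"
        )
    if signal.shape[2] > N_FRAMES_USED:
        logger.warning(
            "dynamic series has %d frames; using the first %d",
            signal.shape[2], N_FRAMES_USED,
        )
        signal = signal[:, :, :N_FRAMES_USED]

    tc = np.zeros_like(signal)
    if mask.any():
        tc[mask] = signal_to_concentration(signal[mask], pd_img[mask][:, None], acq)
    else:
        logger.warning("mask excludes every voxel in %s", directory)

    aif_df = pd.read_csv(directory / "aif.csv")
    if not {"time_s", "concentration_mM"} <= set(aif_df.columns):
        raise ValueError("aif.csv must have columns time_s, concentration_mM")
    aif_vals = aif_df["concentration_mM"].to_numpy(dtype=float)[:N_FRAMES_USED]
    t = aif_df["time_s"].to_numpy(dtype=float)
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    aif = Curve(values=aif_vals, dt=dt)
    if aif.n != N_FRAMES_USED:
        raise ValueError(f"AIF must provide at least {N_FRAMES_USED} samples")

    truth = {}
    for p in directory.glob("truth_*.nii.gz"):
        truth[p.name[len("truth_"):-len(".nii.gz")]] = load_map(p)

    return StudyData(
        tc=tc, mask=mask, aif=aif, acquisition=acq,
        manifest=manifest, truth=truth or None,
    )
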