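"""End-to-end benchmark of the perfusion-mapping training strategies.

Runs the full synthetic experiment that the package exists to support:

1. generate a *diverse* and a *homogeneous* training cohort plus a
   held-out *testing* cohort (diverse-like composition);
2. produce reference labels by multigrid model fitting (and, for one
   strategy, the less reliable regular-fit labels);
3. train three classifier networks — diverse/multigrid labels,
   homogeneous/multigrid labels, diverse/regular labels;
4. evaluate every method (regular fit and the three networks) against
   the multigrid fit of the testing cohort, with summary statistics,
   paired t tests, binned error profiles, and the network-vs-multigrid
   wall-clock speedup.

The same driver backs the ``muscleperf compare`` subcommand and the
repository's acceptance script.
"""

from __future__ import annotations

import time

import numpy as np

from .fitting import ATHVoxelFitter
from .metrics import compare_all
from .network import PerfusionNetwork, assemble_training_set, build_feature_matrix
from .simulate import generate_cohort, load_preset

__all__ = ["run_benchmark", "fit_cohort", "label_maps_from_flat"]


def fit_cohort(studies, mode: str) -> list[np.ndarray]:
    """Fit every study of a cohort; returns per-study flat F arrays."""
    out = []
    for study in studies:
        fitter = ATHVoxelFitter(mode=mode)
        fitter.fit(study.masked_tc, study.aif)
        out.append(fitter.perfusion_)
    return out


def label_maps_from_flat(studies, flat_values) -> list[np.ndarray]:
    """Scatter per-voxel label vectors back into (H, W) maps (NaN outside)."""
    maps = []
    for study, vals in zip(studies, flat_values):
        m = np.full(study.mask.shape, np.nan)
        m[study.mask] = vals
        maps.append(m)
    return maps


def _summary_rows(table) -> dict:
    cols = ["n_voxels", "mean", "sd", "median", "mean_error", "rmse", "mae", "pearson_r"]
    return {
        row["method"]: {c: (int(row[c]) if c == "n_voxels" else float(row[c])) for c in cols}
        for _, row in table.iterrows()
    }


def run_benchmark(seed: int = 0, train_voxels: int = 600, test_voxels: int = 400,
                  include_profiles: bool = False) -> dict:
    """Run the full training-strategy comparison at the given problem size.

    ``train_voxels`` / ``test_voxels`` are voxels per dataset (20 training
    and 8 testing datasets), so the defaults give 12,000 training voxels
    per cohort and 3,200 testing voxels.
    """
    ss = np.random.SeedSequence(int(seed))
    nn_seeds = [int(s) for s in ss.generate_state(3) % (2 ** 31)]

    diverse = generate_cohort(load_preset("diverse", rng_seed=seed,
                                          voxels_per_dataset=train_voxels))
    homogeneous = generate_cohort(load_preset("homogeneous", rng_seed=seed,
                                              voxels_per_dataset=train_voxels))
    testing = generate_cohort(load_preset("testing", rng_seed=seed,
                                          voxels_per_dataset=test_voxels))

    # reference labels
    div_mg = fit_cohort(diverse, "multigrid")
    div_rg = fit_cohort(diverse, "regular")
    hom_mg = fit_cohort(homogeneous, "multigrid")

    ts_n1 = assemble_training_set(diverse, label_maps_from_flat(diverse, div_mg),
                                  label_source="multigrid")
    ts_n2 = assemble_training_set(homogeneous, label_maps_from_flat(homogeneous, hom_mg),
                                  label_source="multigrid")
    ts_n4 = assemble_training_set(diverse, label_maps_from_flat(diverse, div_rg),
                                  label_source="regular")

    nets = {}
    for name, ts, s in [("nn_diverse", ts_n1, nn_seeds[0]),
                        ("nn_homogeneous", ts_n2, nn_seeds[1]),
                        ("nn_regular_labels", ts_n4, nn_seeds[2])]:
        nets[name] = PerfusionNetwork(random_state=s).fit(ts.features, ts.labels)

    # testing cohort: multigrid reference (timed), regular fit, NN inference (timed)
    t0 = time.perf_counter()
    test_mg = fit_cohort(testing, "multigrid")
    t_multigrid = time.perf_counter() - t0
    test_rg = fit_cohort(testing, "regular")

    ref = np.concatenate(test_mg)
    estimates = {"regular": np.concatenate(test_rg)}
    t_nn = {}
    for name, net in nets.items():
        t0 = time.perf_counter()
        preds = [net.predict_perfusion(build_feature_matrix(s.masked_tc, s.aif))
                 for s in testing]
        t_nn[name] = time.perf_counter() - t0
        estimates[name] = np.concatenate(preds)

    report = compare_all(ref, estimates, reference_name="multigrid")

    truth = {}
    for label, studies in [("diverse", diverse), ("homogeneous", homogeneous),
                           ("testing", testing)]:
        F = np.concatenate([s.truth_perfusion for s in studies])
        truth[label] = {
            "mean": float(F.mean()),
            "median": float(np.median(F)),
            "frac_above_200": float((F > 200).mean()),
            "n_voxels": int(F.size),
        }

    result = {
        "seed": int(seed),
        "sizes": {
            "train_voxels_per_dataset": train_voxels,
            "test_voxels_per_dataset": test_voxels,
            "n_train_voxels": len(ts_n1),
            "n_test_voxels": int(ref.size),
        },
        "truth": truth,
        "summary": _summary_rows(report["table"]),
        "p_values": report["p_values"],
        "timing": {
            "multigrid_test_fit_s": t_multigrid,
            "nn_test_inference_s": t_nn["nn_diverse"],
            "nn_speedup_factor": t_multigrid / max(t_nn["nn_diverse"], 1e-9),
        },
    }
    if include_profiles:
        result["profiles"] = {
            k: v.to_dict(orient="records") for k, v in report["profiles"].items()
        }
    return result
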