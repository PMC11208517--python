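import numpy as np
import pytest

import pulmovent as pv
from pulmovent.cohort import analyze_scan_pair
from pulmovent.config import AnalysisConfig


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def baseline_pair48():
    """Lesion-free 48^3 phantom pair with default noise and deformation."""
    spec = pv.PhantomSpec(grid_shape=(48, 48, 48), rng_seed=11)
    return pv.make_phantom_pair(spec)


@pytest.fixture(scope="session")
def clean_pair48():
    """Noise-free 48^3 pair for interpolation-sensitive checks."""
    spec = pv.PhantomSpec(grid_shape=(48, 48, 48), rng_seed=12, noise_sd_hu=0.0)
    return pv.make_phantom_pair(spec)


@pytest.fixture(scope="session")
def lesion_pair64():
    """64^3 pair with 4 planted lesions at default settings."""
    spec = pv.PhantomSpec(grid_shape=(64, 64, 64), rng_seed=19)
    return pv.make_phantom_pair(spec, lesions=pv.LesionSpec(count=4))


@pytest.fixture(scope="session")
def basal_reports64(config):
    """Five baseline animals pushed through the full per-pair pipeline."""
    reports = []
    for seed in range(5):
        spec = pv.PhantomSpec(grid_shape=(64, 64, 64), rng_seed=seed)
        p01, p02, truth = pv.make_phantom_pair(spec)
        rep = analyze_scan_pair(p01, p02, config)
        assert rep.arrays is not None
        reports.append(rep)
    return reports


@pytest.fixture(scope="session")
def thresholds64(basal_reports64, config):
    arrays = [(r.arrays["svg1"], r.arrays["svg2"], r.arrays["delta"])
              for r in basal_reports64]
    return pv.calibrate_thresholds(arrays, config.calibration_percentiles,
                                   config.calibration_mode, cohort_id="basal64")


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory, config):
    """Simulated 3-group longitudinal cohort pushed through run_cohort."""
    from pulmovent.cohort import run_cohort

    data_dir = tmp_path_factory.mktemp("cohort_data")
    plan = pv.CohortPlan(n_per_group=2, groups=("SAL", "BLM", "NINT_14_28"),
                         timepoints_days=(0, 14, 28), peak_lesion_count=8,
                         treatment_attenuation=0.0, rng_seed=77)
    spec = pv.PhantomSpec(grid_shape=(48, 48, 48), rng_seed=77)
    manifest = pv.simulate_cohort(plan, spec, data_dir)
    out_dir = tmp_path_factory.mktemp("cohort_out")
    outputs = run_cohort(data_dir / "manifest.csv", config, str(out_dir))
    return {"plan": plan, "spec": spec, "manifest": manifest,
            "data_dir": data_dir, "out_dir": out_dir, "outputs": outputs,
            "config": config}


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
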