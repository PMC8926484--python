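import numpy as np
import pytest

from herbqc import FingerprintMatrix, Peak, PeakTable, SynthConfig

# Printed replicate peak areas of the IRS saponin (D) used throughout the
# validation tests: precision, repeatability and stability series.
PRECISION_D = [3562.5, 3559.8, 3578.2, 3546.3, 3585.6, 3593.4]
REPEATABILITY_D = [3438.0, 3399.3, 3491.0, 3527.9, 3434.5, 3415.5]
STABILITY_D = [3474.3, 3449.1, 3494.7, 3476.9, 3455.8, 3496.4]

# Published per-volume relative correction factors (seven injection volumes)
RCF_D_A = [1.62, 1.59, 1.63, 1.61, 1.63, 1.66, 1.66]
RCF_D_F = [1.13, 1.14, 1.13, 1.17, 1.15, 1.17, 1.18]
RCF_D_B9 = [0.80, 0.86, 0.82, 0.83, 0.85, 0.85, 0.87]

# Published (S_m, P_m %, alpha) -> (grade, quality) for the five batches
SQFM_TRIPLES = {
    "1": ((0.936, 91.8, 0.060), (2, "Better")),
    "2": ((0.934, 54.4, 0.078), (7, "Defective")),
    "3": ((0.952, 104.7, 0.004), (1, "Best")),
    "4": ((0.938, 117.3, 0.117), (4, "Fine")),
    "5": ((0.718, 104.3, 0.257), (5, "Moderate")),
}


def make_table(injection_id, rts, areas, volume=20.0):
    peaks = [Peak(peak_id=i + 1, rt=float(r), area=float(a))
             for i, (r, a) in enumerate(zip(rts, areas))]
    return PeakTable(injection_id=injection_id, volume=volume, peaks=peaks)


@pytest.fixture
def noise_free_cfg():
    """Study-condition generator with all noise off (exact closed forms hold)."""
    return SynthConfig(noise_cv=0.0, shape_noise_cv=0.0, seed=123)


@pytest.fixture
def default_cfg():
    return SynthConfig(seed=123)


@pytest.fixture
def small_fm():
    rng = np.random.default_rng(42)
    areas = rng.uniform(100.0, 5000.0, size=(5, 11))
    return FingerprintMatrix(batch_ids=[f"b{i + 1}" for i in range(5)], areas=areas)
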