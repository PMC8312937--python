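import numpy as np
import pytest

import voxelbma as vb


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort: 39 CUD + 18 controls at the template frequencies."""
    return vb.generate_cohort(vb.SimulationScenario(seed=2026))


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return vb.build_design_matrix(default_cohort)


@pytest.fixture(scope="session")
def small_regression():
    """A well-conditioned n=20, k=4 continuous regression problem."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(20, 4))
    y = 0.45 + 0.08 * X[:, 1] + rng.normal(0, 0.05, 20)
    return y, X


@pytest.fixture(scope="session")
def planted_run():
    """One full analysis of a stack with a planted negative YCU effect in region 2.

    Effect size -0.0016 FA per YCU-year, pilot-calibrated so the planted
    covariate's FDR-significant set concentrates in the planted region.
    """
    scenario = vb.SimulationScenario(
        grid_shape=(12, 12, 12),
        n_regions=4,
        true_effects={"YCU": (-0.0016, (2,))},
        seed=42,
    )
    cohort = vb.generate_cohort(scenario)
    stack, atlas, truth = vb.generate_fa_stack(cohort, scenario)
    design = vb.build_design_matrix(cohort)
    mask, _ = vb.build_mask(stack)
    results = vb.analyze_stack(stack, design, mask)
    fdr_results, coords = vb.apply_fdr(results, delta=0.10)
    return {
        "scenario": scenario,
        "cohort": cohort,
        "stack": stack,
        "atlas": atlas,
        "truth": truth,
        "design": design,
        "mask": mask,
        "results": results,
        "fdr": fdr_results,
        "coords": coords,
    }
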