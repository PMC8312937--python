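"""Synthetic cohorts and FA stacks with the study's statistical structure.

The generator emulates the analysed cohort: 39 cocaine-use-disorder
subjects (29 male / 10 female, years of cocaine use uniform on
0.25-30) and 18 non-using controls (11 male / 7 female, YCU = 0), with
GAD1a/GAD1b carrier frequencies 0.615/0.846 in the CUD group and
0.421/0.789 in controls. FA volumes live on a small toy grid carved
into axial-slab atlas regions; designated regions carry planted linear
covariate effects on top of a smooth baseline near 0.45, with iid
Gaussian voxel noise, and a sub-threshold region (baseline below the
0.2 mask cutoff) plus a zeroed border exercise the masking rules.

Effect sizes are chosen for test power, not biological realism: the
study reports no FA-per-covariate effect scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import COLUMN_NAMES, SubjectCovariates, build_design_matrix
from .fdr import realized_bayes_fdr
from .volumes import AtlasVolume, FAStack


@dataclass(frozen=True)
class SimulationScenario:
    """Cohort + image generating conditions; defaults mirror the study design."""

    n_cud: int = 39
    n_control: int = 18
    male_proportion_cud: float = 29 / 39
    male_proportion_control: float = 11 / 18
    ycu_range_cud: tuple[float, float] = (0.25, 30.0)
    carrier_freq_cud: tuple[float, float] = (0.615, 0.846)  # (gad1a, gad1b)
    carrier_freq_control: tuple[float, float] = (0.421, 0.789)
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 4
    #: covariate name -> (additive FA effect per covariate unit, region labels)
    true_effects: Mapping[str, tuple[float, tuple[int, ...]]] = field(
        default_factory=dict
    )
    baseline_fa: float = 0.45
    baseline_jitter: float = 0.02
    sub_threshold_region: int | None = None  # region label given baseline 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.male_proportion_cud,
            self.male_proportion_control,
            *self.carrier_freq_cud,
            *self.carrier_freq_control,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"proportion {p} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_cud < 0 or self.n_control < 0 or self.n_cud + self.n_control < 2:
            raise ValueError("need at least 2 subjects in total")
        if self.n_regions < 1 or self.n_regions > self.grid_shape[2]:
            raise ValueError("n_regions must be between 1 and the z extent")
        for name, (_, regs) in self.true_effects.items():
            if name not in COLUMN_NAMES:
                raise ValueError(f"unknown covariate in true_effects: {name!r}")
            for r in regs:
                if not 1 <= r <= self.n_regions:
                    raise ValueError(f"effect region {r} outside 1..{self.n_regions}")


def generate_cohort(scenario: SimulationScenario) -> list[SubjectCovariates]:
    """Draw a cohort at the scenario's frequencies; deterministic under seed."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0]))
    subjects: list[SubjectCovariates] = []
    specs = [
        ("CUD", scenario.n_cud, scenario.male_proportion_cud, scenario.carrier_freq_cud),
        (
            "control",
            scenario.n_control,
            scenario.male_proportion_control,
            scenario.carrier_freq_control,
        ),
    ]
    for group, n, male_p, (fa_freq, fb_freq) in specs:
        for i in range(n):
            sex = int(rng.random() < male_p)
            if group == "CUD":
                lo, hi = scenario.ycu_range_cud
                ycu = float(rng.uniform(lo, hi))
            else:
                ycu = 0.0
            subjects.append(
                SubjectCovariates(
                    subject_id=f"{group.lower()}-{i + 1:03d}",
                    group=group,
                    sex=sex,
                    ycu=ycu,
                    gad1a=int(rng.random() < fa_freq),
                    gad1b=int(rng.random() < fb_freq),
                )
            )
    return subjects


def make_toy_atlas(scenario: SimulationScenario) -> AtlasVolume:
    """Axial-slab toy atlas: z-slabs labeled 1..n_regions, a zeroed 1-voxel border."""
    nx, ny, nz = scenario.grid_shape
    labels = np.zeros(scenario.grid_shape, dtype=np.int32)
    edges = np.linspace(0, nz, scenario.n_regions + 1).astype(int)
    for r in range(scenario.n_regions):
        labels[:, :, edges[r] : edges[r + 1]] = r + 1
    border = np.zeros(scenario.grid_shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    labels[border] = 0
    lookup = {r + 1: f"toy-region-{r + 1:02d}" for r in range(scenario.n_regions)}
    return AtlasVolume(labels=labels, lookup=lookup)


def generate_fa_stack(
    cohort: Sequence[SubjectCovariates], scenario: SimulationScenario
) -> tuple[FAStack, AtlasVolume, dict]:
    """Simulate the FA stack, the toy atlas, and a ground-truth record.

    Per voxel v and subject i, FA is ``baseline(v) + sum_c effect_c *
    x_ic * [v in signal region of c] + N(0, noise_sd^2)``, clipped into
    (0.01, 0.99). The border is set to exactly 0 in every subject (black
    voxels) and the optional sub-threshold region's baseline is 0.15, so
    the masking rules each remove something. The truth record lists the
    signal voxels of every effect covariate, the planted effect sizes,
    and the clip count.

    Raises if a planted effect could push FA outside (0, 1) for the
    cohort's covariate range (containment check).
    """
    atlas = make_toy_atlas(scenario)
    X = build_design_matrix(cohort)
    n = X.n
    nx, ny, nz = scenario.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))

    # containment: baseline +/- 4 sd of jitter+noise + max effect must stay in (0,1)
    headroom = scenario.baseline_fa - 4 * (scenario.baseline_jitter + scenario.noise_sd)
    ceiling = 1 - scenario.baseline_fa - 4 * (scenario.baseline_jitter + scenario.noise_sd)
    for name, (effect, _) in scenario.true_effects.items():
        col = X.values[:, COLUMN_NAMES.index(name)]
        extreme = max(abs(effect * col.min()), abs(effect * col.max()))
        if extreme > min(headroom, ceiling) - 0.05:
            raise ValueError(
                f"effect on {name!r} (up to {extreme:.3f} FA units) risks leaving "
                "the (0, 1) interval; reduce the effect size"
            )

    # smooth spatial jitter: low-frequency cosine mixture, same for all subjects
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    phases = rng.uniform(0, 2 * np.pi, size=3)
    baseline = scenario.baseline_fa + scenario.baseline_jitter * (
        np.cos(2 * np.pi * ii / nx + phases[0])
        + np.cos(2 * np.pi * jj / ny + phases[1])
        + np.cos(2 * np.pi * kk / nz + phases[2])
    ) / 3.0
    if scenario.sub_threshold_region is not None:
        baseline = baseline.copy()
        baseline[atlas.labels == scenario.sub_threshold_region] = 0.15

    data = np.repeat(baseline[..., None], n, axis=3)
    truth: dict = {
        "effects": {},
        "signal_voxels": {},
        "grid_shape": list(scenario.grid_shape),
        "seed": scenario.seed,
    }
    for name, (effect, region_labels) in scenario.true_effects.items():
        col = X.values[:, COLUMN_NAMES.index(name)]
        in_regions = np.isin(atlas.labels, list(region_labels))
        data[in_regions, :] += effect * col[None, :]
        truth["effects"][name] = effect
        truth["signal_voxels"][name] = [
            [int(a) for a in ijk] for ijk in np.argwhere(in_regions)
        ]

    data += rng.normal(0.0, scenario.noise_sd, size=data.shape)
    clipped = int(np.sum((data <= 0.01) | (data >= 0.99)))
    data = np.clip(data, 0.01, 0.99)
    truth["n_clipped"] = clipped

    border = atlas.labels == 0
    data[border, :] = 0.0  # black voxels in every subject

    stack = FAStack(
        data=data,
        affine=np.eye(4),
        subject_order=[s.subject_id for s in cohort],
    )
    return stack, atlas, truth


# -- simulation studies -------------------------------------------------------


def null_fdr_calibration(
    n_replicates: int = 20,
    grid_shape: tuple[int, int, int] = (15, 15, 12),
    delta: float = 0.10,
    seed: int = 0,
) -> dict:
    """FDR behaviour on replicate pure-null images (no planted effects).

    Each replicate draws a fresh study-sized cohort and a null FA stack,
    runs the full per-voxel analysis and per-covariate Bayesian FDR, and
    records two quantities per covariate application: the realized
    Bayesian FDR of the declared set (mean posterior non-inclusion,
    which the rule bounds by delta) and the frequentist false-discovery
    proportion (1 when anything is declared, since every declaration on
    null data is false; 0 otherwise). The defaults give ~2,000 analyzed
    voxels per replicate.
    """
    from .fdr import DEFAULT_DELTA  # local import avoids a cycle at module load
    from .pipeline import analyze_stack, apply_fdr
    from .volumes import build_mask

    bayes_fdrs: list[float] = []
    freq_fdps: list[float] = []
    xis: list[int] = []
    n_voxels = 0
    for rep in range(n_replicates):
        scenario = SimulationScenario(grid_shape=grid_shape, seed=seed + rep)
        cohort = generate_cohort(scenario)
        stack, _, _ = generate_fa_stack(cohort, scenario)
        design = build_design_matrix(cohort)
        mask, n_voxels = build_mask(stack)
        results = analyze_stack(stack, design, mask)
        fdr_results, _ = apply_fdr(results, delta)
        for res in fdr_results:
            bayes_fdrs.append(realized_bayes_fdr(res))
            freq_fdps.append(1.0 if res.xi > 0 else 0.0)
            xis.append(res.xi)
    return {
        "n_replicates": n_replicates,
        "n_voxels_per_replicate": n_voxels,
        "delta": delta,
        "mean_realized_bayes_fdr": float(np.mean(bayes_fdrs)),
        "mean_frequentist_fdp": float(np.mean(freq_fdps)),
        "total_false_discoveries": int(np.sum(xis)),
    }


def planted_recovery(
    effect: float = -0.0016,
    covariate: str = "YCU",
    region: int = 2,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    delta: float = 0.10,
    seed: int = 0,
) -> dict:
    """End-to-end recovery of one planted covariate effect.

    Plants ``effect`` FA units per covariate unit in one toy-atlas
    region, runs the analysis, and reports how the planted covariate's
    PIPs and FDR-significant set separate signal from null voxels. The
    default effect size comes from a pilot calibration of the default
    scenario (see the methods note).
    """
    from .pipeline import analyze_stack, apply_fdr
    from .volumes import build_mask

    scenario = SimulationScenario(
        grid_shape=grid_shape,
        n_regions=4,
        true_effects={covariate: (effect, (region,))},
        seed=seed,
    )
    cohort = generate_cohort(scenario)
    stack, atlas, truth = generate_fa_stack(cohort, scenario)
    design = build_design_matrix(cohort)
    mask, _ = build_mask(stack)
    results = analyze_stack(stack, design, mask)
    fdr_results, coords = apply_fdr(results, delta)

    c = list(results.column_names).index(covariate)
    signal = np.zeros(mask.shape, dtype=bool)
    for ijk in truth["signal_voxels"][covariate]:
        signal[tuple(ijk)] = True
    pips = results.pip_maps[..., c]
    sig_set = set(coords[c])
    signal_masked = {tuple(v) for v in np.argwhere(signal & results.mask)}
    in_region = len(sig_set & signal_masked)
    return {
        "covariate": covariate,
        "effect": effect,
        "xi": fdr_results[c].xi,
        "n_signal_voxels": len(signal_masked),
        "n_in_planted_region": in_region,
        "concentration": in_region / max(fdr_results[c].xi, 1),
        "recall": in_region / max(len(signal_masked), 1),
        "mean_signal_pip": float(np.nanmean(pips[signal & results.mask])),
        "mean_null_pip": float(np.nanmean(pips[~signal & results.mask])),
    }
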