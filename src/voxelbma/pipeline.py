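"""End-to-end voxel-wise analysis: mask -> per-voxel BMA -> FDR -> maps -> tables.

The heavy loop is the per-voxel model enumeration; since the design is
shared across voxels, all X-only factorizations are computed once
(:class:`~voxelbma.bma.ModelSpace`) and voxels are processed in
vectorized chunks. The MC3 engine exists as an alternative for model
spaces too large to enumerate and for validation; its per-voxel RNG is
derived from (master seed, voxel flat index), so results do not depend
on chunking, worker count or scheduling order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .bma import ConstantResponseError, GPrior, ModelSpace, default_g
from .design import (
    COLUMN_NAMES,
    DesignMatrix,
    SubjectCovariates,
    build_design_matrix,
    read_covariates_tsv,
)
from .fdr import DEFAULT_DELTA, FDRResult, fdr_all_covariates
from .mc3 import MC3Config, mc3_run
from .regions import (
    coefficient_sign_proportions,
    count_significant_by_region,
    to_long_format,
)
from .volumes import AtlasVolume, FAStack, build_mask, load_atlas, load_fa_stack, save_volume

_CHUNK = 512


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a path-based pipeline run (CLI surface).

    ``fa`` is a list of per-subject 3-D NIfTI paths in covariate-table
    order, or a single 4-D file plus ``subject_order``.
    """

    fa: tuple[str, ...] | str
    covariates: str
    atlas: str
    atlas_lookup: str
    output_dir: str
    subject_order: tuple[str, ...] | None = None
    fa_threshold: float = 0.2
    engine: str = "enumerate"
    g: float | None = None
    delta: float = DEFAULT_DELTA
    seed: int = 0
    workers: int = 1
    mc3_iterations: int = 20_000
    mc3_burn_in: int = 2_000
    mc3_include_self: bool = True
    checkpoint_interval: int = 50_000

    def __post_init__(self) -> None:
        if self.engine not in ("enumerate", "mc3"):
            raise ValueError("engine must be 'enumerate' or 'mc3'")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class VoxelResults:
    """In-memory result of the per-voxel stage on a masked grid."""

    pip_maps: np.ndarray  # (x, y, z, k), NaN outside mask / at skipped voxels
    coef_maps: np.ndarray  # (x, y, z, k)
    mask: np.ndarray  # analysis mask actually used (skips removed)
    skipped_voxels: list[tuple[int, int, int]]
    column_names: tuple[str, ...]

    @property
    def masked_coords(self) -> np.ndarray:
        return np.argwhere(self.mask)


def analyze_stack(
    stack: FAStack,
    design: DesignMatrix,
    mask: np.ndarray,
    prior: GPrior | None = None,
    engine: str = "enumerate",
    seed: int = 0,
    workers: int = 1,
    mc3_config: MC3Config | None = None,
    space: ModelSpace | None = None,
    checkpoint_path: str | Path | None = None,
    checkpoint_interval: int = 50_000,
    checkpoint_key: str = "",
) -> VoxelResults:
    """Compute PIP and model-averaged-coefficient maps over a masked grid.

    Constant-response voxels are skipped (NaN in the maps, removed from
    the returned mask) and listed. Results are identical for any
    ``workers`` value. With ``checkpoint_path`` set, partial results of
    the enumerate engine are saved every ``checkpoint_interval`` voxels
    and reused on restart when ``checkpoint_key`` (a config digest)
    matches.
    """
    if stack.grid_shape != mask.shape:
        raise ValueError("mask grid does not match the FA stack")
    if stack.n_subjects != design.n:
        raise ValueError("design rows do not match the number of subjects")
    if prior is None:
        prior = default_g(design.n, design.k)
    if space is None:
        space = ModelSpace(design)
    k = design.k

    coords = np.argwhere(mask)
    Y = stack.data[mask].T  # n x V in argwhere order
    spread = Y.max(axis=0) - Y.min(axis=0)
    constant = spread <= 0
    skipped = [tuple(int(c) for c in ijk) for ijk in coords[constant]]
    keep = ~constant
    coords = coords[keep]
    Y = Y[:, keep]

    nvox = Y.shape[1]
    pip_flat = np.empty((k, nvox))
    coef_flat = np.empty((k, nvox))

    if engine == "enumerate":
        chunks = [(s, min(s + _CHUNK, nvox)) for s in range(0, nvox, _CHUNK)]

        start_chunk = 0
        ckpt = Path(checkpoint_path) if checkpoint_path is not None else None
        if ckpt is not None and ckpt.exists():
            saved = np.load(ckpt, allow_pickle=False)
            if (
                str(saved["key"]) == checkpoint_key
                and int(saved["nvox"]) == nvox
                and int(saved["n_done"]) <= nvox
            ):
                n_done = int(saved["n_done"])
                pip_flat[:, :n_done] = saved["pip"]
                coef_flat[:, :n_done] = saved["coef"]
                # resume at the first chunk not fully covered (it is recomputed
                # whole, overwriting any partial region from the checkpoint)
                start_chunk = next(
                    (c for c, (_, hi) in enumerate(chunks) if hi > n_done), len(chunks)
                )

        def do_chunk(lo: int, hi: int):
            return space.batch_pips_and_coefficients(Y[:, lo:hi], prior)

        pending = chunks[start_chunk:]
        since_checkpoint = 0
        group = max(1, checkpoint_interval // _CHUNK)
        for g0 in range(0, len(pending), group):
            batch = pending[g0 : g0 + group]
            if workers > 1 and len(batch) > 1:
                results = Parallel(n_jobs=workers)(
                    delayed(do_chunk)(lo, hi) for lo, hi in batch
                )
            else:
                results = [do_chunk(lo, hi) for lo, hi in batch]
            for (lo, hi), (pips, coefs) in zip(batch, results):
                pip_flat[:, lo:hi] = pips
                coef_flat[:, lo:hi] = coefs
                since_checkpoint += hi - lo
            if ckpt is not None and since_checkpoint >= checkpoint_interval:
                n_done = batch[-1][1]
                np.savez(
                    ckpt,
                    key=checkpoint_key,
                    nvox=nvox,
                    n_done=n_done,
                    pip=pip_flat[:, :n_done],
                    coef=coef_flat[:, :n_done],
                )
                since_checkpoint = 0
        if ckpt is not None and ckpt.exists():
            ckpt.unlink()  # run completed; stale checkpoints must not linger
    elif engine == "mc3":
        cfg = mc3_config or MC3Config()
        flat_index = np.ravel_multi_index(coords.T, mask.shape)

        def do_voxel(v: int):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed & 0x7FFFFFFF, int(flat_index[v])])
            )
            trace = mc3_run(Y[:, v], design, prior, cfg, space=space, rng=rng)
            probs_full = np.zeros(space.n_models)
            probs_full[trace.visited_masks] = trace.renormalized_probs
            pips = space.membership.T @ probs_full
            yc = Y[:, v] - Y[:, v].mean()
            betas = (space._B @ yc) / (1.0 + prior.g)
            coefs = np.asarray(space._scatter @ (betas * probs_full[space._row_model]))
            return pips, coefs.reshape(-1)

        if workers > 1:
            results = Parallel(n_jobs=workers)(delayed(do_voxel)(v) for v in range(nvox))
        else:
            results = [do_voxel(v) for v in range(nvox)]
        for v, (pips, coefs) in enumerate(results):
            pip_flat[:, v] = pips
            coef_flat[:, v] = coefs
    else:
        raise ValueError(f"unknown engine {engine!r}")

    shape = (*mask.shape, k)
    pip_maps = np.full(shape, np.nan)
    coef_maps = np.full(shape, np.nan)
    pip_maps[coords[:, 0], coords[:, 1], coords[:, 2], :] = pip_flat.T
    coef_maps[coords[:, 0], coords[:, 1], coords[:, 2], :] = coef_flat.T

    used_mask = mask.copy()
    for ijk in skipped:
        used_mask[ijk] = False
    return VoxelResults(
        pip_maps=pip_maps,
        coef_maps=coef_maps,
        mask=used_mask,
        skipped_voxels=skipped,
        column_names=tuple(design.column_names),
    )


def apply_fdr(
    results: VoxelResults, delta: float = DEFAULT_DELTA
) -> tuple[list[FDRResult], list[list[tuple[int, int, int]]]]:
    """Per-covariate Bayesian FDR over the analyzed voxels.

    Returns the FDR results (voxel indices are positions in the masked
    voxel list) and, per covariate, the (i, j, k) coordinates of the
    significant voxels.
    """
    coords = results.masked_coords
    pip_matrix = results.pip_maps[results.mask]  # V x k
    fdr_results = fdr_all_covariates(pip_matrix, delta, results.column_names)
    coords_per_cov = [
        [tuple(int(c) for c in coords[i]) for i in res.indices] for res in fdr_results
    ]
    return fdr_results, coords_per_cov


def run_pipeline(
    config: PipelineConfig,
    cohort: Sequence[SubjectCovariates] | None = None,
    stack: FAStack | None = None,
    atlas: AtlasVolume | None = None,
) -> dict:
    """Run the full analysis and write all outputs; returns the manifest.

    Inputs are read from the paths in ``config`` unless pre-loaded
    objects are passed (the simulate subcommand and tests use the
    in-memory route with the same downstream code).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cohort = read_covariates_tsv(config.covariates)
    cov_df = pd.DataFrame({"subject_id": [s.subject_id for s in cohort]})
    if stack is None:
        stack = load_fa_stack(
            list(config.fa) if not isinstance(config.fa, str) else config.fa,
            cov_df,
            subject_order=config.subject_order,
        )
    affine = stack.affine
    if atlas is None:
        atlas, _ = load_atlas(config.atlas, config.atlas_lookup)
    if atlas.labels.shape != stack.grid_shape:
        raise ValueError(
            f"stage=atlas: atlas grid {atlas.labels.shape} != FA grid {stack.grid_shape}"
        )

    design = build_design_matrix(cohort)
    prior = GPrior(config.g) if config.g is not None else default_g(design.n, design.k)

    mask, n_masked = build_mask(stack, config.fa_threshold)
    if n_masked == 0:
        raise ValueError("stage=mask: no voxels survive the FA mask")

    mc3_cfg = MC3Config(
        n_iterations=config.mc3_iterations,
        burn_in=config.mc3_burn_in,
        seed=config.seed,
        include_self_in_neighborhood=config.mc3_include_self,
    )
    results = analyze_stack(
        stack,
        design,
        mask,
        prior=prior,
        engine=config.engine,
        seed=config.seed,
        workers=config.workers,
        mc3_config=mc3_cfg,
        checkpoint_path=out / "checkpoint.npz",
        checkpoint_interval=config.checkpoint_interval,
        checkpoint_key=config.digest(),
    )

    fdr_results, coords_per_cov = apply_fdr(results, config.delta)
    counts = count_significant_by_region(fdr_results, atlas, coords_per_cov)
    pos, neg = coefficient_sign_proportions(
        fdr_results, results.coef_maps, atlas, coords_per_cov
    )

    # -- outputs --------------------------------------------------------------
    def slug(name: str) -> str:
        return name.replace("|", "_x_").lower()

    for c, name in enumerate(results.column_names):
        save_volume(results.pip_maps[..., c], affine, out / f"pip_{slug(name)}.nii.gz")
        save_volume(results.coef_maps[..., c], affine, out / f"coef_{slug(name)}.nii.gz")
        sig = np.zeros(stack.grid_shape, dtype=np.uint8)
        for ijk in coords_per_cov[c]:
            sig[ijk] = 1
        save_volume(sig, affine, out / f"significant_{slug(name)}.nii.gz")
        rows = [
            {
                "i": i,
                "j": j,
                "k": k,
                "pip": pip,
                "coefficient": float(results.coef_maps[i, j, k, c]),
                "sign": int(np.sign(results.coef_maps[i, j, k, c])),
            }
            for (i, j, k), (_, pip) in zip(coords_per_cov[c], fdr_results[c].significant_voxels)
        ]
        pd.DataFrame(
            rows, columns=["i", "j", "k", "pip", "coefficient", "sign"]
        ).to_csv(out / f"significant_{slug(name)}.tsv", sep="\t", index=False)

    counts.to_csv(out / "region_counts.tsv", sep="\t")
    pos.to_csv(out / "region_prop_positive.tsv", sep="\t")
    neg.to_csv(out / "region_prop_negative.tsv", sep="\t")
    to_long_format(counts, pos, neg).to_csv(out / "region_long.tsv", sep="\t", index=False)
    save_volume(results.mask, affine, out / "analysis_mask.nii.gz")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_subjects": design.n,
        "n_covariates": design.k,
        "n_models": 1 << design.k,
        "g": prior.g,
        "voxel_counts": {
            "grid": int(np.prod(stack.grid_shape)),
            "masked": n_masked,
            "analyzed": int(results.mask.sum()),
            "skipped_constant": len(results.skipped_voxels),
        },
        "skipped_voxels": [list(v) for v in results.skipped_voxels],
        "fdr": {
            res.covariate_name: {"phi": res.phi, "xi": res.xi}
            for res in fdr_results
        },
        "total_significant_combinations": int(sum(r.xi for r in fdr_results)),
        "output_dir": str(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def summarize_run(manifest: dict, top_n: int = 3) -> str:
    """Human-readable summary of a completed run manifest."""
    for key in ("voxel_counts", "fdr", "output_dir"):
        if key not in manifest:
            raise ValueError(f"incomplete manifest: missing {key!r}")
    vc = manifest["voxel_counts"]
    lines = [
        f"voxelbma run (version {manifest.get('version', '?')}, "
        f"seed {manifest.get('seed')})",
        f"  voxels: {vc['grid']} grid, {vc['masked']} masked, "
        f"{vc['analyzed']} analyzed, {vc['skipped_constant']} skipped (constant FA)",
        f"  significant voxel/covariate combinations: "
        f"{manifest['total_significant_combinations']}",
        "  per-covariate significant voxel counts (xi):",
    ]
    ranked = sorted(
        manifest["fdr"].items(), key=lambda kv: (-kv[1]["xi"], kv[0])
    )
    for name, info in ranked:
        phi = info["phi"]
        phi_txt = f"{phi:.4f}" if np.isfinite(phi) else "inf (none pass)"
        lines.append(f"    {name:<18} xi={info['xi']:<6} phi={phi_txt}")

    counts_path = Path(manifest["output_dir"]) / "region_counts.tsv"
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lines.append(f"  top regions per covariate (up to {top_n}):")
        for name, _ in ranked:
            col = counts[name]
            top = col[col > 0].sort_values(ascending=False).head(top_n)
            if len(top):
                joined = ", ".join(f"{r}={int(v)}" for r, v in top.items())
                lines.append(f"    {name:<18} {joined}")
    if manifest["total_significant_combinations"] == 0:
        lines.append("  no significant voxels at this FDR level")
    return "\n".join(lines)
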