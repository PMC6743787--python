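"""End-to-end experiment driver.

A single :class:`PipelineConfig` fixes every stage: phantom + dual-energy
polychromatic simulation -> projection-space material decomposition ->
virtual-monochromatic reference -> residual CNN training and projection
correction -> reconstructions (MLEM, normalized BP, the weighted MAR
hybrid, plus MLEM / FBP / SART-TV / VM-MLEM baselines) -> artifact metrics
(AI, MSE, ASF, GLCM). One global seed is fanned out to named sub-streams
(noise, patch cropping, weight init), so identical seeds give bitwise
identical reports.

Volumes are compared through metrics computed on each algorithm's in-focus
slice; since the algorithms reconstruct on different intensity scales, the
MSE table is computed on min-max normalized slices while the AI (a
coefficient-of-variation statistic) is scale-free by construction.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .decomposition import build_sensitivity_matrix, decompose_projections, vm_projection
from .dncnn import (
    TrainingConfig,
    build_model,
    correct_projections,
    make_training_patches,
    predict_residual,
    train_sgdm,
)
from .geometry import TomoGeometry
from .materials import AttenuationTable
from .metrics import ROISpec, artifact_index, asf_curve, glcm_features, image_mse
from .phantom import MATERIAL_ORDER, PhantomConfig, build_phantom
from .projector import ProjectionStack, material_pathlengths, polychromatic_project
from .recon import (
    SystemOperator,
    back_project,
    fbp_reconstruct,
    hybrid_mar,
    mlem_reconstruct,
    sart_tv_reconstruct,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "sweep_hyperparameters", "seed_for"]

_SEED_STREAMS = {"noise": 0, "patches": 1, "weights": 2}


def seed_for(global_seed: int, stream: str) -> int:
    """Deterministic per-stream child seed below 2^31."""
    if stream not in _SEED_STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}")
    ss = np.random.SeedSequence([int(global_seed), _SEED_STREAMS[stream]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Full experiment configuration; ``geometry`` and ``phantom`` are required."""

    geometry: TomoGeometry
    phantom: PhantomConfig
    seed: int = 0
    low_kv: float = 70.0
    high_kv: float = 140.0
    vm_energy_kev: float = 140.0
    noise_photons: float | None = 1e5
    training: TrainingConfig = field(default_factory=TrainingConfig)
    holdout_fraction: float = 0.1
    model_depth: int = 20
    model_channels: int = 64
    mlem_iterations: int = 30
    sart_iterations: int = 10
    tv_iterations: int = 100
    tv_step: float = 50.0
    hybrid_w: float = 0.7
    mlem_incident_count: float = 1e4
    ai_mode: str = "cv"
    rois: dict | None = None  # explicit ROI layout; default derived from phantom

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for block in ("geometry", "phantom"):
            if block not in d:
                raise ValueError(f"config missing required block: {block!r}")
        kwargs = {}
        kwargs["geometry"] = TomoGeometry.from_dict(d.pop("geometry"))
        kwargs["phantom"] = PhantomConfig(**_tupled(d.pop("phantom")))
        if "training" in d:
            kwargs["training"] = TrainingConfig(**d.pop("training"))
        known = set(cls.__dataclass_fields__)
        for key, val in d.items():
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _tupled(d: dict) -> dict:
    d = dict(d)
    if "grid_shape" in d:
        d["grid_shape"] = tuple(d["grid_shape"])
    return d


@dataclass
class RunReport:
    """Per-algorithm metrics plus provenance; every metric traces to a volume."""

    ai: dict
    mse_vs_hybrid: dict
    asf: dict
    glcm: dict
    training_loss: list
    holdout_views: list
    sensitivity_condition_number: float
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "ai": self.ai,
            "mse_vs_hybrid": self.mse_vs_hybrid,
            "asf": self.asf,
            "glcm": self.glcm,
            "training_loss": self.training_loss,
            "holdout_views": self.holdout_views,
            "sensitivity_condition_number": self.sensitivity_condition_number,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        """Flat per-algorithm metric table (AI, MSE vs hybrid, GLCM)."""
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["algorithm", "ai_mean", "ai_stderr", "mse_vs_hybrid",
                 "glcm_idm", "glcm_contrast", "glcm_correlation"]
            )
            for name in self.ai:
                g = self.glcm[name]
                writer.writerow(
                    [
                        name,
                        f"{self.ai[name]['mean']:.6g}",
                        f"{self.ai[name]['stderr']:.6g}",
                        f"{self.mse_vs_hybrid.get(name, ''):.6g}" if name in self.mse_vs_hybrid else "",
                        f"{g['inverse_difference_moment']:.6g}",
                        f"{g['contrast']:.6g}",
                        "" if g["correlation"] is None else f"{g['correlation']:.6g}",
                    ]
                )


def default_roi_layout(config: PipelineConfig) -> dict:
    """Place AI/ASF ROIs from the phantom geometry.

    The nail lies along u (columns) through the volume center, so metal
    streaks spread along v (rows). Ten 4x14 artifact ROIs straddle the
    implant band symmetrically along v; the background ROI sits in open
    water far from the implant at the same columns.
    """
    geo = config.geometry
    nv, nu = geo.detector_shape
    recon_pitch = geo.pixel_pitch_mm / geo.magnification
    rc, cc = nv // 2, nu // 2
    h, w = 4, 14
    band = int(math.ceil(config.phantom.implant_radius_mm / recon_pitch))

    col = max(0, cc - w // 2)
    case_px = config.phantom.case_radius_mm / recon_pitch
    artifact = []
    # five offsets per side, covering the streak corridor from just outside
    # the implant's blur penumbra (1.5 x implant radius, so the ROIs sample
    # streaks rather than the reconstructed implant itself) out to ~70% of
    # the case radius (clear of the case boundary)
    near = int(round(1.5 * band)) + 2
    far = max(near + 4, int(0.70 * case_px) - h)
    offsets = np.unique(np.round(np.linspace(near, far, 5)).astype(int))
    for off in offsets:
        off = int(off)
        artifact.append(ROISpec(row=max(0, rc - off - h), col=col, height=h, width=w))
        artifact.append(ROISpec(row=min(nv - h, rc + off), col=col, height=h, width=w))
    # background: open water, off the streak corridor both in rows and columns
    bg_row = rc + int(0.72 * case_px)
    bg_col = cc - int(0.45 * case_px)
    bg = ROISpec(
        row=min(nv - h, max(0, bg_row)),
        col=min(nu - w, max(0, bg_col)),
        height=h,
        width=w,
        role="background",
    )
    feature = ROISpec(row=artifact[0].row, col=col, height=h, width=w, role="feature")
    return {"artifact": artifact, "background": bg, "feature": feature}


class PipelineState:
    """Lazy, cache-aware execution of the pipeline stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.cache: dict = {}
        self.timings: dict = {}

    def _run(self, name, fn):
        if name not in self.timings:
            t0 = time.perf_counter()
            fn()
            self.timings[name] = time.perf_counter() - t0
        return self.cache

    # --- stage: simulate -------------------------------------------------
    def simulate(self):
        def fn():
            cfg = self.config
            from .spectra import simulate_spectrum

            attn = AttenuationTable.for_materials()
            phantom = build_phantom(cfg.phantom)
            paths = material_pathlengths(phantom, cfg.geometry)
            spec_l = simulate_spectrum(cfg.low_kv)
            spec_h = simulate_spectrum(cfg.high_kv)
            rng = np.random.default_rng(seed_for(cfg.seed, "noise"))
            noise = cfg.noise_photons
            self.cache.update(
                attn=attn,
                phantom=phantom,
                paths=paths,
                spec_low=spec_l,
                spec_high=spec_h,
                stack_low=polychromatic_project(paths, spec_l, attn, noise, rng, tag="70kV"),
                stack_high=polychromatic_project(paths, spec_h, attn, noise, rng, tag="140kV"),
            )

        return self._run("simulate", fn)

    # --- stage: decompose ------------------------------------------------
    def decompose(self):
        self.simulate()

        def fn():
            cfg = self.config
            c = self.cache
            ref = _central_ray_densities(c["paths"])
            sens = build_sensitivity_matrix(c["spec_low"], c["spec_high"], c["attn"], ref)
            fractions = decompose_projections(c["stack_low"], c["stack_high"], sens)
            vm = vm_projection(fractions, cfg.geometry, cfg.vm_energy_kev, c["attn"])
            c.update(sensitivity=sens, fractions=fractions, stack_vm=vm)

        return self._run("decompose", fn)

    # --- stage: train + correct -------------------------------------------
    def correct(self):
        self.decompose()

        def fn():
            cfg = self.config
            c = self.cache
            n_views = cfg.geometry.n_views
            n_hold = math.ceil(cfg.holdout_fraction * n_views)
            rng = np.random.default_rng(seed_for(cfg.seed, "patches"))
            perm = rng.permutation(n_views)
            holdout = np.sort(perm[:n_hold])
            train_views = np.sort(perm[n_hold:])

            tcfg = replace(cfg.training, seed=seed_for(cfg.seed, "patches"))
            patches = make_training_patches(c["stack_low"], c["stack_vm"], tcfg, views=train_views)
            model = build_model(cfg.model_depth, cfg.model_channels, seed=seed_for(cfg.seed, "weights"))
            model, losses = train_sgdm(model, patches, tcfg)
            residual = predict_residual(model, c["stack_low"])
            corrected = correct_projections(c["stack_low"], residual)
            c.update(
                model=model,
                training_loss=losses,
                stack_residual=residual,
                stack_corrected=corrected,
                holdout_views=holdout.tolist(),
                train_views=train_views.tolist(),
            )

        return self._run("correct", fn)

    # --- stage: reconstruct ------------------------------------------------
    def reconstruct(self):
        self.correct()

        def fn():
            cfg = self.config
            c = self.cache
            op = SystemOperator(cfg.geometry)

            def counts(stack: ProjectionStack) -> ProjectionStack:
                # MLEM data model: non-negative synthetic counts
                return ProjectionStack(
                    data=np.maximum(stack.data, 0.0) * cfg.mlem_incident_count,
                    geometry=stack.geometry,
                    tag=stack.tag + "-counts",
                    convention="intensity",
                )

            def mlem(stack: ProjectionStack):
                # reconstruct on the counts scale, report on the intensity
                # scale (MLEM is linear in the data) so MLEM and normalized
                # BP volumes are commensurate for the hybrid blend
                vol, _ = mlem_reconstruct(counts(stack), cfg.geometry, cfg.mlem_iterations, op=op)
                vol.data = vol.data / cfg.mlem_incident_count
                return vol

            mlem_cor = mlem(c["stack_corrected"])
            bp_cor = back_project(c["stack_corrected"], cfg.geometry, op=op, normalize=True)
            volumes = {
                "MLEM-corrected": mlem_cor,
                "BP-corrected": bp_cor,
                "DnCNN-MARHR": hybrid_mar(mlem_cor, bp_cor, cfg.hybrid_w),
                "MLEM-70kV": mlem(c["stack_low"]),
                "VM-MLEM": mlem(c["stack_vm"]),
                "FBP-70kV": fbp_reconstruct(c["stack_low"], cfg.geometry, op=op),
                "SART-TV-140kV": sart_tv_reconstruct(
                    c["stack_high"],
                    cfg.geometry,
                    cfg.sart_iterations,
                    cfg.tv_iterations,
                    cfg.tv_step,
                    op=op,
                ),
            }
            c.update(volumes=volumes, operator=op)

        return self._run("reconstruct", fn)

    # --- stage: metrics ----------------------------------------------------
    def evaluate(self):
        self.reconstruct()

        def fn():
            cfg = self.config
            c = self.cache
            rois = cfg.rois or default_roi_layout(cfg)
            ai, mse, asf, glcm = {}, {}, {}, {}
            volumes = c["volumes"]
            z0 = volumes["DnCNN-MARHR"].in_focus_index
            hybrid_slice = _norm01(volumes["DnCNN-MARHR"].data)[z0]
            for name, vol in volumes.items():
                # metrics are computed after volume-level min-max
                # normalization: the algorithms reconstruct on different
                # intensity scales (FBP output is even zero-mean), and the
                # volume-wide window maps each onto a common [0, 1] scale
                # the way reconstructions are windowed for ROI analysis
                sl = _norm01(vol.data)[z0]
                res = artifact_index(sl, rois["artifact"], rois["background"], mode=cfg.ai_mode)
                ai[name] = {"mean": res.mean, "stderr": res.stderr, "values": res.values.tolist()}
                if name != "DnCNN-MARHR":
                    mse[name] = image_mse(hybrid_slice, sl)
                asf[name] = asf_curve(vol.data, rois["feature"], rois["background"], z0).tolist()
                g = glcm_features(sl)
                glcm[name] = {
                    "inverse_difference_moment": g.inverse_difference_moment,
                    "contrast": g.contrast,
                    "correlation": g.correlation,
                }
            c["report"] = RunReport(
                ai=ai,
                mse_vs_hybrid=mse,
                asf=asf,
                glcm=glcm,
                training_loss=c["training_loss"],
                holdout_views=c["holdout_views"],
                sensitivity_condition_number=c["sensitivity"].condition_number,
                provenance={
                    "seed": cfg.seed,
                    "config_hash": cfg.config_hash(),
                    "rois": {
                        "artifact": [r.to_dict() for r in rois["artifact"]],
                        "background": rois["background"].to_dict(),
                        "feature": rois["feature"].to_dict(),
                    },
                },
            )

        return self._run("evaluate", fn)


def _central_ray_densities(paths) -> dict:
    """Reference area densities: per material, its central-view central-ray K."""
    out = {}
    iv = paths.geometry.n_views // 2
    nv, nu = paths.geometry.detector_shape
    for name in MATERIAL_ORDER:
        k = paths.maps[name][iv, nv // 2, nu // 2]
        if k <= 0:  # central ray misses this material: fall back to the map peak
            k = float(paths.maps[name].max())
        if k <= 0:
            raise ValueError(f"phantom contains no {name}; cannot set reference density")
        out[name] = float(k)
    return out


def _norm01(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute every stage and return (and optionally persist) the report.

    With ``outdir`` set, all intermediate stacks and volumes are written as
    float32 TIFF + JSON sidecars along with the report and a manifest; on a
    stage failure the completed intermediates are still on disk.
    """
    state = PipelineState(config)
    if outdir is None:
        state.evaluate()
        return state.cache["report"]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .stackio import write_stack

    manifest = {"config": config.to_dict(), "artifacts": []}

    def persist():
        c = state.cache
        for key in ("stack_low", "stack_high", "stack_vm", "stack_residual", "stack_corrected"):
            if key in c:
                files = write_stack(c[key], outdir / key)
                manifest["artifacts"] += [str(f) for f in files]
        for name, vol in c.get("volumes", {}).items():
            files = write_stack(vol, outdir / f"vol_{name}")
            manifest["artifacts"] += [str(f) for f in files]
        if "sensitivity" in c:
            (outdir / "sensitivity.json").write_text(json.dumps(c["sensitivity"].to_dict(), indent=1))
        if "model" in c:
            c["model"].save(outdir / "dncnn_model.h5")
        if "training_loss" in c:
            with open(outdir / "training_loss.csv", "w") as fh:
                fh.write("epoch,loss\n")
                for i, l in enumerate(c["training_loss"]):
                    fh.write(f"{i},{l}\n")

    try:
        state.evaluate()
    except Exception as exc:
        persist()
        stage = _failed_stage(state)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    persist()
    report = state.cache["report"]
    report.to_json(outdir / "report.json")
    report.to_csv(outdir / "report.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def _failed_stage(state: PipelineState) -> str:
    for stage, keys in (
        ("simulate", "stack_low"),
        ("decompose", "stack_vm"),
        ("train", "stack_corrected"),
        ("reconstruct", "volumes"),
        ("evaluate", "report"),
    ):
        if keys not in state.cache:
            return stage
    return "evaluate"


def sweep_hyperparameters(config: PipelineConfig, grid: dict, use_cache: bool = True):
    """Repeat the pipeline over a one-parameter grid, reusing cached stages.

    ``grid`` maps one parameter name ("mini_batch", "epochs" or "w") to a
    list of values. Simulation and decomposition are computed once; a sweep
    over ``w`` additionally reuses the trained network and base
    reconstructions. Per-point failures are recorded and the sweep
    continues. Returns (rows, best) where best follows the tie-break:
    lowest AI mean, then lowest standard error, then smallest value.
    """
    if len(grid) != 1:
        raise ValueError("grid must sweep exactly one parameter")
    (param, values), = grid.items()
    if param not in ("mini_batch", "epochs", "w"):
        raise ValueError(f"unsupported sweep parameter {param!r}")
    if len(values) == 0:
        raise ValueError("sweep grid is empty")

    base = PipelineState(config)
    if use_cache:
        base.decompose()
        if param == "w":
            base.reconstruct()

    rows = []
    for val in values:
        try:
            if param == "w":
                cfg = replace(config, hybrid_w=float(val))
            elif param == "mini_batch":
                cfg = replace(config, training=replace(config.training, mini_batch=int(val)))
            else:
                cfg = replace(config, training=replace(config.training, epochs=int(val)))
            state = PipelineState(cfg)
            if use_cache:
                carry = ("attn", "phantom", "paths", "spec_low", "spec_high",
                         "stack_low", "stack_high", "sensitivity", "fractions", "stack_vm")
                for k in carry:
                    state.cache[k] = base.cache[k]
                state.timings["simulate"] = state.timings["decompose"] = 0.0
                if param == "w":
                    for k in ("model", "training_loss", "stack_residual", "stack_corrected",
                              "holdout_views", "train_views", "operator"):
                        state.cache[k] = base.cache[k]
                    vols = dict(base.cache["volumes"])
                    vols["DnCNN-MARHR"] = hybrid_mar(
                        vols["MLEM-corrected"], vols["BP-corrected"], float(val)
                    )
                    state.cache["volumes"] = vols
                    state.timings["correct"] = state.timings["reconstruct"] = 0.0
            state.evaluate()
            rep = state.cache["report"]
            ai = rep.ai["DnCNN-MARHR"]
            rows.append(
                {"param": param, "value": val, "ai_mean": ai["mean"], "ai_stderr": ai["stderr"], "error": None}
            )
        except Exception as exc:  # per-point failure: record and continue
            rows.append({"param": param, "value": val, "ai_mean": None, "ai_stderr": None, "error": str(exc)})

    ok = [r for r in rows if r["error"] is None]
    best = min(ok, key=lambda r: (r["ai_mean"], r["ai_stderr"], r["value"])) if ok else None
    return rows, best
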