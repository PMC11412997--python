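"""End-to-end orchestration: config, staged runs, manifests.

A run is a sequence of stages over one output directory::

    simulate -> tf -> rsm -> fit -> contrast -> geometry -> report

Every stage writes its artifacts under ``<out>/<stage>/`` plus the resolved
configuration, and appends checksums to ``<out>/manifest.json``. Stages are
idempotent given the same config and seed; a stage whose upstream artifacts
are missing fails with an error naming the stage to run first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fits, geometry, io, models, rsm, stats, synth, timefreq

logger = logging.getLogger("wmrsa")

STAGES = ("simulate", "tf", "rsm", "fit", "contrast", "geometry", "report")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    out_dir: str = "wmrsa_out"
    seed: int = 0
    n_subjects: int = 4
    n_channels: int = 8
    n_categories: int = 6
    n_exemplars: int = 10
    n_trials_per_session: int = 60
    n_sessions: int = 1
    effect_band: tuple[float, float] = (13.0, 29.0)
    effect_window: tuple[float, float] = (0.1, 0.7)
    effect_snr: float = 1.2
    item_effect_snr: float = 0.0
    maintenance_mix: float = 1.0
    epoch_span: tuple[float, float] = (-0.5, 1.5)
    window_width: float = 0.5
    window_step: float = 0.1
    contrast_band: str = "beta"
    n_perm: int = 200
    alpha_form: float = 0.05
    alpha: float = 0.05
    bonferroni_m: int = 1
    geometry_layers: int = 7
    geometry_timepoints: int = 8
    geometry_within: list = field(default_factory=lambda: [0.3] * 7)
    geometry_between: list = field(
        default_factory=lambda: [0.3, 0.25, 0.2, 0.15, 0.1, 0.05, 0.0]
    )
    geometry_noise_sd: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for key in ("effect_band", "effect_window", "epoch_span"):
            v = getattr(self, key)
            if len(v) != 2 or not v[0] < v[1]:
                raise ValueError(f"{key} must be an increasing (lo, hi) pair")
        if self.contrast_band not in timefreq.BAND_BOUNDS:
            raise ValueError(f"unknown band {self.contrast_band!r}")
        if len(self.geometry_within) != self.geometry_layers:
            raise ValueError("geometry_within must have geometry_layers entries")
        if len(self.geometry_between) != self.geometry_layers:
            raise ValueError("geometry_between must have geometry_layers entries")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("effect_band", "effect_window", "epoch_span"):
            d[key] = list(d[key])
        return d

    def synthetic_spec(self) -> synth.SyntheticSpec:
        return synth.SyntheticSpec(
            n_subjects=self.n_subjects,
            n_channels=self.n_channels,
            n_sessions=self.n_sessions,
            n_trials_per_session=self.n_trials_per_session,
            effect_band=tuple(self.effect_band),
            effect_window=tuple(self.effect_window),
            effect_snr=self.effect_snr,
            item_effect_snr=self.item_effect_snr,
            maintenance_mix=self.maintenance_mix,
            maintenance_window=tuple(self.effect_window),
            epoch_span=tuple(self.epoch_span),
            seed=self.seed,
        )


def _stage_dir(cfg: RunConfig, stage: str, create: bool = False) -> Path:
    p = Path(cfg.out_dir) / stage
    if create:
        p.mkdir(parents=True, exist_ok=True)
    return p


def _require(cfg: RunConfig, upstream: str, pattern: str) -> list[Path]:
    found = sorted(_stage_dir(cfg, upstream).glob(pattern))
    if not found:
        raise FileNotFoundError(
            f"missing upstream artifacts ({upstream}/{pattern}); "
            f"run stage {upstream!r} first"
        )
    return found


def _update_manifest(cfg: RunConfig, stage: str, paths: list[Path]) -> None:
    manifest_path = Path(cfg.out_dir) / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest[stage] = {
        str(p.relative_to(cfg.out_dir)): io.file_checksum(p) for p in sorted(paths)
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))


def _subject_rng(cfg: RunConfig, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, subject]))


def run_stage(stage: str, cfg: RunConfig) -> list[Path]:
    """Run one pipeline stage; returns the paths written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    io.write_json(out_root / "config.json", cfg.to_dict())
    logger.info("stage %s -> %s", stage, out_root / stage)
    written = globals()[f"_stage_{stage}"](cfg)
    _update_manifest(cfg, stage, written)
    return written


def run_all(cfg: RunConfig) -> dict[str, list[Path]]:
    return {stage: run_stage(stage, cfg) for stage in STAGES}


def _stage_simulate(cfg: RunConfig) -> list[Path]:
    d = _stage_dir(cfg, "simulate", create=True)
    stim = synth.make_stimulus_set(cfg.n_categories, cfg.n_exemplars)
    spec = cfg.synthetic_spec()
    written = []
    for s in range(cfg.n_subjects):
        rng = _subject_rng(cfg, s)
        table = synth.simulate_trial_table(stim, spec, rng=rng)
        sub = synth.simulate_epochs(table, spec, stim, mode="tf", rng=rng)
        paths = {
            "table": d / f"subj{s:02d}_trials.tsv",
            "enc": d / f"subj{s:02d}_encoding.h5",
            "mnt": d / f"subj{s:02d}_maintenance.h5",
        }
        io.save_trial_table(paths["table"], table)
        io.save_tfpower(paths["enc"], sub.encoding)
        io.save_tfpower(paths["mnt"], sub.maintenance)
        written.extend(paths.values())
    spec_path = d / "spec.json"
    io.write_json(spec_path, dataclasses.asdict(spec))
    written.append(spec_path)
    return written


def _stage_tf(cfg: RunConfig) -> list[Path]:
    _require(cfg, "simulate", "subj*_encoding.h5")
    d = _stage_dir(cfg, "tf", create=True)
    grid = timefreq.build_frequency_grid()
    bands = timefreq.assign_bands(grid)
    paths = [d / "grid.json", d / "bands.json"]
    io.write_json(paths[0], grid.to_dict())
    io.write_json(paths[1], bands.to_dict())
    return paths


def _stage_rsm(cfg: RunConfig) -> list[Path]:
    enc_paths = _require(cfg, "simulate", "subj*_encoding.h5")
    d = _stage_dir(cfg, "rsm", create=True)
    scheme = rsm.WindowScheme(cfg.window_width, cfg.window_step)
    written = []
    import h5py

    for enc_path in enc_paths:
        s = enc_path.stem.split("_")[0]
        power = io.load_tfpower(enc_path)
        meta = io.load_trial_table(enc_path.with_name(f"{s}_trials.tsv"))
        meta = meta[meta.phase == "encoding"].reset_index(drop=True)
        item_power = rsm.average_repetitions(power, meta, phase="encoding")
        stack, centers = fits.frequency_rsm_stack(item_power, scheme)
        out = d / f"{s}_rsm_stack.h5"
        with h5py.File(out, "w") as fh:
            fh.create_dataset("stack", data=stack, compression="gzip")
            fh["window_times"] = centers
            fh["frequencies"] = item_power.frequencies
            fh["items"] = item_power.items
            fh["categories"] = item_power.categories
        written.append(out)
    return written


def _load_stacks(cfg: RunConfig):
    import h5py

    stack_paths = _require(cfg, "rsm", "subj*_rsm_stack.h5")
    stacks, meta = [], None
    for p in stack_paths:
        with h5py.File(p, "r") as fh:
            stacks.append(fh["stack"][()])
            meta = dict(
                window_times=fh["window_times"][()],
                frequencies=fh["frequencies"][()],
                items=fh["items"][()],
                categories=fh["categories"][()],
            )
    return stacks, meta


def _cluster_rows(result: stats.ClusterResult) -> list[dict]:
    return [
        dict(
            cluster=i,
            mass=c.mass,
            p_corrected=c.p,
            n_cells=int(c.cells[0].size),
        )
        for i, c in enumerate(result.clusters)
    ]


def _stage_fit(cfg: RunConfig) -> list[Path]:
    import pandas as pd

    stacks, meta = _load_stacks(cfg)
    d = _stage_dir(cfg, "fit", create=True)
    stim = synth.make_stimulus_set(cfg.n_categories, cfg.n_exemplars)
    model = models.category_model(stim)
    fit = fits.model_fit_map(
        stacks,
        model,
        meta["categories"],
        meta["window_times"],
        meta["frequencies"],
        n_perm=cfg.n_perm,
        alpha_form=cfg.alpha_form,
        seed=cfg.seed,
    )
    paths = [d / "category_fit_clusters.tsv", d / "category_fit.json"]
    pd.DataFrame(_cluster_rows(fit.clusters)).to_csv(paths[0], sep="\t", index=False)
    io.write_json(
        paths[1],
        dict(
            model=fit.model_tag,
            n_subjects=len(stacks),
            n_perm=cfg.n_perm,
            max_t=float(np.nanmax(fit.t)),
            n_significant_clusters=len(fit.clusters.significant(cfg.alpha)),
        ),
    )
    return paths


def _stage_contrast(cfg: RunConfig) -> list[Path]:
    import pandas as pd

    enc_paths = _require(cfg, "simulate", "subj*_encoding.h5")
    d = _stage_dir(cfg, "contrast", create=True)
    grid = timefreq.build_frequency_grid()
    bands = timefreq.assign_bands(grid)
    scheme = rsm.WindowScheme(cfg.window_width, cfg.window_step)
    feats = []
    for enc_path in enc_paths:
        s = enc_path.stem.split("_")[0]
        power = io.load_tfpower(enc_path)
        meta = io.load_trial_table(enc_path.with_name(f"{s}_trials.tsv"))
        meta = meta[meta.phase == "encoding"].reset_index(drop=True)
        item_power = rsm.average_repetitions(power, meta, phase="encoding")
        feats.append(
            rsm.build_feature_series(
                item_power,
                scheme,
                scope=f"band:{cfg.contrast_band}",
                freq_indices=bands.members[cfg.contrast_band],
            )
        )
    ees = fits.category_contrast(
        feats, n_perm=cfg.n_perm, alpha_form=cfg.alpha_form, seed=cfg.seed
    )
    paths = [d / "ees_clusters.tsv", d / "ees.json"]
    pd.DataFrame(_cluster_rows(ees.clusters)).to_csv(paths[0], sep="\t", index=False)
    io.write_json(
        paths[1],
        dict(
            band=cfg.contrast_band,
            n_same_pairs=ees.n_same_pairs,
            n_diff_pairs=ees.n_diff_pairs,
            n_excluded_pairs=ees.n_excluded_pairs,
            n_significant_clusters=len(ees.clusters.significant(cfg.alpha)),
        ),
    )
    return paths


def _stage_geometry(cfg: RunConfig) -> list[Path]:
    import pandas as pd

    d = _stage_dir(cfg, "geometry", create=True)
    stim = synth.make_stimulus_set(cfg.n_categories, cfg.n_exemplars)
    schedule = synth.GeometrySchedule(
        n_layers=cfg.geometry_layers,
        n_timepoints=cfg.geometry_timepoints,
        within_by_layer=list(cfg.geometry_within),
        between_by_layer=list(cfg.geometry_between),
        noise_sd=cfg.geometry_noise_sd,
        seed=cfg.seed,
    )
    stack = synth.simulate_layered_rsms(schedule, stim)
    rows = []
    for li, mat in enumerate(stack.last_timepoints()):
        res = geometry.cci_permutation_test(
            mat, stim.category_of, n_perm=cfg.n_perm, seed=cfg.seed + li
        )
        rows.append(
            dict(
                layer=stack.layers[li],
                cci=res.cci,
                mean_within=res.mean_within,
                mean_between=res.mean_between,
                p=res.p,
                null_q95=res.null_q95,
            )
        )
    cci_df = pd.DataFrame(rows)
    bonf = stats.bonferroni(cci_df.p.to_numpy(), m=cfg.geometry_layers, alpha=cfg.alpha)
    cci_df["significant_bonferroni"] = bonf["significant"]
    slope = geometry.slope_analysis(stack, stim.category_of)
    paths = [d / "cci_profile.tsv", d / "slopes.json"]
    cci_df.to_csv(paths[0], sep="\t", index=False)
    io.write_json(
        paths[1],
        dict(
            mean_slope_within=slope.mean_within,
            mean_slope_between=slope.mean_between,
            t_within=slope.t_within,
            p_within=slope.p_within,
            t_between=slope.t_between,
            p_between=slope.p_between,
            n_rsms=stack.n_rsms,
        ),
    )
    return paths


def _stage_report(cfg: RunConfig) -> list[Path]:
    out_root = Path(cfg.out_dir)
    report = {"config": cfg.to_dict(), "stages": {}}
    for stage in STAGES[:-1]:
        stage_dir = out_root / stage
        if not stage_dir.exists():
            raise FileNotFoundError(
                f"missing upstream artifacts ({stage}); run stage {stage!r} first"
            )
        for p in sorted(stage_dir.glob("*.json")):
            report["stages"].setdefault(stage, {})[p.name] = json.loads(
                p.read_text()
            )
    path = out_root / "report.json"
    io.write_json(path, report)
    return [path]
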