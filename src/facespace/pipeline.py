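"""End-to-end orchestration: faces -> space -> stimuli -> design ->
simulate -> preprocess -> ROIs -> univariate -> MVPA -> group stats.

Stages are computed in dependency order from a single seeded config;
stage toggles control which outputs are *written*, while upstream
dependencies are recomputed deterministically in memory, so rerunning
with the same config is byte-identical for the deterministic stages.
Every stage output directory carries a provenance JSON naming the seed,
the config hash and its input stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boldsim, design, faces, glm, mvpa, preprocess, space, stats, univariate

STAGES = (
    "faces",
    "space",
    "stimuli",
    "design",
    "simulate",
    "preprocess",
    "rois",
    "univariate",
    "mvpa",
    "stats",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # faces / space
    n_per_class: int = 20
    classes: tuple[str, ...] = ("A", "B")
    canvas: tuple[int, int] = (100, 120)  # width, height
    n_components: int | str = "max"
    # stimuli
    stim_components: int = 3
    boundary_mean: float = 4.0
    boundary_sd: float = 1.0
    feather_px: int = 5
    # design / simulation
    tr: float = 2.0
    n_subjects: int = 4
    scans_per_subject: int = 2
    n_voxels: int = 24
    noise_sd: float = 0.5
    pattern_strength: float = 0.4
    profiles: dict = field(
        default_factory=lambda: {
            "l_ffa": {"kind": "flat", "baseline": 0.5},
            "r_ffa": {"kind": "ramp", "baseline": 0.5, "slope": 0.1},
        }
    )
    # preprocessing / analysis
    highpass_hz: float = 0.01
    n_lags: int = 8
    fwe_method: str = "bonferroni"
    alpha: float = 0.05
    lattice_shape: tuple[int, int, int] = (10, 10, 4)
    localiser_effect_pct: float = 2.0
    localiser_noise_sd: float = 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["classes"] = list(self.classes)
        d["canvas"] = list(self.canvas)
        d["lattice_shape"] = list(self.lattice_shape)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _provenance(cfg: PipelineConfig, stage: str, inputs: list[str]) -> dict:
    return {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "inputs": inputs,
    }


def _write_prov(path: Path, cfg: PipelineConfig, stage: str, inputs: list[str]) -> None:
    path.mkdir(parents=True, exist_ok=True)
    (path / "provenance.json").write_text(
        json.dumps(_provenance(cfg, stage, inputs), indent=2, sort_keys=True)
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    ss = np.random.SeedSequence(cfg.seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    want = set(cfg.stages)
    unknown = want - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    w, h = cfg.canvas

    # --- faces ---------------------------------------------------------
    faces_dir = out / "faces"
    need_faces = bool(want & {"faces", "space", "stimuli"})
    manifest = None
    if need_faces:
        if "faces" in want:
            manifest = faces.generate_dataset(
                cfg.n_per_class, cfg.classes, faces_dir, seed=seeds[0],
                width=w, height=h, overwrite=True,
            )
            _write_prov(faces_dir, cfg, "faces", [])
        else:
            import tempfile

            tmp = Path(tempfile.mkdtemp())
            manifest = faces.generate_dataset(
                cfg.n_per_class, cfg.classes, tmp, seed=seeds[0],
                width=w, height=h, overwrite=True,
            )
            faces_dir = tmp

    # --- space ---------------------------------------------------------
    model = None
    if want & {"space", "stimuli"}:
        import imageio.v3 as iio

        cls = cfg.classes[0]
        lms = faces.load_landmarks(faces_dir / f"landmarks_{cls}.tsv")
        sub = manifest[manifest["class"] == cls]
        imgs = [iio.imread(faces_dir / f).astype(float) / 255.0 for f in sub["file"]]
        lsets = [lms[f] for f in sub["file"]]
        vectors, avg_lms = space.vectorize_faces(imgs, lsets)
        model = space.build_face_space(vectors, k=cfg.n_components)
        if "space" in want:
            sdir = out / "space"
            sdir.mkdir(exist_ok=True)
            model.save(sdir / "model.npz")
            coords = np.stack([space.project(v, model) for v in vectors])
            pd.DataFrame(
                coords, columns=[f"pc{i + 1}" for i in range(model.k)]
            ).assign(file=list(sub["file"])).to_csv(
                sdir / "coords.tsv", sep="\t", index=False
            )
            _write_prov(sdir, cfg, "space", ["faces"])

    # --- stimuli -------------------------------------------------------
    if "stimuli" in want:
        import imageio.v3 as iio

        stim_dir = out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        cset = design.caricature_condition_set(
            cfg.boundary_mean, cfg.boundary_sd, components=cfg.stim_components
        )
        rendered = {}
        rows = []
        for row in cset.itertuples():
            coords = np.zeros(cfg.stim_components)
            coords[row.component - 1] = row.level_sd
            img = space.render_face(space.synthesize(coords, model))
            stim = space.prepare_stimulus(
                img,
                orientation=row.orientation,
                feather_px=cfg.feather_px,
            )
            fname = f"{row.trial_type}.png"
            iio.imwrite(stim_dir / fname, (np.clip(stim, 0, 1) * 255).round().astype(np.uint8))
            rendered[row.trial_type] = stim
            rows.append({"file": fname, **row._asdict()})
        mask = space.make_noise_mask(list(rendered.values()), (h, w, 1), seed=seeds[1])
        iio.imwrite(stim_dir / "noise_mask.png", (np.atleast_3d(mask)[..., 0] * 255).round().astype(np.uint8))
        pd.DataFrame(rows).drop(columns=["Index"]).to_csv(
            stim_dir / "levels.tsv", sep="\t", index=False
        )
        _write_prov(stim_dir, cfg, "stimuli", ["space"])

    # --- design --------------------------------------------------------
    cset = design.caricature_condition_set(
        cfg.boundary_mean, cfg.boundary_sd, components=cfg.stim_components
    )
    if "design" in want:
        ddir = out / "design"
        ddir.mkdir(exist_ok=True)
        cset.to_csv(ddir / "conditions.tsv", sep="\t", index=False)
        sched = design.event_related_schedule(cset, tr=cfg.tr, seed=seeds[2])
        sched.to_tsv(ddir / "caricature_run.tsv")
        loc = design.localiser_schedule(tr=cfg.tr, seed=seeds[2])
        loc.to_tsv(ddir / "localiser_run.tsv")
        trials = design.behavioural_trial_list(seed=seeds[2])
        trials.to_csv(ddir / "behavioural_trials.tsv", sep="\t")
        _write_prov(ddir, cfg, "design", [])

    # --- simulate ------------------------------------------------------
    profiles = {
        roi: boldsim.TuningProfile(**p) for roi, p in cfg.profiles.items()
    }
    need_sim = bool(want & {"simulate", "preprocess", "univariate", "mvpa", "stats"})
    study = None
    if need_sim:
        study = boldsim.simulate_study(
            profiles=profiles,
            n_subjects=cfg.n_subjects,
            scans_per_subject=cfg.scans_per_subject,
            condition_set=cset,
            n_voxels=cfg.n_voxels,
            pattern_strength=cfg.pattern_strength,
            noise_sd=cfg.noise_sd,
            seed=seeds[3],
        )
        if "simulate" in want:
            simdir = out / "sim"
            simdir.mkdir(exist_ok=True)
            study.save_ground_truth(simdir / "ground_truth.json")
            for (s, roi), runs in study.runs.items():
                for r in runs:
                    r.schedule.to_tsv(simdir / f"sub{s}_{roi}_scan{r.scan_id}_events.tsv")
            _write_prov(simdir, cfg, "simulate", ["design"])

    # --- preprocess ----------------------------------------------------
    pre: dict = {}
    if need_sim:
        for key, runs in study.runs.items():
            data, trans, per_run = preprocess.preprocess_runs(runs, cfg.highpass_hz)
            pre[key] = (data, trans, per_run, [r.schedule for r in runs])
        if "preprocess" in want:
            pdir = out / "preproc"
            pdir.mkdir(exist_ok=True)
            summary = [
                {
                    "subject": s,
                    "roi": roi,
                    "n_voxels": d[0].shape[0],
                    "n_trs": d[0].shape[1],
                    "transitions": json.dumps(d[1]),
                }
                for (s, roi), d in pre.items()
            ]
            pd.DataFrame(summary).to_csv(pdir / "preproc_summary.tsv", sep="\t", index=False)
            _write_prov(pdir, cfg, "preprocess", ["simulate"])

    # --- rois (synthetic localiser lattice) ----------------------------
    if "rois" in want:
        rng = np.random.default_rng(seeds[4])
        shape = cfg.lattice_shape
        anat = np.zeros(shape, dtype=bool)
        anat[1:-1, 1:-1, :] = True
        masks = {}
        centers = {"faces": (3, 3), "objects": (6, 6), "scenes": (3, 7)}
        for cat, (cx, cy) in centers.items():
            m = np.zeros(shape, dtype=bool)
            m[cx : cx + 2, cy : cy + 2, 1:3] = True
            masks[cat] = m & anat
        loc_scheds = [
            design.localiser_schedule(tr=cfg.tr, seed=seeds[4] + i) for i in range(2)
        ]
        Y = np.concatenate(
            [
                boldsim.simulate_localiser_lattice(
                    shape, masks, s,
                    effect_pct=cfg.localiser_effect_pct,
                    noise_sd=cfg.localiser_noise_sd,
                    seed=seeds[4] + 10 + i,
                )
                for i, s in enumerate(loc_scheds)
            ],
            axis=1,
        )
        filt = preprocess.highpass_matrix(loc_scheds[0].n_volumes, cfg.tr, cfg.highpass_hz)
        n0 = loc_scheds[0].n_volumes
        Yp = np.concatenate(
            [
                (100.0 * (Y[:, i * n0 : (i + 1) * n0] - Y[:, i * n0 : (i + 1) * n0].mean(1, keepdims=True))
                 / Y[:, i * n0 : (i + 1) * n0].mean(1, keepdims=True)) @ filt.T
                for i in range(2)
            ],
            axis=1,
        )
        rois, ztable = glm.localiser_roi_pipeline(
            Yp, loc_scheds,
            anatomical_mask=anat,
            lattice_shape=shape,
            alpha=cfg.alpha,
            fwe_method=cfg.fwe_method,
            filter_matrix=filt,
        )
        rdir = out / "rois"
        rdir.mkdir(exist_ok=True)
        idx = np.arange(int(np.prod(shape)))
        coords = np.stack(np.unravel_index(idx, shape), axis=1)
        df = pd.DataFrame(coords, columns=["x", "y", "z"])
        df["label"] = rois.labels
        df["ffa"] = rois.ffa_mask if rois.ffa_mask is not None else False
        for cat in ztable.columns:
            df[f"z_{cat}"] = ztable[cat].to_numpy()
        truth = np.full(idx.size, "none", dtype=object)
        for cat, m in masks.items():
            truth[m.reshape(-1)] = {"faces": "face", "objects": "object", "scenes": "scene"}[cat]
        df["true_label"] = truth
        df.to_csv(rdir / "voxel_labels.tsv", sep="\t", index=False)
        glm.save_lattice_nifti(
            ztable["faces"].to_numpy(), shape, rdir / "z_faces.nii.gz"
        )
        glm.save_lattice_nifti(
            (rois.ffa_mask if rois.ffa_mask is not None else np.zeros(idx.size)).astype(float),
            shape,
            rdir / "ffa_mask.nii.gz",
        )
        _write_prov(rdir, cfg, "rois", ["design"])

    # --- univariate (level-pooled: 7 analysis conditions) --------------
    amp_rows = []
    level_table = cset[["level_label", "level_offset", "orientation"]].drop_duplicates()
    level_conds = list(level_table["level_label"])
    if want & {"univariate", "stats"}:
        for (s, roi), (data, trans, per_run, scheds) in pre.items():
            pooled = [design.pool_by_level(sch) for sch in scheds]
            filt = preprocess.highpass_matrix(scheds[0].n_volumes, cfg.tr, cfg.highpass_hz)
            X = univariate.build_fir_design(
                pooled, n_lags=cfg.n_lags, conditions=level_conds, filter_matrix=filt
            )
            fir = univariate.deconvolve_roi(data, X, level_conds, cfg.n_lags, tr=cfg.tr)
            for cond, val in univariate.amplitude_indices(fir).items():
                amp_rows.append({"subject": s, "roi": roi, "condition": cond, "index": val})
        amp = pd.DataFrame(amp_rows).merge(
            level_table, left_on="condition", right_on="level_label"
        )
        if "univariate" in want:
            udir = out / "univariate"
            udir.mkdir(exist_ok=True)
            amp.drop(columns=["level_label"]).to_csv(
                udir / "amplitudes.tsv", sep="\t", index=False
            )
            _write_prov(udir, cfg, "univariate", ["preprocess"])

    # --- mvpa ----------------------------------------------------------
    if "mvpa" in want:
        mdir = out / "mvpa"
        mdir.mkdir(exist_ok=True)
        upright = list(
            level_table.loc[level_table["orientation"] == "upright", "level_label"]
        )
        frames = []
        summaries_by_roi: dict[str, list] = {}
        for (s, roi), (data, trans, per_run, scheds) in pre.items():
            pooled = [design.pool_by_level(sch) for sch in scheds]
            filt = preprocess.highpass_matrix(scheds[0].n_volumes, cfg.tr, cfg.highpass_hz)
            pats = mvpa.subject_beta_patterns(
                [r.data for r in per_run], pooled,
                upright_conditions=upright, filter_matrix=filt, roi=roi,
            )
            summ = mvpa.cross_scan_correlation(pats)
            frames.append(summ.to_frame(subject=s, roi=roi))
            summaries_by_roi.setdefault(roi, []).append(summ)
        pd.concat(frames).to_csv(mdir / "correlations.tsv", sep="\t", index=False)
        group_rows = []
        for roi, summs in summaries_by_roi.items():
            if len(summs) >= 3:
                rep = mvpa.mvpa_group_tests(summs)
                cells = rep["cells"].assign(roi=roi)
                group_rows.append(cells)
                trend = rep["diagonal_trend"]
                (mdir / f"group_trend_{roi}.json").write_text(
                    json.dumps(vars(trend), indent=2)
                )
        if group_rows:
            pd.concat(group_rows).to_csv(mdir / "group_cells.tsv", sep="\t", index=False)
        _write_prov(mdir, cfg, "mvpa", ["preprocess"])

    # --- stats ---------------------------------------------------------
    if "stats" in want and amp_rows:
        stdir = out / "stats"
        stdir.mkdir(exist_ok=True)
        amp = pd.DataFrame(amp_rows).merge(
            level_table, left_on="condition", right_on="level_label"
        )
        hemi = amp["roi"].str.extract(r"^(l|r)_", expand=False).fillna("r")
        amp["hemisphere"] = hemi.map({"l": "left", "r": "right"})
        results = stats.caricature_anovas(amp)
        pd.concat(
            [r.to_frame().assign(analysis=name) for name, r in results.items()]
        ).to_csv(stdir / "anova.tsv", sep="\t", index=False)
        up = amp[amp["orientation"] == "upright"]
        wide = up.pivot_table(index="subject", columns="level_offset", values="index")
        trend = stats.linear_trend(wide.to_numpy())
        (stdir / "linear_trend.json").write_text(json.dumps(vars(trend), indent=2))
        _write_prov(stdir, cfg, "stats", ["univariate"])

    return out


def report(run_dir: str | Path, out_subdir: str = "report") -> Path:
    """Summary figures + figure-data TSVs from a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    rep = run / out_subdir
    missing = [
        s for s in ("rois", "univariate", "mvpa", "stats")
        if not (run / s).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    rep.mkdir(exist_ok=True)

    vox = pd.read_csv(run / "rois" / "voxel_labels.tsv", sep="\t")
    z_slice = vox[vox["z"] == 1].pivot_table(index="x", columns="y", values="z_faces")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(z_slice.to_numpy(), cmap="hot")
    fig.colorbar(im, ax=ax, label="Z (faces > objects + scenes)")
    ax.set_title("Localiser face contrast, lattice slice z=1")
    fig.savefig(rep / "fig_roi_map.png", dpi=120)
    plt.close(fig)
    vox.to_csv(rep / "fig_roi_map.tsv", sep="\t", index=False)

    amp = pd.read_csv(run / "univariate" / "amplitudes.tsv", sep="\t")
    up = amp[amp["orientation"] == "upright"]
    g = up.groupby(["roi", "level_offset"])["index"].mean().reset_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    for roi, grp in g.groupby("roi"):
        ax.bar(
            [f"{o:+d}SD\n{roi}" for o in grp["level_offset"]],
            grp["index"],
            label=roi,
        )
    ax.set_ylabel("MSD amplitude index (% signal)")
    ax.set_title("Response amplitude by caricature level")
    fig.tight_layout()
    fig.savefig(rep / "fig_amplitudes.png", dpi=120)
    plt.close(fig)
    g.to_csv(rep / "fig_amplitudes.tsv", sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    for (roi, subj), grp in up.groupby(["roi", "subject"]):
        grp = grp.sort_values("level_offset")
        ax.plot(grp["level_offset"], grp["index"], marker="o", alpha=0.5,
                label=f"{roi} sub{subj}")
    ax.set_xlabel("caricature level offset (SD)")
    ax.set_ylabel("MSD amplitude index")
    ax.set_title("Per-subject amplitude index by level")
    ax.legend(fontsize=5)
    fig.tight_layout()
    fig.savefig(rep / "fig_fir_index.png", dpi=120)
    plt.close(fig)
    up.to_csv(rep / "fig_fir_index.tsv", sep="\t", index=False)

    corr = pd.read_csv(run / "mvpa" / "correlations.tsv", sep="\t")
    roi0 = corr["roi"].iloc[-1]
    mean_z = (
        corr[corr["roi"] == roi0]
        .pivot_table(index="level_i", columns="level_j", values="mean_z")
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mean_z.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(mean_z.columns)), mean_z.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(mean_z.index)), mean_z.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="mean Fisher Z")
    ax.set_title(f"Between-scan pattern similarity ({roi0})")
    fig.tight_layout()
    fig.savefig(rep / "fig_mvpa_matrix.png", dpi=120)
    plt.close(fig)
    mean_z.to_csv(rep / "fig_mvpa_matrix.tsv", sep="\t")

    return rep
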