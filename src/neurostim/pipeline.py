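"""End-to-end orchestration of the two-session in-silico experiment.

A single seeded configuration drives nine stages:

    simulate      -> stimulus pool + ground-truth cohorts (gains calibrated)
    fit-encoders  -> per base subject and region, grid-searched fwRF models
    build-group   -> group (prediction-averaged) model per region
    select        -> Max/Avg natural condition sets per region
    synthesize    -> Max/Avg synthetic condition sets per region
    session1      -> Session-1 manifest + simulated trial table
    personalize   -> per novel subject, linear-ensemble encoding model
    session2      -> per-subject Session-2 sets, manifests and trials
    stats         -> LME contrasts, permutation p, FDR, Cohen's d,
                     accuracies, similarity matrices, hierarchy trend

Each stage reads its inputs from, and writes its outputs to, a workspace
directory, so stages can be re-run individually; every output file is
content-hashed into a JSON run manifest and all randomness derives from
the master seed.  Defaults are desk scale: they preserve the experimental
arithmetic (40-image condition sets, 4 conditions x 3 regions in Session 1,
128 images over six conditions in Session 2, 32-per-cell training split)
over a reduced image pool, a compact feature bank and a small generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import fwrf, selection, stats, synthesis
from . import synthetic_data as synth_data
from .synthetic_data import SessionDesign, SetEntry

log = logging.getLogger("neurostim")

STAGES = ("simulate", "fit-encoders", "build-group", "select", "synthesize",
          "session1", "personalize", "session2", "stats")

_S1_CONTRASTS = [("GroupAvgSyn", "GroupMaxSyn"), ("GroupAvgNat", "GroupMaxNat"),
                 ("GroupMaxNat", "GroupMaxSyn"), ("GroupAvgNat", "GroupAvgSyn")]
_S2_CONTRASTS = [("OtherMaxSyn", "SelfMaxSyn"), ("GroupMaxSyn", "SelfMaxSyn"),
                 ("OtherMaxNat", "SelfMaxNat"), ("GroupMaxNat", "SelfMaxNat"),
                 ("SelfMaxNat", "SelfMaxSyn")]


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the full in-silico experiment."""

    seed: int = 0
    outdir: str = "runs/demo"
    image_side: int = 64
    bank_seed: int = 0

    # cohorts and pool
    n_base_subjects: int = 8
    n_novel_subjects: int = 6
    n_unique_per_subject: int = 80
    n_shared: int = 40
    n_classes: int = 12
    regions: tuple[str, ...] = ("FFA1", "EBA", "VWFA1")
    base_shared_tuning: float = 0.5
    base_noise: tuple[float, float] = (0.2, 0.5)
    novel_shared_tuning: float = 0.5
    novel_noise: tuple[float, float] = (0.35, 1.2)

    # encoder fitting
    k_top: int = 24
    center_spacing: float = 1.4
    n_radii: int = 8
    r_min: float = 0.04
    r_max: float = 0.4
    n_lambdas: int = 9
    lam_min: float = 1e-6
    lam_max: float = 1e2

    # condition sets and sessions
    set_size: int = 40
    session1_repeats: int = 2
    session2_repeats: int = 2
    session2_counts: tuple[int, int, int] = (32, 20, 12)
    n_train_per_cell: int = 32

    # synthesis
    n_gen_classes: int = 8
    noise_dim: int = 6
    synth_steps: int = 60
    synth_step_size: float = 0.3
    n_probe_per_class: int = 100
    n_top_classes: int = 4
    reg_weight: float = 0.01

    # statistics
    n_perm: int = 1000
    fdr_q: float = 0.05

    write_pngs: bool = True

    @property
    def personalize_region(self) -> str:
        return self.regions[0]

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw = raw.get("pipeline", raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def nsd_scale(self) -> dict:
        """The full-scale (not desk-scale) design constants, for reference:
        cohort, pool, grid and split sizes at the sizes of the original
        datasets."""
        return {
            "n_base_subjects": 8, "n_novel_subjects": 6,
            "n_unique_per_subject": 9000, "n_shared": 1000,
            "n_validation_pairs": 3000, "k_top": 512,
            "lam_min": 1e3, "lam_max": 1e7,
            "n_probe_classes": 1000, "set_size": 40,
        }


def seed_for(cfg: PipelineConfig, tag: int) -> int:
    return int(np.random.SeedSequence([cfg.seed, tag]).generate_state(1)[0]
               % (2**31))


# ---------------------------------------------------------------------------
# Workspace
# ---------------------------------------------------------------------------

class Workspace:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.root = Path(cfg.outdir)
        self.root.mkdir(parents=True, exist_ok=True)

    def path(self, *parts) -> Path:
        p = self.root.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def require(self, relpath: str, produced_by: str) -> Path:
        p = self.root / relpath
        if not p.exists():
            raise StageError(f"missing {relpath!r}; run stage "
                             f"{produced_by!r} first")
        return p

    # -- manifest ----------------------------------------------------------
    def _manifest_path(self) -> Path:
        return self.root / "run_manifest.json"

    def record(self, stage: str, files: list[Path], seed: int,
               wall_clock: float) -> None:
        mpath = self._manifest_path()
        manifest = (json.loads(mpath.read_text()) if mpath.exists()
                    else {"stages": {}})
        hashes = {}
        for f in sorted(files):
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            hashes[str(f.relative_to(self.root))] = digest
        manifest["stages"][stage] = {
            "seed": seed, "wall_clock_s": round(wall_clock, 3),
            "files": hashes,
        }
        tmp = mpath.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        tmp.replace(mpath)

    def manifest(self) -> dict:
        return json.loads(self._manifest_path().read_text())


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False)
    tmp.replace(path)
    return path

def _write_json(obj, path: Path) -> Path:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=1, sort_keys=True))
    tmp.replace(path)
    return path


# ---------------------------------------------------------------------------
# Shared loaders (stages re-derive deterministic objects from stored params)
# ---------------------------------------------------------------------------

def _bank(cfg: PipelineConfig) -> fwrf.FeatureBank:
    return fwrf.default_bank(cfg.bank_seed, cfg.image_side)

def _grid(cfg: PipelineConfig) -> fwrf.HyperGrid:
    return fwrf.build_hypergrid(
        spacing=cfg.center_spacing, n_radii=cfg.n_radii, r_min=cfg.r_min,
        r_max=cfg.r_max, n_lambdas=cfg.n_lambdas, lam_min=cfg.lam_min,
        lam_max=cfg.lam_max)

def _generator(cfg: PipelineConfig) -> synthesis.GeneratorSpec:
    return synthesis.GeneratorSpec(n_classes=cfg.n_gen_classes,
                                   noise_dim=cfg.noise_dim,
                                   side=cfg.image_side,
                                   seed=seed_for(cfg, 50))

def _load_pool(ws: Workspace) -> synth_data.StimulusPool:
    params = json.loads(ws.require("pool.json", "simulate").read_text())
    return synth_data.make_pool(**params)

def _spec_to_json(s: synth_data.VirtualSubjectSpec) -> dict:
    return {"subject_id": s.subject_id,
            "tuning_weights": s.tuning_weights.tolist(),
            "pooling_center": list(s.pooling_center),
            "pooling_radius": s.pooling_radius,
            "noise_sd": s.noise_sd, "gain": s.gain}

def _spec_from_json(d: dict) -> synth_data.VirtualSubjectSpec:
    return synth_data.VirtualSubjectSpec(
        subject_id=d["subject_id"],
        tuning_weights=np.asarray(d["tuning_weights"]),
        pooling_center=tuple(d["pooling_center"]),
        pooling_radius=d["pooling_radius"],
        noise_sd=d["noise_sd"], gain=d["gain"])

def _load_cohorts(ws: Workspace) -> dict:
    raw = json.loads(ws.require("cohort.json", "simulate").read_text())
    return {region: {kind: [_spec_from_json(d) for d in specs]
                     for kind, specs in kinds.items()}
            for region, kinds in raw.items()}

def _load_base_models(ws: Workspace, cfg: PipelineConfig, region: str
                      ) -> list[fwrf.EncodingModel]:
    models = []
    for i in range(cfg.n_base_subjects):
        p = ws.require(f"models/{region}_base{i:02d}.h5", "fit-encoders")
        models.append(fwrf.load_encoding_model(str(p)))
    return models

def _load_group_model(ws: Workspace, cfg: PipelineConfig, region: str
                      ) -> fwrf.GroupModel:
    ws.require(f"models/group_{region}.json", "build-group")
    return fwrf.make_group_model(_load_base_models(ws, cfg, region))

def _pool_index(pool: synth_data.StimulusPool) -> dict:
    return {s.image_id: s for s in pool.stimuli}

def _load_natural_sets(ws: Workspace, pool_idx: dict, region: str
                       ) -> dict[str, selection.StimulusSet]:
    p = ws.require(f"sets/natural_{region}.tsv", "select")
    df = pd.read_csv(p, sep="\t")
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        stimuli = [pool_idx[i].relabeled(condition=cond, target_region=region)
                   for i in grp["image_id"]]
        out[cond] = selection.StimulusSet(
            condition=cond, provider=f"group-{region}", stimuli=stimuli,
            predictions=grp["prediction"].to_numpy())
    return out

def _load_synth_set(ws: Workspace, cfg: PipelineConfig, name: str,
                    condition: str, region: str) -> selection.StimulusSet:
    p = ws.require(f"sets/synth_{name}.tsv", "synthesize")
    df = pd.read_csv(p, sep="\t")
    gen = _generator(cfg)
    stimuli = []
    for _, row in df.iterrows():
        z = np.fromstring(row["z_final"], sep=",")
        pix = gen.render(int(row["class_id"]), z)
        stimuli.append(synth_data.ImageStim.from_pixels(
            row["image_id"], pix, source="synthetic", condition=condition,
            target_region=region, class_label=int(row["class_id"])))
    return selection.StimulusSet(condition=condition, provider=name,
                                 stimuli=stimuli,
                                 predictions=df["predicted_activation"].to_numpy())


def _calibration_stimuli(pool: synth_data.StimulusPool, n: int = 160):
    shared = pool.shared
    unique = pool.unique
    return (shared + unique)[:max(n, len(shared))]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    pool_params = dict(n_subjects=cfg.n_base_subjects,
                       n_unique_per_subject=cfg.n_unique_per_subject,
                       n_shared=cfg.n_shared, n_classes=cfg.n_classes,
                       seed=seed_for(cfg, 1), side=cfg.image_side)
    pool = synth_data.make_pool(**pool_params)
    bank = _bank(cfg)
    grid = _grid(cfg)
    calib = _calibration_stimuli(pool)
    calib_levels = fwrf._extract_batch(
        np.asarray([s.pixels for s in calib]), bank)
    cohorts = {}
    novel_noise = np.linspace(cfg.novel_noise[0], cfg.novel_noise[1],
                              cfg.n_novel_subjects)
    for ri, region in enumerate(cfg.regions):
        # one canonical pooling field per region: regional retinotopy is
        # consistent across subjects, which is what makes a group model
        # informative for a novel individual
        frng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 90, ri]))
        central = [c for c in grid.centers
                   if abs(c[0]) <= 2.9 and abs(c[1]) <= 2.9]
        region_center = [central[frng.integers(len(central))]]
        region_radius = [grid.radii[frng.integers(2, len(grid.radii))]]
        # one population tuning direction per region, shared between the
        # base and the novel cohorts; all tuning draws are shaped by the
        # stimulus feature covariance at the region's field
        region_field = fwrf.PoolingField(region_center[0], region_radius[0])
        cov = synth_data.feature_covariance(calib, bank, region_field,
                                            levels=calib_levels)
        w_region = cov @ frng.standard_normal(bank.n_channels_total)
        base = synth_data.make_virtual_cohort(
            cfg.n_base_subjects, cfg.base_shared_tuning, cfg.base_noise,
            seed_for(cfg, 100 + ri), n_channels=bank.n_channels_total,
            id_prefix="base", center_choices=region_center,
            radius_choices=region_radius, common_direction=w_region,
            shape_matrix=cov)
        novel = synth_data.make_virtual_cohort(
            cfg.n_novel_subjects, cfg.novel_shared_tuning, cfg.novel_noise,
            seed_for(cfg, 200 + ri), n_channels=bank.n_channels_total,
            id_prefix="novel", center_choices=region_center,
            radius_choices=region_radius, noise_sds=novel_noise,
            common_direction=w_region, shape_matrix=cov)
        synth_data.calibrate_gains(base + novel, calib, bank)
        cohorts[region] = {"base": base, "novel": novel}
    files = [
        _write_json(pool_params, ws.path("pool.json")),
        _write_json({region: {k: [_spec_to_json(s) for s in v]
                              for k, v in kinds.items()}
                     for region, kinds in cohorts.items()},
                    ws.path("cohort.json")),
    ]
    rows = [{"image_id": s.image_id, "owner": pool.ownership[s.image_id],
             "class_label": s.class_label} for s in pool.stimuli]
    files.append(_write_tsv(pd.DataFrame(rows), ws.path("pool_manifest.tsv")))
    log.info("simulate: pool of %d images, %d regions",
             len(pool.stimuli), len(cfg.regions))
    return files


def stage_fit_encoders(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    pool = _load_pool(ws)
    cohorts = _load_cohorts(ws)
    bank, grid = _bank(cfg), _grid(cfg)
    files = []
    for ri, region in enumerate(cfg.regions):
        for i, spec in enumerate(cohorts[region]["base"]):
            train_imgs = pool.owned_by(i)
            val_imgs = pool.shared
            table = synth_data.simulate_responses(
                [spec], train_imgs + val_imgs, region, 1, bank,
                seed=seed_for(cfg, 300 + 10 * ri + i))
            resp = table.set_index("image_id")["response"]
            # z-score the subject's responses before fitting (the real
            # betas enter the model on a normalized scale)
            resp = (resp - resp.mean()) / resp.std(ddof=0)
            y_tr = resp.loc[[s.image_id for s in train_imgs]].to_numpy()
            y_va = resp.loc[[s.image_id for s in val_imgs]].to_numpy()
            model = fwrf.grid_search_fit(
                (train_imgs, y_tr), (val_imgs, y_va), bank, cfg.k_top, grid,
                region=region, subject_id=spec.subject_id)
            out = ws.path("models", f"{region}_base{i:02d}.h5")
            fwrf.save_encoding_model(model, str(out))
            files.extend([out, Path(str(out) + ".json")])
            log.info("fit %s/%s: val r=%.3f center=%s radius=%.3f",
                     region, spec.subject_id, model.val_accuracy,
                     model.field.center, model.field.radius)
    return files


def stage_build_group(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    files = []
    for region in cfg.regions:
        base_files = [f"models/{region}_base{i:02d}.h5"
                      for i in range(cfg.n_base_subjects)]
        for bf in base_files:
            ws.require(bf, "fit-encoders")
        group = fwrf.make_group_model(_load_base_models(ws, cfg, region))
        files.append(_write_json(
            {"region": region, "base_models": base_files,
             "n_models": len(group.base_models)},
            ws.path("models", f"group_{region}.json")))
    return files


def stage_select(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    pool = _load_pool(ws)
    bank = _bank(cfg)
    natural = pool.unique          # shared images are excluded by design
    px = np.asarray([s.pixels for s in natural])
    levels = fwrf._extract_batch(px, bank)
    spare = cfg.session2_counts[2] + cfg.session2_counts[0]
    files = []
    used: set[str] = set()       # keep the regions' natural sets disjoint
    for region in cfg.regions:
        model = _load_group_model(ws, cfg, region)
        preds = fwrf.predict_from_levels(model, levels)
        avail = [i for i, s in enumerate(natural) if s.image_id not in used]
        n_max = min(cfg.set_size + spare, len(avail) - cfg.set_size)
        max_set = selection.select_max(
            [natural[i] for i in avail], model, n_max,
            condition="GroupMaxNat", predictions=preds[avail])
        keep = set(max_set.image_ids[:cfg.set_size])
        rest_idx = [i for i in avail
                    if natural[i].image_id not in keep]
        avg_set = selection.select_avg(
            [natural[i] for i in rest_idx], model, cfg.set_size,
            condition="GroupAvgNat", predictions=preds[rest_idx])
        used |= keep | set(avg_set.image_ids)
        rows = []
        for st in (max_set, avg_set):
            for s, p in zip(st.stimuli, st.predictions):
                rows.append({"condition": st.condition, "image_id": s.image_id,
                             "prediction": p})
        files.append(_write_tsv(pd.DataFrame(rows),
                                ws.path("sets", f"natural_{region}.tsv")))
        log.info("select %s: MaxNat mean pred %.3f, AvgNat mean |pred| %.3f",
                 region, max_set.predictions[:cfg.set_size].mean(),
                 np.abs(avg_set.predictions).mean())
    return files


def stage_synthesize(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    gen = _generator(cfg)
    files = []
    for ri, region in enumerate(cfg.regions):
        model = _load_group_model(ws, cfg, region)
        scfg = synthesis.SynthesisConfig(
            reg_weight=cfg.reg_weight, n_probe_per_class=cfg.n_probe_per_class,
            n_top_classes=cfg.n_top_classes, steps=cfg.synth_steps,
            step_size=cfg.synth_step_size, seed=seed_for(cfg, 400 + ri))
        probe = synthesis.probe_classes(gen, model, cfg.n_probe_per_class,
                                        scfg.seed)
        for mode, cond in (("Max", "GroupMaxSyn"), ("Avg", "GroupAvgSyn")):
            st, logdf = synthesis.generate_set(
                gen, model, mode, cfg.set_size, scfg,
                id_prefix=f"s1syn_{region}_{mode.lower()}", condition=cond,
                target_region=region, provider=f"group-{region}", probe=probe)
            files.append(_write_tsv(
                logdf, ws.path("sets", f"synth_{region}_{mode}.tsv")))
            if cfg.write_pngs:
                synth_data.write_images(st.stimuli,
                                        ws.path("session1", "images"))
            log.info("synthesize %s %s: mean predicted %.3f", region, mode,
                     st.predictions.mean())
    return files


def _session1_sets(ws: Workspace, cfg: PipelineConfig, pool=None
                   ) -> tuple[SessionDesign, dict]:
    pool = pool if pool is not None else _load_pool(ws)
    idx = _pool_index(pool)
    sets: dict[str, list] = {}
    entries = []
    for region in cfg.regions:
        nat = _load_natural_sets(ws, idx, region)
        syn_max = _load_synth_set(ws, cfg, f"{region}_Max", "GroupMaxSyn",
                                  region)
        syn_avg = _load_synth_set(ws, cfg, f"{region}_Avg", "GroupAvgSyn",
                                  region)
        for cond, st in (("GroupMaxNat", nat["GroupMaxNat"]),
                         ("GroupAvgNat", nat["GroupAvgNat"]),
                         ("GroupMaxSyn", syn_max), ("GroupAvgSyn", syn_avg)):
            src = "natural" if cond.endswith("Nat") else "synthetic"
            key = f"{region}:{cond}"
            sets[key] = list(st.stimuli)[:cfg.set_size]
            entries.append(SetEntry(condition=key, source=src,
                                    provider=st.provider, count=cfg.set_size))
    design = SessionDesign(session=1, entries=entries,
                           target_regions=list(cfg.regions),
                           n_repeats=cfg.session1_repeats)
    return design, sets


def stage_session1(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    pool = _load_pool(ws)
    cohorts = _load_cohorts(ws)
    design, sets = _session1_sets(ws, cfg, pool)
    novel = {region: cohorts[region]["novel"] for region in cfg.regions}
    manifest, table = synth_data.make_session_tables(
        design, sets, novel, _bank(cfg), seed=seed_for(cfg, 500))
    files = [
        _write_tsv(manifest, ws.path("session1", "manifest.tsv")),
        _write_tsv(table, ws.path("session1", "trials.tsv")),
    ]
    if cfg.write_pngs:
        nat = [im for imgs in sets.values() for im in imgs
               if im.source == "natural"]
        synth_data.write_images(nat, ws.path("session1", "images"))
    log.info("session1: %d manifest rows, %d trial rows",
             len(manifest), len(table))
    return files


def stage_personalize(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    region = cfg.personalize_region
    manifest = pd.read_csv(ws.require("session1/manifest.tsv", "session1"),
                           sep="\t")
    table = pd.read_csv(ws.require("session1/trials.tsv", "session1"),
                        sep="\t")
    pool = _load_pool(ws)
    design, sets = _session1_sets(ws, cfg, pool)
    stim_by_id = {im.image_id: im for imgs in sets.values() for im in imgs}
    stimuli = [stim_by_id[i] for i in manifest["image_id"]]
    base_models = _load_base_models(ws, cfg, region)
    group = fwrf.make_group_model(base_models)
    P = ens.base_prediction_matrix(base_models, stimuli)
    order = {i: k for k, i in enumerate(manifest["image_id"])}
    files = []
    rows = []
    cohorts = _load_cohorts(ws)
    for si, spec in enumerate(cohorts[region]["novel"]):
        subj = spec.subject_id
        train_ids, test_ids = ens.split_session1(
            table[table["subject_id"] == subj], manifest,
            cfg.n_train_per_cell, seed=seed_for(cfg, 600 + si))
        means = ens.image_mean_responses(table, subj, region)
        tr_rows = [order[i] for i in train_ids]
        model = ens.fit_ensemble(
            base_models, None, means.loc[train_ids].to_numpy(),
            prediction_matrix=P[tr_rows], subject_id=subj, region=region)
        out = ws.path("ensembles", f"{subj}.json")
        ens.save_ensemble(model, str(out),
                          base_refs=[f"models/{region}_base{i:02d}.h5"
                                     for i in range(len(base_models))],
                          split_seed=seed_for(cfg, 600 + si))
        files.append(out)
        te_rows = [order[i] for i in test_ids]
        pred_pers = P[te_rows] @ model.ensemble_weights + model.bias
        pred_group = P[te_rows].mean(axis=1)
        y_te = means.loc[test_ids].to_numpy()
        rows.append({
            "subject_id": subj, "region": region,
            "n_train": len(train_ids), "n_test": len(test_ids),
            "personalized_r": fwrf._pearson(pred_pers, y_te),
            "group_r": fwrf._pearson(pred_group, y_te),
        })
        log.info("personalize %s: test r pers=%.3f group=%.3f", subj,
                 rows[-1]["personalized_r"], rows[-1]["group_r"])
    files.append(_write_tsv(pd.DataFrame(rows),
                            ws.path("ensembles", "accuracy.tsv")))
    del group
    return files


def stage_session2(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    region = cfg.personalize_region
    pool = _load_pool(ws)
    idx = _pool_index(pool)
    bank = _bank(cfg)
    gen = _generator(cfg)
    base_models = _load_base_models(ws, cfg, region)
    cohorts = _load_cohorts(ws)
    novel = cohorts[region]["novel"]
    n_self, n_other, n_group = cfg.session2_counts
    self_set_size = n_self + n_other      # spare for the Other draws

    natural = pool.unique
    levels = fwrf._extract_batch(np.asarray([s.pixels for s in natural]),
                                 bank)
    self_sets: dict[str, dict[str, selection.StimulusSet]] = {}
    files = []
    for si, spec in enumerate(novel):
        subj = spec.subject_id
        model = ens.load_ensemble(str(ws.require(f"ensembles/{subj}.json",
                                                 "personalize")), base_models)
        preds = fwrf.predict_from_levels(model, levels)
        nat = selection.select_max(natural, model, self_set_size,
                                   condition="SelfMaxNat", predictions=preds,
                                   provider=f"self-{subj}")
        scfg = synthesis.SynthesisConfig(
            reg_weight=cfg.reg_weight, n_probe_per_class=cfg.n_probe_per_class,
            n_top_classes=cfg.n_top_classes, steps=cfg.synth_steps,
            step_size=cfg.synth_step_size, seed=seed_for(cfg, 700 + si))
        syn, logdf = synthesis.generate_set(
            gen, model, "Max", n_self, scfg, id_prefix=f"s2syn_{subj}",
            condition="SelfMaxSyn", target_region=region,
            provider=f"self-{subj}")
        files.append(_write_tsv(logdf,
                                ws.path("sets", f"synth_self_{subj}.tsv")))
        self_sets[subj] = {"Nat": nat, "Syn": syn}

    group_nat_df = pd.read_csv(ws.require(f"sets/natural_{region}.tsv",
                                          "select"), sep="\t")
    gmax = group_nat_df[group_nat_df["condition"] == "GroupMaxNat"]
    group_nat = selection.StimulusSet(
        condition="GroupMaxNat", provider="group",
        stimuli=[idx[i] for i in gmax["image_id"]],
        predictions=gmax["prediction"].to_numpy())
    group_syn = _load_synth_set(ws, cfg, f"{region}_Max", "GroupMaxSyn",
                                region)
    designs = selection.assemble_session2(
        self_sets, {"Nat": group_nat, "Syn": group_syn},
        counts=cfg.session2_counts, seed=seed_for(cfg, 710), region=region,
        n_repeats=cfg.session2_repeats)

    all_tables = []
    for si, spec in enumerate(novel):
        subj = spec.subject_id
        design, sets = designs[subj]
        design.target_regions = list(cfg.regions)   # measure all regions
        subj_by_region = {r: [cohorts[r]["novel"][si]] for r in cfg.regions}
        manifest, table = synth_data.make_session_tables(
            design, sets, subj_by_region, bank, seed=seed_for(cfg, 720 + si))
        files.append(_write_tsv(manifest,
                                ws.path("session2", f"{subj}_manifest.tsv")))
        files.append(_write_tsv(table,
                                ws.path("session2", f"{subj}_trials.tsv")))
        all_tables.append(table)
        if cfg.write_pngs:
            synth_data.write_images([im for imgs in sets.values()
                                     for im in imgs],
                                    ws.path("session2", "images"))
        log.info("session2 %s: %d manifest rows", subj, len(manifest))
    files.append(_write_tsv(pd.concat(all_tables, ignore_index=True),
                            ws.path("session2", "trials.tsv")))
    return files


def _image_means(ztable: pd.DataFrame) -> pd.DataFrame:
    return (ztable.groupby(["subject_id", "region", "image_id"],
                           as_index=False)["response"].mean())


def stage_stats(ws: Workspace) -> list[Path]:
    cfg = ws.cfg
    files = []
    manifest = pd.read_csv(ws.require("session1/manifest.tsv", "session1"),
                           sep="\t")
    table = pd.read_csv(ws.require("session1/trials.tsv", "session1"),
                        sep="\t")
    zt = stats.zscore_responses(table)
    means = _image_means(zt)
    cond_of = manifest.set_index("image_id")["condition"]
    target_of = manifest.set_index("image_id")["target_region"]
    means["condition"] = means["image_id"].map(
        cond_of.str.split(":").str[-1])
    means["target_region"] = means["image_id"].map(target_of)

    # Session-1 LME contrasts (on-target: images designed for the region)
    s1_rows = []
    for region in cfg.regions:
        on = means[(means["region"] == region)
                   & (means["target_region"] == region)]
        pvals = []
        for ci, (a, b) in enumerate(_S1_CONTRASTS):
            sub = on[on["condition"].isin([a, b])]
            res = stats.permutation_test(
                sub["response"], (sub["condition"] == b).astype(int),
                sub["subject_id"], n_perm=cfg.n_perm,
                seed=seed_for(cfg, 800) + ci)
            s1_rows.append({"region": region, "contrast": f"{a} vs {b}",
                            "beta": res.beta_obs, "p_raw": res.p_two_sided})
            pvals.append(res.p_two_sided)
        flags = stats.fdr_bh(pvals, cfg.fdr_q)
        for row, flag in zip(s1_rows[-len(pvals):], flags):
            row["fdr_significant"] = bool(flag)
    s1_stats = pd.DataFrame(s1_rows)
    files.append(_write_tsv(s1_stats, ws.path("stats", "lme_session1.tsv")))

    # Cohen's d per (subject, region, source)
    d_rows = []
    for region in cfg.regions:
        on = means[(means["region"] == region)
                   & (means["target_region"] == region)]
        for subj, sub in on.groupby("subject_id"):
            for src, (mx, av) in (("Nat", ("GroupMaxNat", "GroupAvgNat")),
                                  ("Syn", ("GroupMaxSyn", "GroupAvgSyn"))):
                d = stats.cohens_d(
                    sub[sub["condition"] == mx]["response"],
                    sub[sub["condition"] == av]["response"])
                d_rows.append({"subject_id": subj, "region": region,
                               "source": src, "cohens_d": d})
    d_table = pd.DataFrame(d_rows)
    files.append(_write_tsv(d_table, ws.path("stats", "cohens_d.tsv")))

    # Group-model encoding accuracy per (subject, region), also per source
    pool = _load_pool(ws)
    design, sets = _session1_sets(ws, cfg, pool)
    stim_by_id = {im.image_id: im for imgs in sets.values() for im in imgs}
    stimuli = [stim_by_id[i] for i in manifest["image_id"]]
    px = np.asarray([s.pixels for s in stimuli])
    levels = fwrf._extract_batch(px, _bank(cfg))
    acc_rows = []
    src_of = manifest.set_index("image_id")["source"]
    for region in cfg.regions:
        model = _load_group_model(ws, cfg, region)
        preds = pd.Series(fwrf.predict_from_levels(model, levels),
                          index=manifest["image_id"])
        for subj in sorted(zt["subject_id"].unique()):
            tsub = zt[(zt["subject_id"] == subj) & (zt["region"] == region)]
            nat_ids = [i for i in preds.index if src_of[i] == "natural"]
            syn_ids = [i for i in preds.index if src_of[i] == "synthetic"]
            acc_rows.append({
                "subject_id": subj, "region": region,
                "accuracy": stats.encoding_accuracy(preds, tsub),
                "accuracy_nat": stats.encoding_accuracy(
                    preds[nat_ids], tsub[tsub["image_id"].isin(nat_ids)]),
                "accuracy_syn": stats.encoding_accuracy(
                    preds[syn_ids], tsub[tsub["image_id"].isin(syn_ids)]),
            })
    acc_table = pd.DataFrame(acc_rows)
    files.append(_write_tsv(acc_table, ws.path("stats", "accuracy.tsv")))

    # accuracy vs modulation (pooled over regions and sources)
    merged = d_table.merge(acc_table[["subject_id", "region", "accuracy"]],
                           on=["subject_id", "region"])
    r_ad, p_ad = stats.accuracy_vs_d_correlation(
        merged["accuracy"], merged["cohens_d"], n_perm=cfg.n_perm,
        seed=seed_for(cfg, 810))
    t_ns, r_ns = stats.nat_syn_accuracy_compare(acc_table["accuracy_nat"],
                                                acc_table["accuracy_syn"])

    # inter-subject similarity / reliability per region
    for region in cfg.regions:
        sim = stats.subject_similarity_matrix(
            zt[zt["image_id"].isin(
                manifest[manifest["target_region"] == region]["image_id"])],
            region)
        files.append(_write_tsv(sim.reset_index(names="subject_id"),
                                ws.path("stats", f"similarity_{region}.tsv")))

    # ---- Session 2 ----
    s2 = pd.read_csv(ws.require("session2/trials.tsv", "session2"), sep="\t")
    s2_manifests = {}
    for subj in s2["subject_id"].unique():
        s2_manifests[subj] = pd.read_csv(
            ws.require(f"session2/{subj}_manifest.tsv", "session2"), sep="\t")
    zt2 = stats.zscore_responses(s2)
    m2 = _image_means(zt2)
    cond2 = {subj: mf.set_index("image_id")["condition"]
             for subj, mf in s2_manifests.items()}
    m2["condition"] = [cond2[s][i] for s, i in
                       zip(m2["subject_id"], m2["image_id"])]
    s2_rows = []
    for region in cfg.regions:
        sub_r = m2[m2["region"] == region]
        pvals = []
        for ci, (a, b) in enumerate(_S2_CONTRASTS):
            sub = sub_r[sub_r["condition"].isin([a, b])]
            res = stats.permutation_test(
                sub["response"], (sub["condition"] == b).astype(int),
                sub["subject_id"], n_perm=cfg.n_perm,
                seed=seed_for(cfg, 820) + ci)
            s2_rows.append({"region": region, "contrast": f"{a} vs {b}",
                            "beta": res.beta_obs, "p_raw": res.p_two_sided})
            pvals.append(res.p_two_sided)
        flags = stats.fdr_bh(pvals, cfg.fdr_q)
        for row, flag in zip(s2_rows[-len(pvals):], flags):
            row["fdr_significant"] = bool(flag)
    s2_stats = pd.DataFrame(s2_rows)
    files.append(_write_tsv(s2_stats, ws.path("stats", "lme_session2.tsv")))

    # hierarchy trend: per-subject t stats of Self vs Group/Other (synthetic)
    from scipy import stats as sps
    t_rows = []
    for region in cfg.regions:
        sub_r = m2[m2["region"] == region]
        for subj, sub in sub_r.groupby("subject_id"):
            self_v = sub[sub["condition"] == "SelfMaxSyn"]["response"]
            for ctype, other_cond in (("SelfVsGroup", "GroupMaxSyn"),
                                      ("SelfVsOther", "OtherMaxSyn")):
                other_v = sub[sub["condition"] == other_cond]["response"]
                t_rows.append({
                    "subject_id": subj, "region": region,
                    "contrast_type": ctype,
                    "t_stat": float(sps.ttest_ind(self_v, other_v).statistic),
                })
    t_df = pd.DataFrame(t_rows)
    levels = {r: i + 1 for i, r in enumerate(cfg.regions)}
    trend, trend_p = stats.hierarchy_trend_lme(
        t_df, levels, n_perm=cfg.n_perm, seed=seed_for(cfg, 830))
    files.append(_write_tsv(t_df, ws.path("stats", "hierarchy_tstats.tsv")))

    summary = {
        "mean_cohens_d_nat": float(
            d_table[d_table["source"] == "Nat"]["cohens_d"].mean()),
        "mean_cohens_d_syn": float(
            d_table[d_table["source"] == "Syn"]["cohens_d"].mean()),
        "accuracy_vs_d_r": r_ad, "accuracy_vs_d_p": p_ad,
        "nat_syn_accuracy_t": t_ns, "nat_syn_accuracy_r": r_ns,
        "hierarchy_level_beta": trend.beta, "hierarchy_level_p": trend_p,
        "mean_group_accuracy": float(acc_table["accuracy"].mean()),
    }
    files.append(_write_json(summary, ws.path("stats", "summary.json")))
    log.info("stats: %s", summary)
    return files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit-encoders": stage_fit_encoders,
    "build-group": stage_build_group,
    "select": stage_select,
    "synthesize": stage_synthesize,
    "session1": stage_session1,
    "personalize": stage_personalize,
    "session2": stage_session2,
    "stats": stage_stats,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one stage; outputs are written atomically and content-hashed."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; one of {STAGES}")
    ws = Workspace(cfg)
    t0 = time.perf_counter()
    files = _STAGE_FUNCS[name](ws)
    dt = time.perf_counter() - t0
    ws.record(name, files, cfg.seed, dt)
    log.info("stage %s done in %.1fs (%d files)", name, dt, len(files))
    return ws.manifest()["stages"][name]


def full_run(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    ws = Workspace(cfg)
    _write_json(dataclasses.asdict(cfg), ws.path("config.json"))
    for name in STAGES:
        run_stage(name, cfg)
    return ws.manifest()
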