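"""Resumable end-to-end pipeline over on-disk artifacts.

Runs the two-stage design as a chain of file-backed stages:

    data -> oracle -> uncertainty -> masks -> ensemble -> predict -> evaluate

Every stage writes its artifacts plus a JSON sidecar holding the seeds and
a hash of the configuration that produced them.  On rerun a stage whose
sidecar hash matches is loaded from disk instead of recomputed; a missing
upstream artifact or an unreadable file fails with an error naming the
stage.  All randomness flows from the master seed recorded in the
sidecars.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesian_unet import UNetConfig, load_model, save_model
from .ensemble import compute_uncertainty_maps, load_ensemble, save_ensemble
from .inference import as_predict_fn, plan_tiling, sliding_window_predict
from .masking import sample_lambda_schedule, make_mask
from .metrics import evaluate_pair
from .phantom import PhantomConfig, export_dataset, generate_dataset
from .training import TrainConfig, records_from_phantoms, train_uncertainty_oracle
from .io_preprocess import load_records, read_nifti, write_nifti
from .uncertainty import UncertaintyMap
from .ensemble import fuse

logger = logging.getLogger(__name__)


def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_fresh(sidecar: Path, confhash: str) -> bool:
    if not sidecar.exists():
        return False
    try:
        meta = json.loads(sidecar.read_text())
    except (OSError, json.JSONDecodeError):
        return False
    return meta.get("config_hash") == confhash


def _write_sidecar(sidecar: Path, confhash: str, **extra) -> None:
    sidecar.write_text(json.dumps(dict(config_hash=confhash, **extra), indent=2))


def end_to_end(out_dir,
               phantom_config: PhantomConfig = PhantomConfig(),
               n_train: int = 60,
               n_test: int = 15,
               K: int = 5,
               unet_config: UNetConfig = UNetConfig(depth=3, base_filters=8,
                                                    dropout_rate=0.0),
               oracle_config: UNetConfig = UNetConfig(depth=3, base_filters=8,
                                                      dropout_rate=0.5,
                                                      dropout_mode="train_and_inference"),
               train_config: TrainConfig = TrainConfig(),
               master_seed: int = 0,
               T: int = 20) -> Path:
    """Run (or resume) the full pipeline; returns the metrics TSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    # ---- stage: data -------------------------------------------------
    data_hash = _hash_config(dict(p=asdict(phantom_config), n_train=n_train,
                                  n_test=n_test))
    data_dir = out / "data"
    sidecar = data_dir / "stage.json"
    if not _stage_fresh(sidecar, data_hash):
        train = generate_dataset(phantom_config, n_train, seed=phantom_config.seed)
        test = generate_dataset(phantom_config, n_test, seed=phantom_config.seed + 7919)
        export_dataset(train, data_dir / "train")
        export_dataset(test, data_dir / "test")
        _write_sidecar(sidecar, data_hash, seed=phantom_config.seed)
        logger.info("stage data: generated %d train / %d test phantoms", n_train, n_test)
    else:
        logger.info("stage data: up to date, skipped")
    try:
        rtrain = load_records(data_dir / "train" / "manifest.tsv")
        rtest = load_records(data_dir / "test" / "manifest.tsv")
        clean_test = [r.label for r in load_records(data_dir / "test" / "manifest.tsv",
                                                    label_col="clean_label")]
    except Exception as err:
        raise RuntimeError("stage 'data' artifacts unreadable; rerun the data stage") from err
    from .io_preprocess import gaussian_normalize
    for rec in rtrain + rtest:
        rec.image = gaussian_normalize(rec.image)

    # ---- stage: oracle -----------------------------------------------
    oracle_hash = _hash_config(dict(data=data_hash, cfg=asdict(oracle_config),
                                    t=asdict(train_config), seed=master_seed))
    oracle_path = out / "oracle.npz"
    sidecar = out / "oracle.json"
    if not _stage_fresh(sidecar, oracle_hash):
        from .bench import ORACLE_EPOCH_FACTOR

        cfg = TrainConfig(**{**train_config.__dict__, "seed": master_seed + 1000,
                             "epochs": ORACLE_EPOCH_FACTOR * train_config.epochs})
        oracle = train_uncertainty_oracle(rtrain, oracle_config, cfg)
        save_model(oracle, oracle_path)
        _write_sidecar(sidecar, oracle_hash, seed=master_seed + 1000)
        logger.info("stage oracle: trained (%.1fs elapsed)", time.time() - t_start)
    else:
        logger.info("stage oracle: up to date, skipped")
    if not oracle_path.exists():
        raise RuntimeError("stage 'oracle' artifact missing; run the oracle stage first")
    try:
        oracle = load_model(oracle_path)
    except Exception as err:
        raise RuntimeError("stage 'oracle' checkpoint unreadable") from err

    # ---- stage: uncertainty ------------------------------------------
    unc_hash = _hash_config(dict(oracle=oracle_hash, T=T, seed=master_seed))
    unc_dir = out / "uncertainty"
    sidecar = unc_dir / "stage.json"
    if not _stage_fresh(sidecar, unc_hash):
        unc_dir.mkdir(exist_ok=True)
        maps = compute_uncertainty_maps(rtrain, oracle, T=T, seed=master_seed)
        for rec, u in zip(rtrain, maps):
            write_nifti(unc_dir / f"{rec.subject_id}_unc.nii", u.values.astype(np.float32))
            (unc_dir / f"{rec.subject_id}_unc.json").write_text(json.dumps(dict(
                T=T, seed=master_seed, theta=oracle.config.dropout_rate,
                normalization_stats=u.normalization_stats)))
        _write_sidecar(sidecar, unc_hash, T=T, seed=master_seed)
        logger.info("stage uncertainty: %d maps (%.1fs elapsed)",
                    len(maps), time.time() - t_start)
    else:
        logger.info("stage uncertainty: up to date, skipped")

    # ---- stage: masks ------------------------------------------------
    schedule = sample_lambda_schedule(K, seed=master_seed)
    mask_hash = _hash_config(dict(unc=unc_hash, lambdas=schedule.lambdas))
    masks_dir = out / "masks"
    sidecar = masks_dir / "stage.json"
    if not _stage_fresh(sidecar, mask_hash):
        try:
            unc_maps = [
                UncertaintyMap(values=read_nifti(unc_dir / f"{rec.subject_id}_unc.nii")[0]
                               .astype(np.float64),
                               normalized=True)
                for rec in rtrain
            ]
        except Exception as err:
            raise RuntimeError(
                "stage 'masks' failed: uncertainty maps missing or unreadable; "
                "run the uncertainty stage first") from err
        for lam in schedule.lambdas:
            lam_dir = masks_dir / f"lambda_{lam:.1f}"
            lam_dir.mkdir(parents=True, exist_ok=True)
            for rec, u in zip(rtrain, unc_maps):
                m = make_mask(u, lam, source_sample_id=rec.subject_id)
                write_nifti(lam_dir / f"{rec.subject_id}_mask.nii", m.mask)
            (lam_dir / "masks.json").write_text(json.dumps(dict(
                lam=lam, oracle="oracle.npz")))
        _write_sidecar(sidecar, mask_hash, lambdas=schedule.lambdas)
        logger.info("stage masks: %d lambda sets", K)
    else:
        logger.info("stage masks: up to date, skipped")

    # ---- stage: ensemble ---------------------------------------------
    ens_hash = _hash_config(dict(masks=mask_hash, cfg=asdict(unet_config),
                                 t=asdict(train_config), seed=master_seed, K=K))
    ens_dir = out / "ensemble"
    sidecar = ens_dir / "stage.json"
    if not _stage_fresh(sidecar, ens_hash):
        from .ensemble import EnsembleModel
        from .training import train_base_model

        members = []
        for k, lam in enumerate(schedule.lambdas):
            lam_dir = masks_dir / f"lambda_{lam:.1f}"
            try:
                lam_masks = [
                    read_nifti(lam_dir / f"{rec.subject_id}_mask.nii")[0]
                    .astype(np.uint8)
                    for rec in rtrain
                ]
            except Exception as err:
                raise RuntimeError(
                    "stage 'masks' artifacts missing or unreadable; "
                    "rerun the masks stage") from err
            cfg_k = TrainConfig(**{**train_config.__dict__, "seed": master_seed + k})
            try:
                members.append(train_base_model(rtrain, lam_masks, unet_config,
                                                cfg_k, lambda_used=lam))
            except Exception as err:
                raise RuntimeError(
                    f"stage 'ensemble' failed on member {k} (lambda={lam})") from err
        ens = EnsembleModel(members=members, schedule=schedule)
        save_ensemble(ens, ens_dir)
        _write_sidecar(sidecar, ens_hash, seed=master_seed)
        logger.info("stage ensemble: %d members (%.1fs elapsed)", K,
                    time.time() - t_start)
    else:
        logger.info("stage ensemble: up to date, skipped")
    try:
        ens = load_ensemble(ens_dir)
    except Exception as err:
        raise RuntimeError("stage 'ensemble' artifacts unreadable; "
                           "rerun the ensemble stage") from err

    # ---- stage: predict ----------------------------------------------
    pred_hash = _hash_config(dict(ens=ens_hash, patch=train_config.patch_shape))
    pred_dir = out / "predictions"
    sidecar = pred_dir / "stage.json"
    if not _stage_fresh(sidecar, pred_hash):
        pred_dir.mkdir(exist_ok=True)
        plan = plan_tiling(rtest[0].label.shape, train_config.patch_shape)
        for rec in rtest:
            member_maps = [sliding_window_predict(as_predict_fn(m), rec.image, plan)
                           for m in ens.members]
            pred = fuse(member_maps)
            write_nifti(pred_dir / f"{rec.subject_id}_prob.nii",
                        pred.fused_probability.astype(np.float32))
            write_nifti(pred_dir / f"{rec.subject_id}_seg.nii", pred.segmentation)
            write_nifti(pred_dir / f"{rec.subject_id}_unc.nii",
                        pred.epistemic_uncertainty.astype(np.float32))
        _write_sidecar(sidecar, pred_hash)
        logger.info("stage predict: %d volumes (%.1fs elapsed)", len(rtest),
                    time.time() - t_start)
    else:
        logger.info("stage predict: up to date, skipped")

    # ---- stage: evaluate ---------------------------------------------
    metrics_path = out / "metrics.tsv"
    rows = []
    for rec, gt in zip(rtest, clean_test):
        try:
            seg, _ = read_nifti(pred_dir / f"{rec.subject_id}_seg.nii")
        except Exception as err:
            raise RuntimeError("stage 'evaluate' failed: predictions missing; "
                               "run the predict stage first") from err
        r = evaluate_pair(seg.astype(np.uint8), gt)
        rows.append(dict(sample_id=rec.subject_id, dice=r.dice, h95=r.h95,
                         recall=r.recall, lesion_f1=r.lesion_f1,
                         recall_large=r.recall_large, recall_small=r.recall_small))
    df = pd.DataFrame(rows)
    summary = df.drop(columns="sample_id").agg(["mean", "std"])
    df.to_csv(metrics_path, sep="\t", index=False)
    summary.to_csv(out / "metrics_summary.tsv", sep="\t")
    logger.info("pipeline complete in %.1fs: mean dice %.3f",
                time.time() - t_start, df["dice"].mean())
    return metrics_path
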