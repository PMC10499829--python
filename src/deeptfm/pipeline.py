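"""End-to-end pipeline: phantoms -> sPSF -> dataset -> train -> evaluate.

A :class:`RunConfig` collects every stage's parameters in nested sections
plus one global seed; each stochastic stage derives its stream from the
global seed through :func:`deeptfm.io.substream` (stage name -> substream),
so two runs with equal configs are bit-identical.  Completed stages are
skipped on re-run: each stage directory carries a hash of the config section
that feeds it, and a matching hash short-circuits the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import emccd, forward, inverse, io, metrics, phantoms, psf, scatter_mc

__all__ = ["RunConfig", "run_pipeline"]

_DEFAULTS: dict = {
    "seed": 0,
    "optics": {
        "na": 1.0,
        "refractive_index": 1.33,
        "wavelength_ex_um": 1.036,
        "wavelength_em_um": 0.58,
        "psf_shape": [13, 21, 21],
        "voxel_size_um": [1.0, 1.0, 1.0],
    },
    "medium": {"mu_s_per_um": 0.02, "g": 0.9, "n_tissue": 1.33},
    "camera": {
        "g_em": 300.0,
        "n_stages": 512,
        "dark_mean": 0.2,
        "read_sigma": 60.0,
        "lut_max_input": 200,
        "lut_draws": 10000,
        "lut_pool": 100000,
    },
    "patterns": {"t_count": 32, "fill_fraction": 0.5},
    "phantoms": {
        "kind": "beads",
        "n_volumes": 100,
        "shape": [13, 64, 64],
        "n_small": 3,
        "n_large": 2,
    },
    "dataset": {
        "depth_sls": 4.0,
        "photons_per_unit": 50.0,
        "spsf_photons": 200000,
        "spsf_shape": [63, 63],
        "split": [4, 1],
        "n_test": 0,
    },
    "network": {
        "base_width": 16,
        "depth_levels": 4,
        "scse_reduction": 2,
        "loss": "kl",
    },
    "training": {"lr": 1.0e-3, "beta1": 0.9, "beta2": 0.999,
                 "batch_size": 10, "epochs": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclasses.dataclass
class RunConfig:
    """Nested pipeline configuration with a single global seed."""

    sections: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        return cls(_merge(_DEFAULTS, overrides or {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.sections, f, sort_keys=True)

    def __getitem__(self, key):
        return self.sections[key]

    @property
    def seed(self) -> int:
        return int(self.sections["seed"])


def _stage_hash(*parts) -> str:
    blob = json.dumps(parts, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def _stage_done(stage_dir: Path, digest: str) -> bool:
    marker = stage_dir / "complete.json"
    if marker.exists():
        try:
            return json.loads(marker.read_text()).get("hash") == digest
        except json.JSONDecodeError:
            return False
    return False


def _mark_done(stage_dir: Path, digest: str, payload: dict | None = None) -> None:
    (stage_dir / "complete.json").write_text(
        json.dumps({"hash": digest, **(payload or {})}, indent=2)
    )


def run_pipeline(config: RunConfig, out_root: str | Path) -> dict:
    """Execute the full pipeline; idempotent per stage.  Returns the manifest."""
    log = io.get_logger("deeptfm.pipeline")
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_root / "run.yaml")
    seed = config.seed
    c = config.sections

    # --- phantoms ---------------------------------------------------------
    ph_dir = out_root / "phantoms"
    ph_dir.mkdir(exist_ok=True)
    ph_hash = _stage_hash("phantoms", c["phantoms"], seed)
    objects: list[phantoms.ObjectVolume] = []
    shape = tuple(c["phantoms"]["shape"])
    n_volumes = int(c["phantoms"]["n_volumes"])
    if not _stage_done(ph_dir, ph_hash):
        log.info("stage phantoms: generating %d %s volumes", n_volumes, c["phantoms"]["kind"])
        for i in range(n_volumes):
            sub_seed = int(io.substream(seed, "phantom", i).generate_state(1)[0] & 0x7FFFFFFF)
            if c["phantoms"]["kind"] == "beads":
                spec = phantoms.BeadSpec(
                    seed=sub_seed,
                    n_small=c["phantoms"].get("n_small"),
                    n_large=c["phantoms"].get("n_large"),
                )
                obj = phantoms.generate_beads_volume(spec, shape)
            else:
                obj = phantoms.generate_vessel_volume(shape=shape, seed=sub_seed)
            io.write_stack(ph_dir / f"object_{i:05d}.tif", obj.intensity,
                           {"seed": sub_seed, "kind": c["phantoms"]["kind"]})
            objects.append(obj)
        _mark_done(ph_dir, ph_hash, {"n": n_volumes})
    else:
        log.info("stage phantoms: complete, skipping")
        for i in range(n_volumes):
            arr, _ = io.read_stack(ph_dir / f"object_{i:05d}.tif")
            objects.append(phantoms.ObjectVolume(arr))

    # --- optics / sPSF ----------------------------------------------------
    medium = scatter_mc.ScatteringMedium(
        mu_s=c["medium"]["mu_s_per_um"], g=c["medium"]["g"],
        n_tissue=c["medium"]["n_tissue"],
    )
    opt = c["optics"]
    vx = tuple(opt["voxel_size_um"])
    ex_psf = psf.make_gaussian_psf(opt["na"], opt["wavelength_ex_um"],
                                   opt["refractive_index"], tuple(opt["psf_shape"]),
                                   vx, kind="excitation")
    em_psf = psf.make_gaussian_psf(opt["na"], opt["wavelength_em_um"],
                                   opt["refractive_index"], tuple(opt["psf_shape"]),
                                   vx, kind="emission")
    ds = c["dataset"]
    depth_um = float(ds["depth_sls"]) * medium.scattering_length
    depths = forward.spsf_depths_for_object(shape[0], vx[2], depth_um)
    sp_dir = out_root / "spsf"
    sp_dir.mkdir(exist_ok=True)
    sp_hash = _stage_hash("spsf", c["medium"], opt["na"], ds["depth_sls"],
                          ds["spsf_photons"], ds["spsf_shape"], list(depths), seed)
    sp_path = sp_dir / "spsf.h5"
    if not _stage_done(sp_dir, sp_hash):
        log.info("stage spsf: %d depths x %d photons", len(set(depths)), ds["spsf_photons"])
        spsf_stack = scatter_mc.build_spsf_stack(
            medium, sorted(set(depths)), na=opt["na"],
            n_photons=int(ds["spsf_photons"]), shape=tuple(ds["spsf_shape"]),
            pixel_size=vx[0], seed=seed,
        )
        spsf_stack.save(sp_path)
        _mark_done(sp_dir, sp_hash)
    else:
        log.info("stage spsf: complete, skipping")
        spsf_stack = scatter_mc.ScatteringPSFStack.load(sp_path)
    per_plane = scatter_mc.ScatteringPSFStack(
        images=np.stack([spsf_stack.image_at(d) for d in depths]),
        depths=np.asarray(depths),
        pixel_size=spsf_stack.pixel_size,
        acceptance=np.zeros(len(depths)),
        photons_launched=spsf_stack.photons_launched,
    )

    # --- dataset ----------------------------------------------------------
    cam = c["camera"]
    camera = emccd.CameraModel(
        g_em=cam["g_em"], n_stages=cam["n_stages"],
        dark_mean=cam["dark_mean"], read_sigma=cam["read_sigma"],
        lut_max_input=cam["lut_max_input"],
    )
    data_dir = out_root / "dataset"
    data_dir.mkdir(exist_ok=True)
    data_hash = _stage_hash("dataset", c["patterns"], c["camera"], ds, ph_hash, sp_hash, seed)
    manifest_path = data_dir / "manifest.json"
    if not _stage_done(data_dir, data_hash):
        log.info("stage dataset: simulating %d stacks", len(objects))
        lut = emccd.build_em_lut(
            camera, n_draws=int(cam["lut_draws"]), pool_size=int(cam["lut_pool"]),
            seed=np.random.default_rng(io.substream(seed, "lut")),
        )
        patterns = psf.make_random_patterns(
            t_count=int(c["patterns"]["t_count"]), shape=shape[1:],
            fill_fraction=float(c["patterns"]["fill_fraction"]),
            seed=int(io.substream(seed, "patterns").generate_state(1)[0] & 0x7FFFFFFF),
        )
        psf.save_patterns(data_dir / "patterns.tif", patterns)
        forward.build_dataset(
            objects, data_dir, patterns, ex_psf, em_psf, per_plane, camera, lut,
            photons_per_unit=float(ds["photons_per_unit"]), seed=seed,
            split=tuple(ds["split"]), n_test=int(ds["n_test"]),
            depth_sls=float(ds["depth_sls"]),
        )
        _mark_done(data_dir, data_hash)
    else:
        log.info("stage dataset: complete, skipping")

    # --- training ---------------------------------------------------------
    net_dir = out_root / "model"
    net_dir.mkdir(exist_ok=True)
    net_hash = _stage_hash("train", c["network"], c["training"], data_hash, seed)
    ckpt = net_dir / "model"
    if not _stage_done(net_dir, net_hash):
        Xtr, Ytr = forward.load_dataset(manifest_path, "train")
        Xva, Yva = forward.load_dataset(manifest_path, "val")
        net_cfg = inverse.NetworkConfig(
            in_channels=int(c["patterns"]["t_count"]),
            base_width=int(c["network"]["base_width"]),
            depth_levels=int(c["network"]["depth_levels"]),
            scse_reduction=int(c["network"]["scse_reduction"]),
            loss=c["network"]["loss"],
            seed=seed,
        )
        tr = c["training"]
        train_cfg = inverse.TrainConfig(
            lr=float(tr["lr"]), beta1=float(tr["beta1"]), beta2=float(tr["beta2"]),
            batch_size=int(tr["batch_size"]), epochs=int(tr["epochs"]), seed=seed,
        )
        log.info("stage train: %d train / %d val stacks, %d epochs",
                 len(Xtr), len(Xva), train_cfg.epochs)
        net, history = inverse.train((Xtr, Ytr), (Xva, Yva), net_cfg, train_cfg)
        inverse.save_model(ckpt, net, extra={"history": history})
        import pandas as pd
        pd.DataFrame(history).to_csv(net_dir / "history.csv", index=False)
        _mark_done(net_dir, net_hash)
    else:
        log.info("stage train: complete, skipping")
        net, _ = inverse.load_model(ckpt)

    # --- evaluation -------------------------------------------------------
    eval_dir = out_root / "evaluation"
    eval_dir.mkdir(exist_ok=True)
    eval_hash = _stage_hash("evaluate", net_hash, data_hash)
    if not _stage_done(eval_dir, eval_hash):
        Xva, Yva = forward.load_dataset(manifest_path, "val")
        pairs = [
            (Yva[i, 0], net.predict(Xva[i:i + 1])[0, 0]) for i in range(len(Xva))
        ]
        df, summary = metrics.evaluate_cohort(pairs)
        df.to_csv(eval_dir / "metrics.csv", index=False)
        (eval_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        _mark_done(eval_dir, eval_hash, payload=summary)
        log.info("stage evaluate: %s", summary)

    manifest = {
        "config": c,
        "stages": {
            "phantoms": str(ph_dir),
            "spsf": str(sp_path),
            "dataset": str(manifest_path),
            "model": str(ckpt.with_suffix(".npz")),
            "evaluation": str(eval_dir / "summary.json"),
        },
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
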