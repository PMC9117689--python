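"""End-to-end orchestration: simulate/featurize → landscape → MSM (→ SCA, NEB).

Configuration lives in a single YAML file; every produced artifact carries the
config hash and seed in a comment header and is listed with a content hash in
the run manifest, so reruns with the same config are byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import landscape as ls
from . import msm as msm_mod
from . import neb as neb_mod
from . import sca as sca_mod
from . import synth
from .errors import ValidationError
from .surfaces import get_surface

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "conformscape_out"
    seed: int = 7
    # synthetic trajectory stage
    n_traj: int = 10
    n_steps: int = 20000
    kT: float = 1.0
    dt: float = 0.05
    # landscape
    bins: tuple[int, int] = (100, 100)
    temperature: float = 300.0
    # msm
    k_microstates: int = 500
    lags: tuple[int, ...] = (1, 2, 4, 8, 16)
    n_macro: int = 3
    frame_interval: float = 1.0
    # optional stages
    run_sca: bool = False
    msa_path: str | None = None
    epsilon: float = 0.05
    background_q: float = 0.05
    run_neb: bool = False
    neb_surface: str = "muller-brown"
    neb_replicas: int = neb_mod.DEFAULT_N_REPLICAS
    features_paths: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.run_sca and not self.msa_path:
            raise ValidationError("run_sca requires msa_path")
        for p in list(self.features_paths) + ([self.msa_path] if self.msa_path else []):
            if p and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")
        if self.n_macro < 2:
            raise ValidationError("n_macro must be at least 2")

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # identical analyses hash alike anywhere
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(**raw)
    for key in ("bins", "lags"):
        setattr(cfg, key, tuple(getattr(cfg, key)))
    return cfg


def _write_csv(df, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the artifact manifest.

    A stage failure halts the run; the manifest written so far is preserved
    on disk (manifest.json) with the failing stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.digest()
    header = f"# conformscape config={tag} seed={config.seed}\n"
    manifest: dict = {"config_hash": tag, "seed": config.seed, "artifacts": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    current = "features"
    try:
        if config.features_paths:
            import pandas as pd
            feats = [pd.read_csv(p, comment="#") for p in config.features_paths]
        else:
            surface = get_surface("cv-three-well")
            result = synth.simulate_brownian(surface, synth.BrownianConfig(
                steps=config.n_steps, kT=config.kT, dt=config.dt,
                n_traj=config.n_traj, seed=config.seed))
            feats = result.features
        fpath = out / "features.csv"
        import pandas as pd
        pooled = pd.concat(
            [f.assign(traj=i) for i, f in enumerate(feats)], ignore_index=True)
        _write_csv(pooled, fpath, header)
        record("features", fpath)

        current = "landscape"
        grid = ls.estimate_landscape(feats, n_bins=config.bins,
                                     temperature=config.temperature)
        lpath = out / "landscape.csv"
        _write_csv(grid.to_frame(), lpath, header)
        record("landscape", lpath)

        current = "msm"
        micro = msm_mod.cluster_microstates(feats, k=config.k_microstates,
                                            seed=config.seed)
        scan = msm_mod.implied_timescales(micro.assignments, config.lags,
                                          frame_interval=config.frame_interval)
        spath = out / "timescales.csv"
        _write_csv(scan.to_frame(), spath, header)
        record("timescales", spath)
        choice = msm_mod.choose_lag(scan)
        model = msm_mod.estimate_tpm(micro.assignments, choice.lag_frames,
                                     frame_interval=config.frame_interval)
        macro = msm_mod.pcca_macrostates(model, n_macro=config.n_macro)
        labels = msm_mod.macro_label_frames(micro.assignments, model, macro)
        mpath = out / "macrostates.json"
        mpath.write_text(json.dumps({
            "config": tag, "seed": config.seed,
            "lag_frames": choice.lag_frames, "markovian": choice.markovian,
            "micro_to_macro": macro.micro_to_macro.tolist(),
            "proportions_stationary": macro.proportions.tolist(),
            "proportions_counts": msm_mod.count_proportions(
                labels, config.n_macro).tolist(),
        }, indent=1))
        record("macrostates", mpath)

        if config.run_sca:
            current = "sca"
            msa = sca_mod.load_msa(Path(config.msa_path).read_text())
            profile = sca_mod.conservation_profile(msa, q=config.background_q)
            C = sca_mod.sca_matrix(msa, q=config.background_q)
            sectors = sca_mod.define_sectors(C, epsilon=config.epsilon)
            scapath = out / "sca.json"
            scapath.write_text(json.dumps({
                "config": tag,
                "conservation": profile.score.tolist(),
                "red": sectors.red.tolist(),
                "blue": sectors.blue.tolist(),
            }, indent=1))
            record("sca", scapath)

        if config.run_neb:
            current = "neb"
            surface = get_surface(config.neb_surface)
            if config.neb_surface == "muller-brown":
                start, end = (-0.558, 1.442), (0.623, 0.028)
            else:
                wells = surface.metadata.get("wells") or []
                if len(wells) < 2:
                    raise ValidationError("NEB surface needs two endpoints")
                start, end = wells[0].center, wells[-1].center
            band = neb_mod.init_band(start, end, n_replicas=config.neb_replicas)
            relaxed = neb_mod.relax_band(band, surface, seed=config.seed)
            import pandas as pd
            npath = out / "neb_band.csv"
            bdf = pd.DataFrame(relaxed.replicas,
                               columns=[f"x{i}" for i in range(relaxed.dim)])
            bdf.insert(0, "replica", np.arange(relaxed.n_replicas))
            bdf["energy"] = relaxed.energies
            _write_csv(bdf, npath, header)
            record("neb_band", npath)
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
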