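"""Structured run configuration (YAML) shared by the CLI stages.

Every random operation in a run receives an explicit seed derived from
``RunConfig.seed``, and a config round-trips load -> save -> load
identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import VirusGeometry, build_capsid, build_tail
from .simulate import FieldComposition, LabelingParams, NoiseParams

__all__ = ["RunConfig", "load_config", "save_config"]


def _d(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int = 0
    output_dir: str = "results"
    geometry: dict = _d(width_nm=86.0, length_nm=120.0, edge_eq_nm=50.0,
                        edge_cross_nm=[70.0, 73.0], tail_length_nm=140.0,
                        tail_width_nm=24.0, basal_width_nm=50.0,
                        basal_fraction=0.15)
    labeling: dict = _d(ele=0.5, linkage_nm=7.0,
                        linkage_mode="outward_hemisphere",
                        events_per_label=20.0)
    noise: dict = _d(sigma_xy_nm=3.0, sigma_z_nm=6.0, photons_mean=53000.0,
                     photons_dispersion=0.3, background_per_pixel=300.0)
    composition: dict = _d(n_particles=100, frac_standing=0.65,
                           frac_lying=0.35, frac_dimer=0.26,
                           frac_blurred=0.06, tilt_sd_deg=5.0,
                           density_per_um2=1.25)
    analysis: dict = _d(bin_nm=6.0, slab_nm=100.0, stripe_nm=17.0,
                        eps_nm=30.0, min_pts=10, zscore_threshold=3.5,
                        n_windows=20, voxel_nm=8.0)
    n_frames: int = 100_000

    # ---- factories -------------------------------------------------
    def make_geometry(self) -> VirusGeometry:
        g = self.geometry
        return VirusGeometry(
            capsid=build_capsid(g["width_nm"], g["length_nm"],
                                g["edge_eq_nm"], tuple(g["edge_cross_nm"])),
            tail=build_tail(g["tail_length_nm"], g["tail_width_nm"],
                            g["basal_width_nm"], g["basal_fraction"]))

    def make_labeling(self) -> LabelingParams:
        return LabelingParams(**self.labeling)

    def make_noise(self) -> NoiseParams:
        return NoiseParams(**self.noise)

    def make_composition(self, **override) -> FieldComposition:
        kw = {**self.composition, **override}
        return FieldComposition(**kw)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + salt)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, val in data.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        cur = getattr(cfg, key)
        if isinstance(cur, dict):
            unknown = set(val) - set(cur)
            if unknown:
                raise ValueError(f"unknown config key(s) {key}.{unknown}")
            cur.update(val)
        else:
            setattr(cfg, key, val)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
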