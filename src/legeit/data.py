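"""Dataset assembly and HDF5 persistence.

One dataset bundles, per sample: the ideal conductivity map (training
label), the tissue label map, the 208-dim boundary voltage vector (with
its scheduled noise already applied), the stored clean voltages, the HTV
pre-reconstruction (network input) and the SNR tag.  The noise schedule
cycles clean / 30 / 45 / 55 dB over sample index, frozen at build time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import forward, htv, phantoms

__all__ = ["EITDataset", "build_dataset", "save_dataset", "load_dataset"]

SNR_TAG_CLEAN = -1.0  # stored tag for noise-free samples


@dataclass
class EITDataset:
    conductivity: np.ndarray      # (n, g, g) labels/targets, S/m
    labels: np.ndarray            # (n, g, g) int8
    voltages: np.ndarray          # (n, 208) with scheduled noise
    clean_voltages: np.ndarray    # (n, 208)
    htv_input: np.ndarray         # (n, g, g) or empty until pre-reconstruction
    snr_tag: np.ndarray           # (n,) dB, -1 for clean
    grid_size: int
    base_seed: int
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.conductivity)


def build_dataset(n: int, base_seed: int = 0, grid_size: int = 64,
                  sens: "forward.SensitivityMatrix | None" = None,
                  htv_config: "htv.HTVConfig | None" = None,
                  prereconstruct: bool = True,
                  progress: bool = False) -> EITDataset:
    """Phantoms -> forward voltages -> scheduled noise -> HTV inputs."""
    sens = sens or forward.build_sensitivity(grid_size=grid_size)
    phs = phantoms.generate_dataset(n, base_seed, grid_size=grid_size)
    g = grid_size
    cond = np.stack([p.conductivity for p in phs]).astype(np.float32)
    labs = np.stack([p.labels for p in phs])
    clean = np.empty((n, sens.J.shape[0]))
    noisy = np.empty_like(clean)
    tags = np.empty(n)
    for i, p in enumerate(phs):
        vf = forward.solve_forward(sens, p.conductivity)
        clean[i] = vf.v
        snr = forward.noise_schedule(i)
        tags[i] = SNR_TAG_CLEAN if snr is None else snr
        noisy[i] = forward.add_noise(vf, snr, seed=base_seed * 100003 + i).v
    ds = EITDataset(conductivity=cond, labels=labs, voltages=noisy,
                    clean_voltages=clean,
                    htv_input=np.zeros((0, g, g), np.float32),
                    snr_tag=tags, grid_size=g, base_seed=base_seed,
                    meta={"n": n})
    if prereconstruct:
        ds.htv_input = htv.batch_prereconstruct(noisy, sens, htv_config,
                                                progress=progress)
    return ds


def save_dataset(ds: EITDataset, path):
    import h5py
    with h5py.File(path, "w") as f:
        for name in ["conductivity", "labels", "voltages", "clean_voltages",
                     "htv_input", "snr_tag"]:
            f.create_dataset(name, data=getattr(ds, name))
        f.attrs["grid_size"] = ds.grid_size
        f.attrs["base_seed"] = ds.base_seed
        f.attrs["meta"] = json.dumps(ds.meta)


def load_dataset(path) -> EITDataset:
    import h5py
    with h5py.File(path, "r") as f:
        return EITDataset(
            conductivity=f["conductivity"][:], labels=f["labels"][:],
            voltages=f["voltages"][:], clean_voltages=f["clean_voltages"][:],
            htv_input=f["htv_input"][:], snr_tag=f["snr_tag"][:],
            grid_size=int(f.attrs["grid_size"]),
            base_seed=int(f.attrs["base_seed"]),
            meta=json.loads(f.attrs["meta"]))
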