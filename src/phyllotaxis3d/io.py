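"""File I/O: trajectories and k-space as HDF5/CSV, configs as YAML, volumes as NIfTI."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bssfp import Tissue
from .phantom import Compartment, ImperfectionModel, KSpaceData, PhantomSpec
from .trajectory import SpokeSet, TrajectoryConfig

__all__ = [
    "save_trajectory_h5", "load_trajectory_h5", "save_trajectory_csv",
    "save_kspace_h5", "load_kspace_h5",
    "load_phantom_yaml", "save_phantom_yaml",
    "load_imperfections_yaml", "save_imperfections_yaml",
    "save_volume_nifti", "save_volume_h5", "load_volume_h5",
]


def save_trajectory_h5(path, spoke_set: SpokeSet) -> None:
    cfg = spoke_set.config
    with h5py.File(path, "w") as f:
        f.create_dataset("directions", data=spoke_set.directions)
        f.create_dataset("angles", data=np.column_stack([spoke_set.theta,
                                                         spoke_set.phi]))
        f.create_dataset("order", data=np.column_stack(
            [spoke_set.n, spoke_set.within, spoke_set.interleave]))
        f.create_dataset("samples", data=spoke_set.sample_positions())
        f.create_dataset("is_si_spoke", data=spoke_set.is_si_spoke)
        f.attrs["design"] = cfg.design
        f.attrs["golden_angle"] = cfg.golden_angle
        f.attrs["k_max"] = cfg.k_max
        f.attrs["n_spokes"] = cfg.n_spokes
        f.attrs["n_interleaves"] = cfg.n_interleaves
        f.attrs["samples_per_spoke"] = cfg.samples_per_spoke
        f.attrs["si_spoke_mode"] = cfg.si_spoke_mode


def load_trajectory_h5(path) -> SpokeSet:
    with h5py.File(path, "r") as f:
        cfg = TrajectoryConfig(
            n_spokes=int(f.attrs["n_spokes"]),
            n_interleaves=int(f.attrs["n_interleaves"]),
            design=str(f.attrs["design"]),
            golden_angle=float(f.attrs["golden_angle"]),
            samples_per_spoke=int(f.attrs["samples_per_spoke"]),
            k_max=float(f.attrs["k_max"]),
            si_spoke_mode=str(f.attrs["si_spoke_mode"]),
        )
        order = f["order"][()]
        angles = f["angles"][()]
        return SpokeSet(
            config=cfg, n=order[:, 0].astype(int),
            within=order[:, 1].astype(int), interleave=order[:, 2].astype(int),
            theta=angles[:, 0], phi=angles[:, 1],
            directions=f["directions"][()],
            is_si_spoke=f["is_si_spoke"][()].astype(bool),
        )


def save_trajectory_csv(path, spoke_set: SpokeSet) -> None:
    """One spoke per row: n, j, k, theta, phi, dx, dy, dz."""
    d = spoke_set.directions
    pd.DataFrame({
        "n": spoke_set.n, "j": spoke_set.within, "k": spoke_set.interleave,
        "theta": spoke_set.theta, "phi": spoke_set.phi,
        "dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2],
    }).to_csv(path, index=False)


def save_kspace_h5(path, kspace: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data_real", data=kspace.samples.real)
        f.create_dataset("data_imag", data=kspace.samples.imag)
        f.create_dataset("coords_nominal", data=kspace.nominal_coords)
        f.create_dataset("coords_effective", data=kspace.effective_coords)
        ss = kspace.spoke_set
        f.create_dataset("spoke_order", data=np.column_stack(
            [ss.n, ss.within, ss.interleave]))
        f.attrs["center_index"] = kspace.center_index
        f.attrs["meta_json"] = json.dumps(kspace.meta, default=str)
        g = f.create_group("trajectory")
        cfg = ss.config
        for key in ("design", "golden_angle", "k_max", "n_spokes",
                    "n_interleaves", "samples_per_spoke", "si_spoke_mode"):
            g.attrs[key] = getattr(cfg, key)
        g.create_dataset("directions", data=ss.directions)
        g.create_dataset("angles", data=np.column_stack([ss.theta, ss.phi]))
        g.create_dataset("is_si_spoke", data=ss.is_si_spoke)


def load_kspace_h5(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        cfg = TrajectoryConfig(
            n_spokes=int(g.attrs["n_spokes"]),
            n_interleaves=int(g.attrs["n_interleaves"]),
            design=str(g.attrs["design"]),
            golden_angle=float(g.attrs["golden_angle"]),
            samples_per_spoke=int(g.attrs["samples_per_spoke"]),
            k_max=float(g.attrs["k_max"]),
            si_spoke_mode=str(g.attrs["si_spoke_mode"]),
        )
        order = f["spoke_order"][()]
        angles = g["angles"][()]
        ss = SpokeSet(
            config=cfg, n=order[:, 0].astype(int),
            within=order[:, 1].astype(int), interleave=order[:, 2].astype(int),
            theta=angles[:, 0], phi=angles[:, 1],
            directions=g["directions"][()],
            is_si_spoke=g["is_si_spoke"][()].astype(bool),
        )
        return KSpaceData(
            samples=f["data_real"][()] + 1j * f["data_imag"][()],
            nominal_coords=f["coords_nominal"][()],
            effective_coords=f["coords_effective"][()],
            spoke_set=ss,
            center_index=int(f.attrs["center_index"]),
            meta=json.loads(f.attrs["meta_json"]),
        )


def load_phantom_yaml(path) -> PhantomSpec:
    with open(path) as f:
        spec = yaml.safe_load(f)
    comps = []
    for c in spec["compartments"]:
        tissue = None
        if "tissue" in c and c["tissue"] is not None:
            t = c["tissue"]
            tissue = Tissue(
                t1_ms=float(t["T1"]), t2_ms=float(t["T2"]),
                off_resonance_hz=float(t.get("off_resonance", 0.0)),
                proton_density=float(t.get("proton_density", 1.0)),
            )
        amp = c.get("amplitude", 1.0)
        if isinstance(amp, dict):
            amp = complex(amp.get("real", 0.0), amp.get("imag", 0.0))
        comps.append(Compartment(
            center=tuple(c["center"]), radius=float(c["radius"]),
            amplitude=complex(amp), tissue=tissue,
        ))
    return PhantomSpec(compartments=tuple(comps))


def save_phantom_yaml(path, phantom: PhantomSpec) -> None:
    comps = []
    for c in phantom.compartments:
        amp = complex(c.amplitude)
        entry = {
            "center": [float(v) for v in c.center], "radius": float(c.radius),
            "amplitude": {"real": float(amp.real), "imag": float(amp.imag)},
        }
        if c.tissue is not None:
            entry["tissue"] = {
                "T1": float(c.tissue.t1_ms), "T2": float(c.tissue.t2_ms),
                "off_resonance": float(c.tissue.off_resonance_hz),
                "proton_density": float(c.tissue.proton_density),
            }
        comps.append(entry)
    with open(path, "w") as f:
        yaml.safe_dump({"compartments": comps}, f)


def load_imperfections_yaml(path) -> ImperfectionModel:
    with open(path) as f:
        spec = yaml.safe_load(f) or {}
    return ImperfectionModel(
        phase_coeffs=tuple(spec.get("phase_coeffs", (0.0, 0.0, 0.0))),
        delays=tuple(spec.get("delays", (0.0, 0.0, 0.0))),
        global_delay=float(spec.get("global_delay", 0.0)),
        noise_sigma=float(spec.get("noise_sigma", 0.0)),
    )


def save_imperfections_yaml(path, model: ImperfectionModel) -> None:
    with open(path, "w") as f:
        yaml.safe_dump({
            "phase_coeffs": [float(v) for v in model.phase_coeffs],
            "delays": [float(v) for v in model.delays],
            "global_delay": float(model.global_delay),
            "noise_sigma": float(model.noise_sigma),
        }, f)


def save_volume_nifti(prefix, volume: np.ndarray, voxel_mm: float = 1.0) -> None:
    """Write magnitude and phase of a complex volume as two NIfTI files."""
    prefix = str(prefix)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.abs(volume).astype(np.float32), affine),
             prefix + "_mag.nii.gz")
    nib.save(nib.Nifti1Image(np.angle(volume).astype(np.float32), affine),
             prefix + "_phase.nii.gz")


def save_volume_h5(path, volume: np.ndarray, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=np.real(volume))
        f.create_dataset("imag", data=np.imag(volume))
        f.attrs["provenance_json"] = json.dumps(provenance or {}, default=str)
    sidecar = Path(str(path)).with_suffix(".json")
    sidecar.write_text(json.dumps(provenance or {}, default=str, indent=2))


def load_volume_h5(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["real"][()] + 1j * f["imag"][()]
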