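"""File-format plumbing: NIfTI volumes, FSL bval/bvec, sidecars, manifests.

NIfTI affines are passed through untouched (no resampling; inputs to the
g-ratio stage are assumed aligned).  FSL .bval/.bvec files carry no pulse
timings, so a small JSON sidecar supplies δ, Δ (ms) and, optionally, per-
shell gradient strengths; G is otherwise derived from each shell's b-value.
"""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np

from .signal_model import (
    GAMMA_PROTON,
    AcquisitionProtocol,
    Shell,
    ShellTable,
    gradient_from_bvalue,
)

__all__ = [
    "load_volume",
    "save_volume",
    "read_bvals_bvecs",
    "read_timing_sidecar",
    "protocol_from_files",
    "write_shell_manifest",
    "read_shell_manifest",
    "read_echo_times",
]


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), affine), str(path))


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-format b-value (1×N) and b-vector (3×N) text files."""
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (3, bvals.size):
        raise ValueError(
            f"bvec shape {bvecs.shape} inconsistent with {bvals.size} b-values")
    return bvals, bvecs


def read_timing_sidecar(path) -> dict:
    """JSON sidecar with pulse timings: keys delta, Delta (ms), optional gamma."""
    with open(path) as fh:
        side = json.load(fh)
    for key in ("delta", "Delta"):
        if key not in side:
            raise ValueError(f"timing sidecar missing {key!r}")
    if side["delta"] >= side["Delta"]:
        raise ValueError("sidecar must satisfy delta < Delta")
    side.setdefault("gamma", GAMMA_PROTON)
    return side


def protocol_from_files(bval_path, bvec_path, sidecar_path,
                        rtol: float = 0.05) -> tuple[AcquisitionProtocol, ShellTable]:
    """Build a protocol and shell assignment from FSL files plus a sidecar."""
    bvals, _ = read_bvals_bvecs(bval_path, bvec_path)
    side = read_timing_sidecar(sidecar_path)
    table = ShellTable.from_bvals(bvals, rtol=rtol)
    if table.n_shells == 0:
        raise ValueError("no non-zero b-shells found")
    gamma, delta, Delta = side["gamma"], side["delta"], side["Delta"]
    shells = tuple(
        Shell(float(b), int((table.assignment == i).sum()),
              gradient_from_bvalue(gamma, delta, Delta, b), delta, Delta)
        for i, b in enumerate(table.shell_b)
    )
    n_b0 = int((table.assignment == -1).sum())
    return AcquisitionProtocol(shells=shells, gamma=gamma, n_b0=n_b0), table


def write_shell_manifest(path, protocol: AcquisitionProtocol) -> None:
    """JSON manifest describing the spherical-mean output's shells."""
    manifest = {
        "gamma": protocol.gamma,
        "n_b0": protocol.n_b0,
        "shells": [
            {"b_value": s.b_value, "n_directions": s.n_directions,
             "gradient_strength": s.gradient_strength,
             "delta": s.delta, "Delta": s.Delta}
            for s in protocol.shells
        ],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_shell_manifest(path) -> AcquisitionProtocol:
    with open(path) as fh:
        manifest = json.load(fh)
    shells = tuple(Shell(**s) for s in manifest["shells"])
    return AcquisitionProtocol(shells=shells, gamma=manifest["gamma"],
                               n_b0=manifest.get("n_b0", 1))


def read_echo_times(path) -> np.ndarray:
    """Echo-time table: one value in ms per line."""
    te = np.loadtxt(str(path), ndmin=1).ravel()
    if te.size < 2:
        raise ValueError("echo-time table needs at least two entries")
    return te
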