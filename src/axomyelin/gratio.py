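"""Aggregate g-ratio from myelin water fraction and intra-axonal fraction.

The voxel-aggregate g-ratio combines a myelin volume fraction (MVF) and an
axon volume fraction (AVF):

    g = (1 + MVF/AVF)^(−1/2)

MVF is obtained from the MWF with an ex vivo calibration,

    MVF = 0.859·MWF / (0.384·MWF + 0.475)

and AVF from the intra-axonal signal fraction of the diffusion model,

    AVF = (1 − MVF) · f_ia.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "mvf_from_mwf",
    "avf_from_mvf",
    "gratio_from_fractions",
    "gratio_volume",
]

# ex vivo MWF -> MVF calibration constants
_CAL_NUM = 0.859
_CAL_SLOPE = 0.384
_CAL_OFFSET = 0.475


def mvf_from_mwf(mwf):
    """Myelin volume fraction from myelin water fraction (ex vivo calibration).

    Strictly increasing on [0, 1] with mvf(0) = 0 and mvf(1) = 1.
    """
    mwf = np.asarray(mwf, float)
    valid = np.isnan(mwf) | ((mwf >= 0.0) & (mwf <= 1.0))
    if not np.all(valid):
        raise ValueError("mwf must lie in [0, 1]")
    out = _CAL_NUM * mwf / (_CAL_SLOPE * mwf + _CAL_OFFSET)
    return out if out.ndim else float(out)


def avf_from_mvf(mvf, f_ia):
    """Axon volume fraction, AVF = (1 − MVF) · f_ia."""
    mvf = np.asarray(mvf, float)
    f_ia = np.asarray(f_ia, float)
    for name, v in (("mvf", mvf), ("f_ia", f_ia)):
        bad = ~(np.isnan(v) | ((v >= 0.0) & (v <= 1.0)))
        if np.any(bad):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = (1.0 - mvf) * f_ia
    return out if out.ndim else float(out)


def gratio_from_fractions(mvf, avf):
    """Aggregate g-ratio, g = (1 + MVF/AVF)^(−1/2).

    g ∈ (0, 1]; g = 1 iff MVF = 0.  Where AVF = 0 with MVF > 0 the ratio is
    undefined and NaN is returned (with a warning).
    """
    mvf = np.asarray(mvf, float)
    avf = np.asarray(avf, float)
    if np.any(mvf[~np.isnan(mvf)] < 0) or np.any(avf[~np.isnan(avf)] < 0):
        raise ValueError("mvf and avf must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 / np.sqrt(1.0 + mvf / avf)
    zero_mvf = (mvf == 0.0)
    g = np.where(zero_mvf, 1.0, g)  # MVF=0 gives g=1 even at AVF=0
    undefined = (avf == 0.0) & (mvf > 0.0)
    if np.any(undefined):
        warnings.warn("g-ratio undefined where AVF=0 with MVF>0; set to NaN")
        g = np.where(undefined, np.nan, g)
    return g if g.ndim else float(g)


def gratio_volume(mwf_map, fia_map, mask=None,
                  exclude_low_mwf: bool = False,
                  mwf_threshold: float = 0.05) -> dict[str, np.ndarray]:
    """Voxelwise g-ratio (plus MVF and AVF maps) from aligned input maps.

    ``exclude_low_mwf`` masks voxels with MWF below ``mwf_threshold`` (nearly
    unmyelinated tissue) before the computation, the same exclusion used in
    correlation analyses.  Outputs are NaN outside the mask.
    """
    mwf = np.asarray(mwf_map, float)
    fia = np.asarray(fia_map, float)
    if mwf.shape != fia.shape:
        raise ValueError("mwf and f_ia maps must share geometry")
    if mask is None:
        mask = np.ones(mwf.shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != mwf.shape:
        raise ValueError("mask shape mismatch")
    mask = mask & np.isfinite(mwf) & np.isfinite(fia)
    if exclude_low_mwf:
        mask = mask & (mwf >= mwf_threshold)

    mvf = np.full(mwf.shape, np.nan)
    avf = np.full(mwf.shape, np.nan)
    g = np.full(mwf.shape, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mvf[mask] = mvf_from_mwf(mwf[mask])
        avf[mask] = avf_from_mvf(mvf[mask], fia[mask])
        g[mask] = gratio_from_fractions(mvf[mask], avf[mask])
    return {"g": g, "mvf": mvf, "avf": avf}
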